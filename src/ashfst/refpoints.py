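"""Reference-point transformations for relative-coancestry matrices.

Every F_ST-like matrix is relative to some reference value: the mean
between-population coancestry (the default here), the minimum
between-population value (Ochoa & Storey's choice, which forces all
entries non-negative), or any external constant below 1.  Moving
between references is an affine map ``F -> (F - c) / (1 - c)``; these
maps form a closed family under composition, preserve the ordering of
elements within one matrix, and leave pairwise (two-population) F_ST
values untouched.
"""

from __future__ import annotations

import numpy as np

from .theory import FstMatrix, ValidationError

__all__ = [
    "to_os_reference",
    "from_os_reference",
    "to_constant_reference",
    "to_percentile_reference",
]

_SINGULAR = 1e-12


def _shift(values: np.ndarray, c: float) -> np.ndarray:
    if abs(1.0 - c) < _SINGULAR:
        raise ValidationError("singular reference shift: constant equals 1")
    return (values - c) / (1.0 - c)


def to_os_reference(f: FstMatrix) -> FstMatrix:
    """Re-express relative to the minimum off-diagonal element.

    The result has all elements non-negative and a zero minimum
    off-diagonal; the pair attaining the minimum is recorded in
    ``argmin_pair`` for diagnostics (its value, not its identity, is
    what the transform uses).
    """
    if f.reference != "mean-between":
        raise ValidationError("to_os_reference expects a mean-between matrix")
    off = f.offdiag()
    c = float(off.min())
    if c >= 1.0 - _SINGULAR:
        raise ValidationError("minimum off-diagonal element equals 1")
    mask = ~np.eye(f.r, dtype=bool)
    flat = np.where(mask, f.values, np.inf)
    i, j = np.unravel_index(int(np.argmin(flat)), f.values.shape)
    return FstMatrix(
        values=_shift(f.values, c),
        reference="minimum-between",
        origin=f.origin,
        argmin_pair=(int(i), int(j)),
    )


def from_os_reference(f_os: FstMatrix) -> FstMatrix:
    """Invert :func:`to_os_reference`.

    Recentres on the mean off-diagonal element of the minimum-referenced
    matrix; round-trips with :func:`to_os_reference` exactly (up to
    floating point).
    """
    if f_os.reference != "minimum-between":
        raise ValidationError("from_os_reference expects a minimum-between matrix")
    c = float(f_os.offdiag().mean())
    if c >= 1.0 - _SINGULAR:
        raise ValidationError("mean off-diagonal element equals 1")
    return FstMatrix(values=_shift(f_os.values, c), reference="mean-between", origin=f_os.origin)


def to_constant_reference(f: FstMatrix, c: float) -> FstMatrix:
    """Shift to an arbitrary external constant ``c < 1``.

    ``c`` must be expressed on the same relative scale as ``f`` (e.g. a
    coancestry of a known outgroup already referenced the same way).
    With ``c = 0`` this is the identity; with ``c`` equal to the
    minimum off-diagonal it reproduces :func:`to_os_reference`.
    """
    if c >= 1.0:
        raise ValidationError("reference constant must be below 1")
    return FstMatrix(
        values=_shift(f.values, c),
        reference="external-constant",
        origin=f.origin,
        constant=float(c),
    )


def to_percentile_reference(f: FstMatrix, q: float) -> FstMatrix:
    """Use the ``q``-th percentile of the off-diagonal elements as reference.

    A robust alternative to the minimum (``q = 0`` recovers it); avoids
    the statistical instability of an extreme order statistic.
    """
    if not (0.0 <= q <= 100.0):
        raise ValidationError("percentile must lie in [0, 100]")
    c = float(np.percentile(f.offdiag(), q))
    return to_constant_reference(f, c)
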