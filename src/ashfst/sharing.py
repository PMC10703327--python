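"""Allele-sharing matrices and the moment estimators built on them.

Allele sharing between two individuals at a biallelic locus is the
probability that one allele drawn uniformly from each individual matches
in type: for dosages ``x, y`` (alternate-allele counts) under ploidy
``k`` it equals ``(x*y + (k-x)*(k-y)) / k**2``.  For diploids this is
the familiar table — 1 for identical homozygotes, 0 for opposite
homozygotes, 0.5 whenever at least one individual is heterozygous —
and self-sharing is 1 for homozygotes, 0.5 for heterozygotes.

Averaging sharing over many loci yields an individual-level matrix
``A`` and a population-level matrix ``Abar`` (self-sharing excluded
from within-population means).  Every estimator here is a ratio of the
form ``(A - ref) / (1 - ref)``: kinship and individual inbreeding use
the mean between-individual sharing as reference, the F_ST family uses
the mean between-population sharing ``Abar_B``.  Being ratios of
differences, they are invariant to adding monomorphic loci and
unbiased for the corresponding relative coancestries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .theory import FstMatrix, ValidationError

__all__ = [
    "GenotypeData",
    "SharingMatrices",
    "KinshipMatrix",
    "pair_sharing_locus",
    "sharing_matrix",
    "kinship_as",
    "individual_fis",
    "fst_matrix_estimate",
    "overall_fst_estimate",
    "pairwise_fst_estimate",
    "MissingDataError",
]

_SINGULAR = 1e-12


class MissingDataError(ValueError):
    """A required quantity cannot be computed because of missing data."""


@dataclass(frozen=True)
class GenotypeData:
    """Integer dosage matrix (individuals x loci) with population labels.

    ``dosages`` holds alternate-allele counts in ``{0, ..., ploidy}``
    as floats, with ``NaN`` marking missing genotypes.  Every sample is
    assigned to exactly one population through ``pop_of``.
    """

    dosages: np.ndarray
    sample_ids: tuple[str, ...]
    pop_of: dict[str, str]
    ploidy: int = 2
    positions: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if d.ndim != 2:
            raise ValidationError("dosages must be a 2-D (samples x loci) matrix")
        if d.shape[1] < 1:
            raise ValidationError("at least one locus is required")
        if len(self.sample_ids) != d.shape[0]:
            raise ValidationError("sample_ids length does not match dosage rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.ploidy < 1:
            raise ValidationError("ploidy must be a positive integer")
        finite = d[np.isfinite(d)]
        if finite.size and (
            np.any(finite < 0)
            or np.any(finite > self.ploidy)
            or np.any(finite != np.round(finite))
        ):
            raise ValidationError(
                f"dosages must be integers in 0..{self.ploidy} or missing"
            )
        missing = [s for s in self.sample_ids if s not in self.pop_of]
        if missing:
            raise ValidationError(f"samples without population assignment: {missing}")
        if self.positions is not None:
            pos = np.asarray(self.positions)
            if pos.shape != (d.shape[1],):
                raise ValidationError("positions must have one entry per locus")
            object.__setattr__(self, "positions", pos)

    @property
    def n_T(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def L(self) -> int:
        return int(self.dosages.shape[1])

    @property
    def populations(self) -> tuple[str, ...]:
        """Distinct population labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of[s], None)
        return tuple(seen)

    @property
    def r(self) -> int:
        return len(self.populations)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population's samples."""
        labels = np.array([self.pop_of[s] for s in self.sample_ids])
        return {p: np.flatnonzero(labels == p) for p in self.populations}

    def n_i(self) -> dict[str, int]:
        return {p: len(ix) for p, ix in self.pop_indices().items()}


@dataclass(frozen=True)
class SharingMatrices:
    """Individual- and population-level mean allele-sharing.

    ``A`` is the n_T x n_T matrix of per-pair sharing averaged over
    jointly non-missing loci (diagonal = self-sharing).  ``Abar`` is
    the r x r population summary; its diagonal excludes self-sharing
    and is NaN for populations with fewer than two sampled individuals.
    """

    A: np.ndarray
    Abar: np.ndarray
    populations: tuple[str, ...]
    loci_used: np.ndarray

    @property
    def A_B_ind(self) -> float:
        """Mean off-diagonal individual-level sharing."""
        n = self.A.shape[0]
        return float(self.A[~np.eye(n, dtype=bool)].mean())

    @property
    def Abar_B(self) -> float:
        """Unweighted mean sharing over the r(r-1)/2 population pairs."""
        r = self.Abar.shape[0]
        return float(self.Abar[~np.eye(r, dtype=bool)].mean())

    @property
    def Abar_S(self) -> float:
        """Mean within-population sharing (populations weighted equally)."""
        return float(np.nanmean(np.diag(self.Abar)))

    @property
    def r(self) -> int:
        return int(self.Abar.shape[0])


@dataclass(frozen=True)
class KinshipMatrix:
    """Allele-sharing kinship relative to the mean between-individual sharing."""

    values: np.ndarray
    reference: str = "mean-between-individuals"

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding relative to the total sample: 2*K_jj - 1."""
        return 2.0 * np.diag(self.values) - 1.0


def pair_sharing_locus(x: float, y: float, k: int = 2) -> float:
    """Allele sharing between dosages ``x`` and ``y`` under ploidy ``k``.

    Probability that one allele drawn uniformly (with replacement) from
    each individual matches: ``(x*y + (k-x)*(k-y)) / k**2``.  Applies
    to self-sharing with ``x == y``.
    """
    if not (0 <= x <= k) or not (0 <= y <= k):
        raise ValidationError(f"dosages must lie in 0..{k}")
    return (x * y + (k - x) * (k - y)) / k**2


def sharing_matrix(g: GenotypeData) -> SharingMatrices:
    """Compute individual (``A``) and population (``Abar``) sharing matrices.

    Per-pair averages run over jointly non-missing loci
    (pairwise-complete).  A pair with no jointly observed locus is an
    error; populations with a single sampled individual get a NaN
    within-population entry (with a warning) but still contribute to
    between-population entries.
    """
    k = g.ploidy
    D = g.dosages
    valid = np.isfinite(D)
    X = np.where(valid, D, 0.0)
    Y = np.where(valid, k - D, 0.0)
    # loci where either member is missing contribute 0 to both products
    S = X @ X.T + Y @ Y.T
    counts = (valid.astype(np.int64)) @ (valid.astype(np.int64)).T
    if np.any(counts == 0):
        jj = np.argwhere(counts == 0)
        pairs = [(g.sample_ids[a], g.sample_ids[b]) for a, b in jj[:5]]
        raise MissingDataError(
            f"pairs with zero jointly observed loci: {pairs}"
            + (" ..." if len(jj) > 5 else "")
        )
    A = S / (k**2 * counts)

    pops = g.populations
    idx = g.pop_indices()
    r = len(pops)
    Abar = np.empty((r, r))
    for a, p in enumerate(pops):
        ia = idx[p]
        for b in range(a, r):
            ib = idx[pops[b]]
            block = A[np.ix_(ia, idx[pops[b]])]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(
                        f"population {p!r} has a single sampled individual; "
                        "its within-population sharing is undefined",
                        stacklevel=2,
                    )
                    Abar[a, a] = np.nan
                else:
                    mask = ~np.eye(len(ia), dtype=bool)
                    Abar[a, a] = block[mask].mean()
            else:
                Abar[a, b] = Abar[b, a] = block.mean()
    return SharingMatrices(A=A, Abar=Abar, populations=pops, loci_used=counts)


def _checked_ref(ref: float, what: str) -> float:
    if abs(1.0 - ref) < _SINGULAR:
        raise ValidationError(f"singular reference: {what} equals 1")
    return ref


def kinship_as(s: SharingMatrices) -> KinshipMatrix:
    """Allele-sharing kinship: ``(A - A_B) / (1 - A_B)``.

    ``A_B`` is the mean off-diagonal element of ``A``; the off-diagonal
    of the result averages to zero by construction.
    """
    ab = _checked_ref(s.A_B_ind, "mean between-individual sharing")
    return KinshipMatrix(values=(s.A - ab) / (1.0 - ab))


def individual_fis(
    s: SharingMatrices, g: GenotypeData
) -> tuple[np.ndarray, dict[str, float], float]:
    """Inbreeding relative to one's own population.

    Returns per-individual values
    ``F_j = 2*(A_jj - A_ii)/(1 - A_ii) - 1`` (``A_ii`` the mean
    between-individual sharing within j's population), per-population
    means (the population F_IS), and the overall F_IS.

    The overall value pools populations with equal weight before the
    ratio is taken — mean within-individual identity over mean
    within-population sharing — which is what makes it coincide
    exactly with the Weir-Cockerham F_IS when sample sizes are equal
    (a mean of the per-population ratios would not).
    """
    pops = s.populations
    idx = g.pop_indices()
    self_sharing = np.diag(s.A)
    per_ind = np.full(g.n_T, np.nan)
    pop_fis: dict[str, float] = {}
    q1_pop = np.full(len(pops), np.nan)  # mean within-individual identity 2*A_jj - 1
    for a, p in enumerate(pops):
        aii = s.Abar[a, a]
        if not np.isfinite(aii):
            pop_fis[p] = np.nan
            continue
        _checked_ref(aii, f"within-population sharing of {p!r}")
        rows = idx[p]
        q1_pop[a] = (2.0 * self_sharing[rows] - 1.0).mean()
        per_ind[rows] = 2.0 * (self_sharing[rows] - aii) / (1.0 - aii) - 1.0
        pop_fis[p] = float(per_ind[rows].mean())
    abar_s = s.Abar_S
    overall = float((np.nanmean(q1_pop) - abar_s) / (1.0 - abar_s))
    return per_ind, pop_fis, overall


def fst_matrix_estimate(s: SharingMatrices) -> FstMatrix:
    """The F_ST matrix estimate ``(Abar - Abar_B) / (1 - Abar_B)``.

    Diagonal entries are population-specific F_ST estimates, the
    off-diagonal entries population-pair values, all relative to the
    mean between-population sharing (off-diagonal mean is zero).
    """
    if s.r < 2:
        raise ValidationError("F_ST requires at least two populations")
    ab = _checked_ref(s.Abar_B, "mean between-population sharing")
    values = (s.Abar - ab) / (1.0 - ab)
    return FstMatrix(values=values, reference="mean-between", origin="estimated-from-data")


def overall_fst_estimate(f: FstMatrix | SharingMatrices) -> float:
    """Overall F_ST: mean of the population-specific (diagonal) estimates.

    Accepts either the estimated F_ST matrix or the sharing matrices
    (in which case it equals ``(Abar_S - Abar_B) / (1 - Abar_B)``).
    """
    if isinstance(f, SharingMatrices):
        f = fst_matrix_estimate(f)
    return float(np.nanmean(np.diag(f.values)))


def pairwise_fst_estimate(s: SharingMatrices | FstMatrix) -> np.ndarray:
    """Pairwise F_ST for every population pair, using only that pair.

    Entry ``(i, i')`` is ``[(A_ii + A_i'i')/2 - A_ii'] / (1 - A_ii')``.
    The same formula applied to the elements of any reference-shifted
    F_ST matrix gives identical values: pairwise F_ST does not depend
    on the reference point.
    """
    mat = s.Abar if isinstance(s, SharingMatrices) else s.values
    r = mat.shape[0]
    diag = np.diag(mat)
    denom = 1.0 - mat
    off = ~np.eye(r, dtype=bool)
    if np.any(np.abs(denom[off]) < _SINGULAR):
        raise ValidationError("singular pair: between-population sharing is 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (0.5 * (diag[:, None] + diag[None, :]) - mat) / denom
    np.fill_diagonal(out, 0.0)
    return out
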