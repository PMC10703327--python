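"""Statistical evaluation: RMSE against theory, subsampling, bootstrap,
and an independent Weir & Cockerham (1984) oracle.

The allele-sharing F_ST matrix estimator weights populations equally;
with equal sample sizes its overall value coincides with the classical
Weir & Cockerham variance-components estimator, which is reimplemented
here from the 1984 a/b/c components as an independent cross-check (it
is never used as the estimator itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sharing import GenotypeData, fst_matrix_estimate, sharing_matrix
from .theory import FstMatrix, ValidationError

__all__ = [
    "RmseReport",
    "rmse",
    "subsample_loci",
    "subsample_individuals",
    "block_bootstrap_ci",
    "wc_oracle",
]


@dataclass(frozen=True)
class RmseReport:
    """Elementwise root-mean-square error of replicate F_ST estimates."""

    per_element: np.ndarray
    n_replicates: int

    @property
    def pooled(self) -> np.ndarray:
        """All elements (diagonal and off-diagonal) flattened."""
        return self.per_element.ravel()

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.per_element)

    @property
    def offdiagonal(self) -> np.ndarray:
        r = self.per_element.shape[0]
        return self.per_element[~np.eye(r, dtype=bool)]

    def median(self, which: str = "pooled") -> float:
        return float(np.median(getattr(self, which)))


def rmse(estimates: list[FstMatrix], expected: FstMatrix) -> RmseReport:
    """Square root of the mean squared deviation from the expected matrix,
    computed per element over replicates."""
    if not estimates:
        raise ValidationError("need at least one replicate estimate")
    for e in estimates:
        if e.values.shape != expected.values.shape:
            raise ValidationError("replicate dimension does not match expectation")
        if e.reference != expected.reference:
            raise ValidationError("mixed reference points in RMSE computation")
    dev = np.stack([e.values - expected.values for e in estimates])
    return RmseReport(per_element=np.sqrt(np.mean(dev**2, axis=0)), n_replicates=len(estimates))


def subsample_loci(g: GenotypeData, L_sub: int, seed: int) -> GenotypeData:
    """Uniform subsample of loci without replacement."""
    if L_sub > g.L:
        raise ValidationError(f"requested {L_sub} loci but only {g.L} available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(g.L, size=L_sub, replace=False))
    return GenotypeData(
        dosages=g.dosages[:, keep],
        sample_ids=g.sample_ids,
        pop_of=g.pop_of,
        ploidy=g.ploidy,
        positions=None if g.positions is None else g.positions[keep],
    )


def subsample_individuals(g: GenotypeData, n_sub: int, seed: int) -> GenotypeData:
    """Subsample ``n_sub`` individuals from every population."""
    rng = np.random.default_rng(seed)
    keep_rows: list[int] = []
    for pop, rows in g.pop_indices().items():
        if n_sub > len(rows):
            raise ValidationError(
                f"requested {n_sub} individuals but population {pop!r} has {len(rows)}"
            )
        keep_rows.extend(rng.choice(rows, size=n_sub, replace=False))
    keep_rows = sorted(keep_rows)
    ids = [g.sample_ids[i] for i in keep_rows]
    return GenotypeData(
        dosages=g.dosages[keep_rows, :],
        sample_ids=ids,
        pop_of={s: g.pop_of[s] for s in ids},
        ploidy=g.ploidy,
        positions=g.positions,
    )


def block_bootstrap_ci(
    g: GenotypeData,
    stat,
    B: int = 1000,
    block_loci: int | None = None,
    block_span: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``stat`` over blocks of loci.

    Blocks are either ``block_loci`` consecutive loci or, when the data
    carry positions, all loci in half-open windows of ``block_span``
    base pairs.  Blocks are resampled with replacement ``B`` times and
    the statistic (a callable GenotypeData -> float) recomputed on each
    resample; blocking preserves local linkage so the interval remains
    honest for correlated loci.
    """
    if B < 1:
        raise ValidationError("B must be at least 1")
    if (block_loci is None) == (block_span is None):
        raise ValidationError("specify exactly one of block_loci or block_span")
    if block_span is not None:
        if g.positions is None:
            raise ValidationError("base-pair blocking requires locus positions")
        pos = np.asarray(g.positions, dtype=np.int64)
        starts = (pos // block_span) * block_span
        blocks = [np.flatnonzero(starts == s) for s in np.unique(starts)]
    else:
        if block_loci < 1:
            raise ValidationError("block_loci must be positive")
        edges = np.arange(0, g.L, block_loci)
        blocks = [np.arange(s, min(s + block_loci, g.L)) for s in edges]
    if len(blocks) < 2:
        raise ValidationError("need at least two blocks to bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    nb = len(blocks)
    for b in range(B):
        chosen = rng.integers(0, nb, size=nb)
        cols = np.concatenate([blocks[c] for c in chosen])
        resampled = GenotypeData(
            dosages=g.dosages[:, cols],
            sample_ids=g.sample_ids,
            pop_of=g.pop_of,
            ploidy=g.ploidy,
        )
        vals[b] = stat(resampled)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def wc_oracle(g: GenotypeData) -> tuple[float, float]:
    """Weir & Cockerham (1984) multilocus F_ST and F_IS for diploid data.

    Computed from the variance components a (among populations),
    b (among individuals within populations) and c (within individuals),
    as ratio-of-sums over loci: F_ST = sum(a)/sum(a+b+c),
    F_IS = 1 - sum(c)/sum(b+c).  Restricted to diploid, complete data;
    loci monomorphic across the whole sample contribute nothing.
    """
    if g.ploidy != 2:
        raise ValidationError("the Weir-Cockerham oracle supports diploids only")
    if not np.all(np.isfinite(g.dosages)):
        raise ValidationError("the Weir-Cockerham oracle requires complete data")
    idx = g.pop_indices()
    r = g.r
    if r < 2:
        raise ValidationError("need at least two populations")
    n_i = np.array([len(rows) for rows in idx.values()], dtype=float)  # per pop
    D = g.dosages
    p_il = np.stack([D[rows].mean(axis=0) / 2.0 for rows in idx.values()])  # r x L
    h_il = np.stack([(D[rows] == 1).mean(axis=0) for rows in idx.values()])  # obs het

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_il).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_il).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0

    denom_st = (a + b + c).sum()
    denom_is = (b + c).sum()
    if denom_st == 0:
        raise ValidationError("all loci monomorphic: Weir-Cockerham estimator undefined")
    # F_IS is 0/0 when every individual is homozygous and populations
    # are internally invariant; report it as missing rather than guess
    fis = float(1.0 - c.sum() / denom_is) if denom_is != 0 else float("nan")
    return float(a.sum() / denom_st), fis
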