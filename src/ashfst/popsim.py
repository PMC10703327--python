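"""Forward-in-time simulator of unlinked biallelic loci under migration.

Each locus starts from a single ancestral frequency shared by all
populations (drawn from a configurable law, uniform on (0.05, 0.95) by
default) and then evolves independently for ``T`` generations of
deterministic backward-migration mixing (``p <- M p``), symmetric
mutation at rate ``mu`` and Wright-Fisher binomial drift with ``2 N_i``
gametes per population.  This is the generative counterpart of the
coancestry recursion in :mod:`ashfst.theory`: F_ST estimated from data
sampled at generation ``T`` is, in expectation, the theory matrix at
generation ``T``.

Genotypes are sampled from the final frequencies as binomial dosages
(random union of gametes within each population), i.e. Hardy-Weinberg
within populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .sharing import GenotypeData
from .theory import MigrationModel, ValidationError

__all__ = ["SimConfig", "simulate_frequencies", "sample_genotypes", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``n_sample`` is the number of individuals drawn per population
    (a scalar applies to all).  The default study design follows the
    simulation protocol this simulator reproduces: 10^4 unlinked loci,
    50 sampled individuals per population.
    """

    model: MigrationModel
    L: int = 10_000
    T: int = 2_000
    n_sample: int | tuple[int, ...] = 50
    ploidy: int = 2
    seed: int = 0
    p0: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValidationError("L must be at least 1")
        if self.T < 1:
            raise ValidationError("T must be at least 1")
        if self.ploidy < 1:
            raise ValidationError("ploidy must be positive")
        n = self.n_per_pop()
        if np.any(n < 1):
            raise ValidationError("sample sizes must be positive")
        if np.any(n > self.model.N):
            import warnings

            warnings.warn("sampling more individuals than the effective size", stacklevel=2)

    def n_per_pop(self) -> np.ndarray:
        r = self.model.r
        n = np.asarray(self.n_sample, dtype=int)
        if n.ndim == 0:
            n = np.full(r, int(n))
        if n.shape != (r,):
            raise ValidationError(f"n_sample must be scalar or length {r}")
        return n


def _default_p0(rng: np.random.Generator, L: int) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=L)


def simulate_frequencies(cfg: SimConfig) -> np.ndarray:
    """Allele frequencies (r x L) at generation ``T``.

    Loci are independent given the seed; the ancestral frequency of
    each locus is common to all populations, representing a shared
    ancestral pool at generation 0.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.model
    r, L = model.r, cfg.L
    draw_p0 = cfg.p0 or _default_p0
    p = np.broadcast_to(draw_p0(rng, L), (r, L)).copy()
    two_n = np.round(2.0 * model.N).astype(np.int64)[:, None]
    M, mu = model.M, model.mu
    for _ in range(cfg.T):
        p = M @ p
        if mu:
            p = p * (1.0 - mu) + (1.0 - p) * mu
        p = rng.binomial(two_n, p) / two_n
    return p


def sample_genotypes(freqs: np.ndarray, cfg: SimConfig) -> GenotypeData:
    """Draw genotype dosages from population allele frequencies.

    Each sampled individual's dosage at a locus is Binomial(ploidy, p_i)
    — a random union of gametes within its population.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = cfg.n_per_pop()
    blocks = []
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    for i in range(cfg.model.r):
        pop = f"pop{i + 1}"
        blocks.append(rng.binomial(cfg.ploidy, freqs[i][None, :], size=(n[i], freqs.shape[1])))
        for j in range(n[i]):
            sid = f"{pop}_ind{j + 1}"
            sample_ids.append(sid)
            pop_of[sid] = pop
    return GenotypeData(
        dosages=np.vstack(blocks).astype(float),
        sample_ids=sample_ids,
        pop_of=pop_of,
        ploidy=cfg.ploidy,
    )


def gamete_pool_frequencies(freqs: np.ndarray, model: MigrationModel) -> np.ndarray:
    """Frequencies of the gamete pools that form generation ``T + 1``.

    One deterministic migration-mixing and mutation step applied to the
    realized generation-``T`` frequencies.  Individuals sampled from
    these pools are independent draws of generation-``T + 1`` genotypes,
    so their expected allele sharing equals the coancestry recursion at
    ``T + 1`` — including the within-population ``1/(2N)`` drift term,
    which the realized (post-drift) frequencies already carry.
    """
    p = model.M @ np.asarray(freqs, dtype=float)
    if model.mu:
        p = p * (1.0 - model.mu) + (1.0 - p) * model.mu
    return p


def simulate_dataset(cfg: SimConfig) -> GenotypeData:
    """Full pipeline: ``T`` generations of drift, then sampling of
    generation ``T + 1`` individuals from the mixed gamete pools.

    Expected F_ST of the sample equals the theory matrix at ``T + 1``
    (indistinguishable from ``T`` once F_ST is stationary).
    """
    pool = gamete_pool_frequencies(simulate_frequencies(cfg), cfg.model)
    return sample_genotypes(pool, cfg)
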