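import numpy as np
import pytest

from ashfst import GenotypeData


def random_genotypes(
    rng: np.random.Generator,
    r: int = 3,
    n_per_pop: int = 10,
    L: int = 50,
    ploidy: int = 2,
    structured: bool = True,
) -> GenotypeData:
    """Random dosage dataset; with ``structured=True`` each population
    gets its own drifted allele frequencies (a star-shaped divergence)."""
    base = rng.uniform(0.1, 0.9, size=L)
    rows, ids, pop_of = [], [], {}
    for i in range(r):
        if structured:
            p = np.clip(base + rng.normal(0, 0.15, size=L), 0.01, 0.99)
        else:
            p = base
        rows.append(rng.binomial(ploidy, p[None, :], size=(n_per_pop, L)))
        for j in range(n_per_pop):
            sid = f"pop{i + 1}_ind{j + 1}"
            ids.append(sid)
            pop_of[sid] = f"pop{i + 1}"
    return GenotypeData(
        dosages=np.vstack(rows).astype(float),
        sample_ids=ids,
        pop_of=pop_of,
        ploidy=ploidy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230871)


@pytest.fixture
def small_structured(rng):
    return random_genotypes(rng, r=4, n_per_pop=8, L=80)
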