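"""File formats and fixture construction.

Formats supported:

- VCF (read via cyvcf2, write for simulated data): biallelic SNPs only,
  dosage = alternate-allele count; any missing allele makes the
  genotype missing; multiallelic or non-SNP records are skipped and
  counted.
- Dosage TSV: first column sample id, header row of locus ids, "NA"
  for missing.
- Population map TSV: ``sample_id <tab> population``.
- Labelled square matrices as TSV (row and column labels).
- Model files as JSON: sizes vector ``N``, dense migration matrix
  ``M``, mutation rate ``mu``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sharing import GenotypeData
from .theory import (
    MigrationModel,
    ValidationError,
    make_finite_island,
    make_river,
    make_stepping_stone_1d,
)

logger = logging.getLogger("ashfst")

__all__ = [
    "read_pop_map",
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_model_json",
    "write_model_json",
    "island10_model",
    "stepping10_model",
    "river14_model",
    "discussion_genotypes",
    "hwe_panmictic_genotypes",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# population map and genotype formats


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample id, population), no header required."""
    pop_of: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sid, pop = (p.strip() for p in parts)
        if not sid or not pop or any(ch.isspace() for ch in pop):
            raise ValidationError(f"{path}:{lineno}: empty or whitespace-containing label")
        if sid in pop_of:
            raise ValidationError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        pop_of[sid] = pop
    return pop_of


def read_vcf(path: str | Path, pop_map: dict[str, str] | str | Path) -> GenotypeData:
    """Load biallelic SNPs from a VCF/BCF into a dosage matrix.

    Dosage is the alternate-allele count per genotype; a genotype with
    any missing allele is missing.  Records that are not biallelic
    SNPs are skipped (logged).  Positions are retained for block
    bootstrapping.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_map]
    if unknown:
        raise ValidationError(f"samples absent from the population map: {unknown}")
    cols: list[np.ndarray] = []
    positions: list[int] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        col = np.empty(len(samples))
        for j, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            col[j] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        cols.append(col)
        positions.append(v.POS)
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records", skipped)
    if not cols:
        raise ValidationError(f"no usable biallelic SNP records in {path}")
    return GenotypeData(
        dosages=np.column_stack(cols),
        sample_ids=samples,
        pop_of={s: pop_map[s] for s in samples},
        ploidy=2,
        positions=np.asarray(positions, dtype=np.int64),
    )


def write_vcf(g: GenotypeData, path: str | Path, header_comment: str = "") -> None:
    """Write diploid dosages as an uncompressed VCF (chrom ``1``, A/G SNPs)."""
    if g.ploidy != 2:
        raise ValidationError("VCF output supports diploid data only")
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    pos = (
        g.positions
        if g.positions is not None
        else np.arange(1, g.L + 1, dtype=np.int64) * 100
    )
    lines = ["##fileformat=VCFv4.2"]
    if header_comment:
        lines.append(f"##ashfst={header_comment}")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("##contig=<ID=1>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids))
    for l in range(g.L):
        gts = "\t".join(
            "./." if not np.isfinite(d) else gt_of[d] for d in g.dosages[:, l]
        )
        lines.append(f"1\t{int(pos[l])}\tsnp{l + 1}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pop_map(g: GenotypeData, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{g.pop_of[s]}\n" for s in g.sample_ids)
    )


def read_dosage_tsv(path: str | Path, pop_map: dict[str, str] | str | Path, ploidy: int = 2) -> GenotypeData:
    """Dosage matrix TSV: header of locus ids, first column sample id, NA = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and np.any(finite != np.round(finite)):
        raise ValidationError(f"{path}: non-integer dosages found")
    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    ids = [str(s) for s in df.index]
    missing = [s for s in ids if s not in pop_map]
    if missing:
        raise ValidationError(f"samples absent from the population map: {missing}")
    return GenotypeData(
        dosages=vals,
        sample_ids=ids,
        pop_of={s: pop_map[s] for s in ids},
        ploidy=ploidy,
    )


def write_dosage_tsv(g: GenotypeData, path: str | Path, header_comment: str = "") -> None:
    df = pd.DataFrame(
        g.dosages,
        index=list(g.sample_ids),
        columns=[f"L{l + 1}" for l in range(g.L)],
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", float_format="%g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(
    values: np.ndarray, labels: list[str], path: str | Path, header_comment: str = ""
) -> None:
    df = pd.DataFrame(np.asarray(values), index=labels, columns=labels)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# model files


def read_model_json(path: str | Path) -> MigrationModel:
    spec = json.loads(Path(path).read_text())
    return MigrationModel(
        N=np.asarray(spec["N"], dtype=float),
        M=np.asarray(spec["M"], dtype=float),
        mu=float(spec.get("mu", 0.0)),
    )


def write_model_json(model: MigrationModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"N": model.N.tolist(), "M": model.M.tolist(), "mu": model.mu},
            indent=1,
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# study scenarios and constructed fixtures

#: Default mutation rate used by the scenario builders.
DEFAULT_MU = 1e-8

RIVER_EDGES = [
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 12), (12, 13), (13, 14),
    (6, 7), (7, 8), (8, 3),
    (9, 10), (10, 11), (11, 5),
]

RIVER_SIZES = [100, 100, 200, 200, 400, 100, 100, 100, 200, 200, 200, 800, 1000, 5000]


def island10_model(m: float = 0.001, mu: float = DEFAULT_MU) -> MigrationModel:
    """Ten-island finite island scenario with heterogeneous sizes."""
    N = [1000, 1000, 10, 10, 100, 100, 500, 500, 2000, 2000]
    return make_finite_island(N, m, mu)


def stepping10_model(m: float = 0.005, r: int = 10, N: float = 1000, mu: float = DEFAULT_MU) -> MigrationModel:
    """Ten-population 1-D stepping stone scenario, constant size."""
    return make_stepping_stone_1d([N] * r, m, mu)


def river14_model(m_down: float = 0.02, m_up: float = 0.005, mu: float = DEFAULT_MU) -> MigrationModel:
    """Fourteen-station river with two tributaries and asymmetric migration."""
    return make_river(RIVER_EDGES, RIVER_SIZES, m_down, m_up, mu)


def discussion_genotypes(r: int = 4, n_per_pop: int = 2, L: int = 10) -> GenotypeData:
    """Thought-experiment dataset with a hand-computable sharing matrix.

    Populations 1 and 2 are fixed for opposite homozygotes at every
    locus; every other population consists entirely of heterozygotes
    (allele frequency 0.5 everywhere).  Population-specific F_ST is 1
    for the two fixed populations regardless of ``r``, and as ``r``
    grows the pair (1,2) tends to -1 under the mean-between reference
    while pairs of heterozygote populations tend to 0.
    """
    if r < 3:
        raise ValidationError("the construction needs at least 3 populations")
    rows = []
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    for i in range(r):
        dose = 0.0 if i == 0 else 2.0 if i == 1 else 1.0
        for j in range(n_per_pop):
            rows.append(np.full(L, dose))
            sid = f"pop{i + 1}_ind{j + 1}"
            sample_ids.append(sid)
            pop_of[sid] = f"pop{i + 1}"
    return GenotypeData(dosages=np.array(rows), sample_ids=sample_ids, pop_of=pop_of, ploidy=2)


def hwe_panmictic_genotypes(
    r: int = 4, n_per_pop: int = 50, L: int = 1000, seed: int = 0
) -> GenotypeData:
    """Samples labelled as r populations but drawn from one panmictic
    Hardy-Weinberg pool (expected F_ST and F_IS are zero)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=L)
    n = r * n_per_pop
    dosages = rng.binomial(2, p[None, :], size=(n, L)).astype(float)
    sample_ids = [f"pop{i // n_per_pop + 1}_ind{i % n_per_pop + 1}" for i in range(n)]
    pop_of = {s: s.split("_")[0] for s in sample_ids}
    return GenotypeData(dosages=dosages, sample_ids=sample_ids, pop_of=pop_of, ploidy=2)


def make_fixtures(name: str, outdir: str | Path) -> list[Path]:
    """Write a named fixture's files; returns the paths written.

    Estimator fixtures produce a dosage TSV and population map; theory
    scenarios produce a model JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _geno(g: GenotypeData, stem: str) -> None:
        dp = outdir / f"{stem}.dosage.tsv"
        pp = outdir / f"{stem}.pops.tsv"
        write_dosage_tsv(g, dp, header_comment=f"fixture {stem}")
        write_pop_map(g, pp)
        written.extend([dp, pp])

    def _model(m: MigrationModel, stem: str) -> None:
        mp = outdir / f"{stem}.model.json"
        write_model_json(m, mp)
        written.append(mp)

    if name == "discussion_r4":
        _geno(discussion_genotypes(r=4), name)
    elif name == "discussion_r500":
        _geno(discussion_genotypes(r=500), name)
    elif name == "hwe_panmictic":
        _geno(hwe_panmictic_genotypes(), name)
    elif name == "island10":
        _model(island10_model(), name)
    elif name == "stepping10":
        _model(stepping10_model(), name)
    elif name == "river14":
        _model(river14_model(), name)
    else:
        raise ValidationError(f"unknown fixture name {name!r}")
    return written
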