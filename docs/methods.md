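# Methods

## The quantities being estimated

All F-statistics here are relative quantities of the form

    F = (Q_w − Q_b) / (1 − Q_b)

where `Q_w` and `Q_b` are probabilities of identity (coancestries)
within and between structural units.  Absolute identity-by-descent
probabilities are not estimable from genotype data; only coancestries
relative to a declared reference are.  The package therefore carries a
reference tag on every F_ST matrix and provides exact transforms
between reference points.

`F_ST` is organised as an r × r matrix: the diagonal holds
population-specific values (mean within-population coancestry relative
to the mean between-population coancestry), the off-diagonal holds
population-pair values.  Off-diagonal entries can be negative — a pair
of populations that together harbour more diversity than a random pair
from the whole set sits below the reference.  The classical pairwise
F_ST (`pairwise_fst_*`) uses only the two populations involved and is
invariant to the global reference.

## Theory engine

Coancestries evolve under a backward migration matrix `M`
(`m[i,j]` = fraction of population i's alleles that were in j one
generation earlier; rows sum to 1), effective sizes `N_i` and a
mutation rate `mu`:

    Θ(t+1) = (1 − mu)² · M Φ(t) Mᵀ

where `Φ` equals `Θ` except on the diagonal, which is
`1/(2N_i) + (1 − 1/(2N_i)) θ_i` (drift).  `Θ(0) = 0`, so all
coancestries are relative to the founding generation.  Expected F_ST
uses the unweighted mean off-diagonal coancestry as reference.

Numerical choices:

- A continent is a finite population of `N = 1e9`.  Consequence: the
  continent element drifts at ~5e-10 per generation forever, so
  equilibrium detection (`iterate_to_equilibrium`) should use a change
  tolerance of about 1e-9 for continent-island models; the island
  elements then match the closed form
  `(1−m)²(1−mu)² / (2N − (2N−1)(1−m)²(1−mu)²)` to ~1e-6.
- Migration matrices are validated (row sums within 1e-12 of 1) and
  never silently renormalised.
- Each recursion step re-symmetrises the matrix (`(X + Xᵀ)/2`) to stop
  float asymmetry accumulating over thousands of generations.
- The river builder treats the stated downstream/upstream rates as
  backward (immigration) fractions: a station receives `m_down` of its
  alleles from each upstream neighbour and `m_up` from each downstream
  neighbour, the diagonal absorbing the remainder.  The
  forward/backward reading is a genuine ambiguity for asymmetric
  models; only structural properties of the river matrix are asserted.

## The allele-sharing estimator

Allele sharing between dosages `x`, `y` at a biallelic locus under
ploidy `k` is `(xy + (k−x)(k−y))/k²` — the probability that one allele
drawn uniformly (with replacement) from each individual matches.
Averaging over loci gives the individual matrix `A` and the population
summary `Ā` (self-sharing excluded from within-population means;
populations weighted equally regardless of sample size).  Every
estimator is then an affine ratio:

- kinship: `K = (A − A_B)/(1 − A_B)` with `A_B` the mean off-diagonal
  of `A`;
- F_ST matrix: `F̂ = (Ā − Ā_B)/(1 − Ā_B)` with `Ā_B` the unweighted
  mean over population pairs;
- individual inbreeding relative to own population:
  `F̂_j = 2(A_jj − Ā_ii)/(1 − Ā_ii) − 1`;
- pairwise: `[(Ā_ii + Ā_i'i')/2 − Ā_ii'] / (1 − Ā_ii')`.

Because numerator and denominator are both differences of sharing
means, appending monomorphic loci rescales them identically: every
ratio estimator is exactly invariant to monomorphic loci, so no MAF
filtering is applied by default.

The overall F_IS pools populations before the ratio — the unweighted
population mean of within-individual identity over the unweighted mean
of within-population sharing.  This is the form that coincides exactly
(to < 1e-12) with the Weir–Cockerham (1984) variance-components F_IS
at equal sample sizes; a mean of the per-population F_IS ratios does
not, differing at the 1e-3–1e-4 level.  The overall F_ST (mean of the
diagonal of `F̂`) likewise equals the Weir–Cockerham F_ST exactly at
equal sample sizes; both identities are enforced by tests against an
independently coded variance-components oracle.

Missing data policy: per-pair averages run over jointly non-missing
loci (pairwise-complete).  A pair with no jointly observed locus is an
error, never an imputation; the per-pair locus counts are kept for
diagnostics.  Populations with one sampled individual get a missing
within-population entry (warning) but still contribute between-
population sharing.

## Reference points

`to_os_reference` shifts to the minimum off-diagonal element (all
entries then ≥ 0, minimum 0), `from_os_reference` inverts it via the
mean off-diagonal, `to_constant_reference` shifts to any constant
c < 1, `to_percentile_reference` to a percentile of the off-diagonal
distribution (a robust alternative to the minimum).  The transforms
compose in closed form (`c = c1 + c2(1 − c1)`), preserve within-matrix
ordering, and leave pairwise values unchanged.  Rankings *across*
matrices (e.g. per-chromosome estimates) are not preserved by the
minimum-reference transform because each matrix subtracts its own
minimum — demonstrated in a unit test with two synthetic matrices.

## Simulator

Unlinked biallelic loci; per locus: common ancestral frequency drawn
uniform on (0.05, 0.95) (configurable), then `T` generations of
deterministic migration mixing `p ← M p`, symmetric mutation
`p ← p(1 − mu) + (1 − p) mu`, and Wright–Fisher binomial drift with
`2N_i` gametes.  Sampling matters: genotypes are drawn
`Binomial(ploidy, p*)` from the *migration-mixed* pool
`p* = mutate(M p(T))`, i.e. the sampled cohort is generation T+1.
Drawing instead from the raw generation-T frequencies inflates
within-population sharing by the with-replacement term
`(1 − θ)/(2N)` — a detectable upward bias for small demes (N = 10).
Expected values for simulated data are therefore taken from the
recursion at T+1 (numerically indistinguishable from T once F_ST is
stationary).

What the simulator does not emulate: linkage (loci are independent;
with linked SNPs roughly an order of magnitude more markers are needed
for comparable error, which is why the block bootstrap is provided for
real data), selection, non-equilibrium demography beyond the migration
matrix, and admixed individuals.  Passing tests show the estimator
recovers the model's expectations for unlinked loci under
random-union-of-gametes reproduction; they do not certify behaviour
under strong linkage or recent admixture.

## Study scenarios (defaults)

- Island: 10 islands, N = (1000, 1000, 10, 10, 100, 100, 500, 500,
  2000, 2000), total immigration m = 0.001 split equally, mu = 1e-8,
  expected F_ST read at 2000 generations.
- Stepping stone: 10 populations, N = 1000, m = 0.005 to the two
  neighbours combined (m/2 each), 4000 generations.  (Scenario
  descriptions elsewhere quote m = 0.02; the builder takes m as a
  parameter and the scenario helper uses 0.005, the value the expected
  matrix at 4000 generations corresponds to.)
- River: 14 stations, two tributaries joining the main stem at
  stations 3 and 5; m_down = 0.02 from each upstream neighbour,
  m_up = 0.005 from each downstream neighbour; sizes growing from 100
  at the sources to 5000 at the mouth; 2000 generations.
- Sampling design: 50 individuals per population, 10^4 unlinked SNPs,
  20 replicates.

## Evaluation design and problem sizes used in the test suite

RMSE is the square root of the mean squared deviation from the theory
expectation, per matrix element over replicates (diagonal and
off-diagonal pooled for summaries, also available separately).

The test suite runs the three scenarios at a reduced design chosen to
keep a full run at desk scale: 20 replicates of 2000 loci (with
200- and 600-locus subsamples for the RMSE ladder and 5-individual
subsamples for the sampling-robustness check).  The 3·SE unbiasedness
tolerance self-calibrates to the extra noise of the smaller design.

One statistical subtlety: requiring every one of ~400 matrix elements
to sit within 3·SE fails with appreciable probability even for an
exactly unbiased estimator (the expected number of |z| > 3 exceedances
among hundreds of correlated elements is of order one).  The
unbiasedness test therefore screens elementwise at 3·SE and re-tests
any flagged element on an independent replicate set: genuine bias
persists across both stages, multiple-comparison noise does not.  A
40-replicate × 4000-locus diagnostic of the river scenario (the
tightest case) gives max |z| = 1.99 over 196 elements.

Block-bootstrap confidence intervals resample blocks (fixed locus
count, or base-pair windows when positions are available) with
replacement and recompute the statistic per resample; percentile
2.5/97.5 bounds are reported.  Blocking exists to respect linkage in
real data; for the simulator's unlinked loci any block size is valid.

## Known limitations

- The Weir–Cockerham oracle covers diploid, complete-data inputs only
  (its role is cross-checking, not estimation).
- The VCF reader keeps biallelic SNPs and skips everything else;
  multiallelic records are not split.
- No phasing, imputation or LD pruning; linkage is handled only
  through the block bootstrap for uncertainty.
- Populations with a single sampled individual have no
  population-specific F_ST (their within-population sharing is
  undefined).
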