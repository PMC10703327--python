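"""Allele-sharing matrices and the moment estimators."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ashfst import (
    GenotypeData,
    fst_matrix_estimate,
    individual_fis,
    kinship_as,
    overall_fst_estimate,
    pair_sharing_locus,
    pairwise_fst_estimate,
    sharing_matrix,
)
from ashfst.io import discussion_genotypes
from ashfst.sharing import MissingDataError
from ashfst.theory import ValidationError

from conftest import random_genotypes


def enumerate_sharing(x: int, y: int, k: int) -> float:
    """Brute-force oracle: draw one of each individual's k allele slots
    (x of them alternate) and count matching ordered draws."""
    matches = 0
    for a in range(k):
        for b in range(k):
            matches += (a < x) == (b < y)
    return matches / k**2


class TestPairSharing:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(2, 2, 1.0), (0, 0, 1.0), (2, 0, 0.0), (1, 2, 0.5), (1, 0, 0.5), (1, 1, 0.5)],
    )
    def test_diploid_table(self, x, y, expected):
        assert pair_sharing_locus(x, y, k=2) == expected

    def test_self_sharing(self):
        assert pair_sharing_locus(1, 1, k=2) == 0.5  # heterozygote
        assert pair_sharing_locus(2, 2, k=2) == 1.0  # homozygote

    def test_haploid(self):
        assert pair_sharing_locus(1, 1, k=1) == 1.0
        assert pair_sharing_locus(1, 0, k=1) == 0.0

    def test_tetraploid_example(self):
        assert pair_sharing_locus(3, 1, k=4) == 0.375

    @given(st.integers(1, 6).flatmap(
        lambda k: st.tuples(st.just(k), st.integers(0, k), st.integers(0, k))
    ))
    @settings(max_examples=100, derandomize=True)
    def test_matches_enumeration_oracle_any_ploidy(self, kxy):
        k, x, y = kxy
        assert pair_sharing_locus(x, y, k) == pytest.approx(
            enumerate_sharing(x, y, k), abs=1e-15
        )

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValidationError):
            pair_sharing_locus(3, 0, k=2)


class TestSharingMatrix:
    def test_identical_homozygotes_share_everything(self):
        g = GenotypeData(
            dosages=np.zeros((2, 5)),
            sample_ids=["a", "b"],
            pop_of={"a": "p1", "b": "p1"},
        )
        s = sharing_matrix(g)
        np.testing.assert_allclose(s.A, 1.0)

    def test_discussion_fixture_hand_values(self):
        """Two populations fixed for opposite homozygotes, two all-het:
        the population sharing matrix is exactly computable by hand."""
        s = sharing_matrix(discussion_genotypes(r=4))
        np.testing.assert_allclose(np.diag(s.Abar), [1.0, 1.0, 0.5, 0.5])
        assert s.Abar[0, 1] == 0.0
        off = s.Abar[~np.eye(4, dtype=bool)]
        assert np.sum(off == 0.5) == 10
        assert s.Abar_B == pytest.approx(2.5 / 6, abs=1e-15)

    def test_missing_pair_handling(self):
        d = np.array([[0.0, np.nan, 1.0], [np.nan, 2.0, 1.0]])
        g = GenotypeData(dosages=d, sample_ids=["a", "b"], pop_of={"a": "p1", "b": "p2"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sharing_matrix(g)
        # only locus 3 is jointly observed: both het -> sharing 0.5
        assert s.A[0, 1] == 0.5
        assert s.loci_used[0, 1] == 1

    def test_no_jointly_observed_locus_is_an_error(self):
        d = np.array([[0.0, np.nan], [np.nan, 2.0]])
        g = GenotypeData(dosages=d, sample_ids=["a", "b"], pop_of={"a": "p1", "b": "p2"})
        with pytest.raises(MissingDataError):
            sharing_matrix(g)

    def test_singleton_population_flagged(self):
        d = np.array([[0.0] * 4, [1.0] * 4, [2.0] * 4])
        g = GenotypeData(
            dosages=d,
            sample_ids=["a", "b", "c"],
            pop_of={"a": "p1", "b": "p1", "c": "p2"},
        )
        with pytest.warns(UserWarning, match="single sampled individual"):
            s = sharing_matrix(g)
        assert np.isnan(s.Abar[1, 1])
        assert np.isfinite(s.Abar[0, 1])


class TestKinshipAndInbreeding:
    def test_identical_heterozygotes_give_zero_kinship(self):
        g = GenotypeData(
            dosages=np.ones((3, 4)),
            sample_ids=["a", "b", "c"],
            pop_of=dict.fromkeys(["a", "b", "c"], "p1"),
        )
        K = kinship_as(sharing_matrix(g))
        np.testing.assert_allclose(K.values, 0.0, atol=1e-15)

    def test_discussion_fixture_self_kinship_of_fixed_population(self):
        s = sharing_matrix(discussion_genotypes(r=4))
        K = kinship_as(s)
        j = 0  # member of population 1 (A_jj = 1)
        assert K.values[j, j] == pytest.approx(1.0, abs=1e-15)

    def test_inbreeding_identity_from_kinship(self, small_structured):
        K = kinship_as(sharing_matrix(small_structured))
        np.testing.assert_allclose(K.inbreeding(), 2 * np.diag(K.values) - 1, atol=1e-15)

    def test_kinship_offdiagonal_zero_mean(self, small_structured):
        K = kinship_as(sharing_matrix(small_structured))
        n = K.values.shape[0]
        assert abs(K.values[~np.eye(n, dtype=bool)].mean()) < 1e-12

    def test_fully_selfed_population_fis_is_one(self):
        # all homozygotes, mixed types so within-population sharing < 1
        d = np.array([[0.0, 2.0, 0.0, 2.0], [2.0, 0.0, 2.0, 0.0], [1.0] * 4, [1.0] * 4])
        ids = ["a", "b", "c", "d"]
        g = GenotypeData(
            dosages=d, sample_ids=ids,
            pop_of={"a": "p1", "b": "p1", "c": "p2", "d": "p2"},
        )
        per_ind, pop_fis, _ = individual_fis(sharing_matrix(g), g)
        np.testing.assert_allclose(per_ind[:2], 1.0, atol=1e-15)
        assert pop_fis["p1"] == pytest.approx(1.0)

    def test_hardy_weinberg_population_fis_near_zero(self):
        rng = np.random.default_rng(5)
        g = random_genotypes(rng, r=3, n_per_pop=60, L=2000, structured=False)
        _, pop_fis, overall = individual_fis(sharing_matrix(g), g)
        assert abs(overall) < 0.02


class TestFstEstimates:
    def test_discussion_fixture_hand_computed_elements(self):
        F = fst_matrix_estimate(sharing_matrix(discussion_genotypes(r=4)))
        assert F.values[0, 0] == pytest.approx(1.0, abs=1e-15)
        assert F.values[2, 2] == pytest.approx(1 / 7, abs=1e-12)
        assert F.values[0, 1] == pytest.approx(-5 / 7, abs=1e-12)
        assert overall_fst_estimate(F) == pytest.approx(4 / 7, abs=1e-12)

    @pytest.mark.parametrize("r", [3, 5, 20, 100])
    def test_fixed_population_fst_is_one_for_any_r(self, r):
        F = fst_matrix_estimate(sharing_matrix(discussion_genotypes(r=r)))
        assert F.values[0, 0] == pytest.approx(1.0, abs=1e-14)
        assert F.values[1, 1] == pytest.approx(1.0, abs=1e-14)

    def test_overall_identity_with_sharing_means(self, small_structured):
        s = sharing_matrix(small_structured)
        direct = (s.Abar_S - s.Abar_B) / (1 - s.Abar_B)
        assert overall_fst_estimate(s) == pytest.approx(direct, abs=1e-12)

    def test_offdiagonal_zero_mean(self, small_structured):
        F = fst_matrix_estimate(sharing_matrix(small_structured))
        assert abs(F.offdiag().mean()) < 1e-12

    def test_panmictic_pool_fst_near_zero(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(30):
            g = random_genotypes(rng, r=3, n_per_pop=15, L=300, structured=False)
            vals.append(overall_fst_estimate(sharing_matrix(g)))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-4

    def test_pairwise_two_fixed_populations_is_one(self):
        F = pairwise_fst_estimate(sharing_matrix(discussion_genotypes(r=4)))
        assert F[0, 1] == pytest.approx(1.0, abs=1e-15)
        assert np.all(np.diag(F) == 0.0)

    def test_pairwise_same_from_sharing_and_from_fst_matrix(self, small_structured):
        s = sharing_matrix(small_structured)
        np.testing.assert_allclose(
            pairwise_fst_estimate(s),
            pairwise_fst_estimate(fst_matrix_estimate(s)),
            atol=1e-12,
        )


class TestInvariances:
    @given(st.integers(0, 2**31 - 1), st.integers(1, 30))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_monomorphic_loci_change_nothing(self, seed, n_mono):
        """Appending loci fixed across the whole sample rescales both
        numerator and denominator of every ratio estimator equally."""
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, r=3, n_per_pop=5, L=30)
        extended = GenotypeData(
            dosages=np.hstack([g.dosages, np.full((g.n_T, n_mono), 2.0)]),
            sample_ids=g.sample_ids,
            pop_of=g.pop_of,
            ploidy=g.ploidy,
        )
        s0, s1 = sharing_matrix(g), sharing_matrix(extended)
        np.testing.assert_allclose(
            kinship_as(s0).values, kinship_as(s1).values, atol=1e-12
        )
        np.testing.assert_allclose(
            fst_matrix_estimate(s0).values, fst_matrix_estimate(s1).values, atol=1e-12
        )
        np.testing.assert_allclose(
            pairwise_fst_estimate(s0), pairwise_fst_estimate(s1), atol=1e-12
        )
        f0 = individual_fis(s0, g)
        f1 = individual_fis(s1, extended)
        np.testing.assert_allclose(f0[0], f1[0], atol=1e-12)
        assert f0[2] == pytest.approx(f1[2], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_population_label_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, r=4, n_per_pop=5, L=40)
        order = rng.permutation(g.n_T)
        ids = [g.sample_ids[i] for i in order]
        g_perm = GenotypeData(
            dosages=g.dosages[order],
            sample_ids=ids,
            pop_of={s: g.pop_of[s] for s in ids},
            ploidy=g.ploidy,
        )
        F = fst_matrix_estimate(sharing_matrix(g))
        Fp = fst_matrix_estimate(sharing_matrix(g_perm))
        pops, pops_p = sharing_matrix(g).populations, sharing_matrix(g_perm).populations
        reorder = [pops_p.index(p) for p in pops]
        np.testing.assert_allclose(Fp.values[np.ix_(reorder, reorder)], F.values, atol=1e-12)

    def test_subsampling_individuals_barely_moves_estimates(self):
        """Estimates from 5 individuals per population stay close to the
        full-sample estimate relative to locus-resampling noise."""
        from ashfst.evalharness import subsample_individuals, subsample_loci

        rng = np.random.default_rng(99)
        g = random_genotypes(rng, r=4, n_per_pop=30, L=600)
        full = fst_matrix_estimate(sharing_matrix(g)).values
        locus_sd = np.std(
            [
                fst_matrix_estimate(
                    sharing_matrix(subsample_loci(g, 300, seed=k))
                ).values
                for k in range(12)
            ],
            axis=0,
        )
        sub = fst_matrix_estimate(
            sharing_matrix(subsample_individuals(g, 5, seed=0))
        ).values
        # median elementwise deviation below the locus-resampling spread
        dev = np.abs(sub - full)
        assert np.median(dev) < np.median(locus_sd) * 3
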