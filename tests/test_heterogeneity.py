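import numpy as np
import pytest
from scipy import stats

import c3mi as m


def _ds(values, prefix="g"):
    return m.ExpressionDataset(
        tuple(f"{prefix}{i}" for i in range(values.shape[0])), values
    )


class TestNormalityAudit:
    def test_gaussian_profiles_reject_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        pv = m.gene_normality_pvalues(_ds(rng.normal(size=(1000, 500))))
        frac = (pv <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 3 * se

    def test_skewed_profiles_strongly_rejected(self):
        rejected = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            pv = m.gene_normality_pvalues(_ds(rng.exponential(size=(50, 500))))
            rejected.append((pv <= 0.05).mean())
        assert np.median(rejected) > 0.95

    def test_output_length_and_minimum_samples(self):
        rng = np.random.default_rng(1)
        assert m.gene_normality_pvalues(_ds(rng.normal(size=(7, 20)))).shape == (7,)
        with pytest.raises(ValueError):
            m.gene_normality_pvalues(_ds(rng.normal(size=(3, 5))))

    def test_constant_profile_flagged_degenerate(self):
        vals = np.vstack([np.full(50, 2.0), np.random.default_rng(0).normal(size=50)])
        with pytest.warns(UserWarning):
            pv = m.gene_normality_pvalues(_ds(vals))
        assert pv[0] < 1e-100


class TestRejectionFraction:
    def test_extremes(self):
        assert m.rejection_fraction(np.ones(10), 0.05) == 0.0
        assert m.rejection_fraction(np.full(10, 1e-300), 0.05) == 1.0

    def test_bonferroni_hand_threshold(self):
        p = np.array([0.001] + [0.5] * 9)
        assert m.rejection_fraction(p, 0.05, "bonferroni") == pytest.approx(0.1)

    def test_empty_and_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            m.rejection_fraction(np.array([]), 0.05)
        with pytest.raises(ValueError):
            m.rejection_fraction(np.array([0.5]), 1.5)


class TestStouffer:
    def test_neutral_pair(self):
        assert m.combine_pair_pvalues(0.5, 0.5) == pytest.approx(0.5)

    def test_two_significant_pvalues_reinforce(self):
        # z = (1.6449 + 1.6449)/sqrt(2) -> p ≈ 0.0100
        assert m.combine_pair_pvalues(0.05, 0.05) == pytest.approx(0.0100, abs=1e-3)

    def test_opposite_zscores_cancel(self):
        assert m.combine_pair_pvalues(0.025, 0.975) == pytest.approx(0.5, abs=1e-12)

    def test_boundary_values_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            p = m.combine_pair_pvalues(0.0, 0.5)
        assert 0.0 < p < 0.5


class TestPairDistributionTests:
    def test_identical_profiles_not_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        ds = m.ExpressionDataset(("a", "b"), np.vstack([x, x]))
        p = m.pair_distribution_pvalues(ds, [("a", "b")])
        assert p[0] == pytest.approx(1.0)

    def test_disjoint_supports_maximally_rejected(self):
        ds = m.ExpressionDataset(
            ("a", "b"), np.vstack([np.linspace(0, 1, 100), np.linspace(5, 6, 100)])
        )
        assert m.pair_distribution_pvalues(ds, [("a", "b")])[0] < 1e-10

    def test_null_pvalues_approximately_uniform(self):
        """Same-distribution profiles give ~Uniform(0,1) KS p-values."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            ds = m.ExpressionDataset(("a", "b"), rng.normal(size=(2, 500)))
            pvals.append(m.pair_distribution_pvalues(ds, [("a", "b")])[0])
        # profiles long enough that the asymptotic p-value is accurate
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRankAccumulation:
    def test_common_length_is_min(self):
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        pv = [np.array([0.1, 0.2, 0.3, 0.4, 0.5])]
        acc = m.tp_fp_rank_accumulate(
            pv, [{("a", "b"), ("a", "c"), ("a", "d")}], [{("b", "c"), ("b", "d")}], pairs
        )
        assert acc.common_lengths == (2,)
        assert acc.r_tp.sum() == acc.r_fp.sum() == 2

    def test_dataset_without_fp_contributes_nothing(self):
        pairs = [("a", "b"), ("a", "c")]
        acc = m.tp_fp_rank_accumulate(
            [np.array([0.1, 0.9])], [{("a", "b")}], [set()], pairs
        )
        assert acc.r_tp.sum() == 0 and acc.r_fp.sum() == 0

    def test_two_dataset_hand_enumeration(self):
        """Manual walk-through: 5 pairs, 2 datasets, known ranks."""
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        # dataset 1 p-values -> ascending ranks: ab=2, ac=1, ad=4, bc=3, bd=5
        pv1 = np.array([0.2, 0.1, 0.4, 0.3, 0.5])
        tp1 = {("a", "b"), ("a", "c")}  # ranks 2 and 1 -> l=1 keeps rank 1
        fp1 = {("a", "d")}  # rank 4
        # dataset 2: ranks ab=1, ac=2, ad=3, bc=4, bd=5
        pv2 = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        tp2 = {("b", "c")}  # rank 4
        fp2 = {("a", "b"), ("b", "d")}  # ranks 1, 5 -> l=1 keeps rank 1
        acc = m.tp_fp_rank_accumulate([pv1, pv2], [tp1, tp2], [fp1, fp2], pairs)
        assert list(acc.r_tp) == [1, 0, 0, 1, 0]  # ranks 1 and 4
        assert list(acc.r_fp) == [1, 0, 0, 1, 0]  # ranks 4 and 1
        assert acc.common_lengths == (1, 1)

    def test_tp_fp_overlap_rejected(self):
        pairs = [("a", "b"), ("a", "c")]
        with pytest.raises(ValueError):
            m.tp_fp_rank_accumulate(
                [np.array([0.1, 0.2])], [{("a", "b")}], [{("a", "b")}], pairs
            )

    def test_tied_pvalues_ranked_by_first_occurrence(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        acc = m.tp_fp_rank_accumulate(
            [np.array([0.5, 0.5, 0.5])], [{("a", "b")}], [{("b", "c")}], pairs
        )
        assert list(acc.r_tp) == [1, 0, 0]  # first occurrence gets rank 1
        assert list(acc.r_fp) == [0, 0, 1]


class TestEcdf:
    def test_uniform_counts(self):
        pts = m.ecdf_points(np.array([1, 1, 1, 1]))
        assert [f for _, f in pts] == pytest.approx([0.25, 0.5, 0.75, 1.0])

    def test_mass_at_first_rank(self):
        pts = m.ecdf_points(np.array([4, 0, 0, 0]))
        assert [f for _, f in pts] == pytest.approx([1.0, 1.0, 1.0, 1.0])

    def test_final_value_is_one_and_monotone(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 5, 30)
        counts[0] += 1
        fr = [f for _, f in m.ecdf_points(counts)]
        assert fr[-1] == pytest.approx(1.0)
        assert all(b >= a for a, b in zip(fr, fr[1:]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.ecdf_points(np.zeros(5))


class TestHomogeneityDetector:
    def test_iid_genes_reject_pairs_at_nominal_rate(self):
        """With all genes i.i.d. from one distribution, the pairwise KS
        rejection fraction stays near alpha — the homogeneous case."""
        rng = np.random.default_rng(9)
        ds = _ds(rng.normal(size=(40, 150)))
        pairs = m.all_pairs(ds.gene_ids)
        pv = m.pair_distribution_pvalues(ds, pairs)
        frac = m.rejection_fraction(pv, 0.05, "none")
        assert frac < 0.12  # ~alpha; pairs share genes so only loosely bounded
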