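"""Entropy-estimator unit tests against independently coded oracles.

The oracle functions below are literal transcriptions of the defining
formulas (plug-in entropy, Miller–Madow correction, shrinkage intensity,
Dirichlet posterior mean), written without reference to the package
internals, so agreement is a genuine dual-route check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import c3mi as m
from _oracles import (
    LOG2E,
    oracle_empirical,
    oracle_miller_madow,
    oracle_sg,
    oracle_shrink,
    random_tables,
)


# ----------------------------------------------------------------- units
class TestEntropyExamples:
    def test_empirical_uniform_and_degenerate(self):
        assert m.entropy_empirical(np.array([4, 4])) == pytest.approx(1.0)
        assert m.entropy_empirical(np.array([8, 0])) == pytest.approx(0.0)

    def test_empirical_direct_summation_example(self):
        # p = (.1, .2, .3, .4) by direct summation
        expect = oracle_empirical([1, 2, 3, 4])
        assert m.entropy_empirical(np.array([1, 2, 3, 4])) == pytest.approx(
            expect, abs=1e-12
        )
        assert expect == pytest.approx(1.846439, abs=1e-6)

    def test_miller_madow_correction(self):
        assert m.entropy_miller_madow(np.array([8, 0])) == pytest.approx(0.0)
        assert m.entropy_miller_madow(np.array([4, 4])) == pytest.approx(
            1.0 + LOG2E / 16, abs=1e-12
        )

    def test_miller_madow_nominal_bin_variant(self):
        h = m.entropy_miller_madow(np.array([8, 0]), occupied=False)
        assert h == pytest.approx(0.0 + 1 / 16 * LOG2E, abs=1e-12)

    def test_shrink_degenerate_cases(self):
        h, lam = m.entropy_shrink(np.array([4, 4]))
        assert (h, lam) == (pytest.approx(1.0), 1.0)  # target == empirical
        h, lam = m.entropy_shrink(np.array([0, 10]))
        assert (h, lam) == (pytest.approx(0.0), 0.0)  # zero numerator

    def test_shrink_formula_transcription(self):
        h, lam = m.entropy_shrink(np.array([9, 1]))
        h_o, lam_o = oracle_shrink([9, 1])
        assert h == pytest.approx(h_o, abs=1e-12)
        assert lam == pytest.approx(lam_o, abs=1e-12)

    def test_sg_symmetry_and_pseudocounts(self):
        assert m.entropy_sg(np.array([4, 4])) == pytest.approx(1.0)
        assert m.entropy_sg(np.array([8, 0])) == pytest.approx(
            oracle_sg([8, 0]), abs=1e-12
        )

    def test_empty_table_rejected(self):
        for fn in (m.entropy_empirical, m.entropy_miller_madow, m.entropy_sg):
            with pytest.raises(ValueError):
                fn(np.array([0, 0]))
        with pytest.raises(ValueError):
            m.entropy_shrink(np.array([1, 0]))  # N <= 1


class TestEstimatorProperties:
    def test_all_estimators_match_oracles_on_random_tables(self):
        for counts in random_tables():
            assert m.entropy_empirical(counts) == pytest.approx(
                oracle_empirical(counts), abs=1e-12
            )
            assert m.entropy_miller_madow(counts) == pytest.approx(
                oracle_miller_madow(counts), abs=1e-12
            )
            h, lam = m.entropy_shrink(counts)
            h_o, lam_o = oracle_shrink(counts)
            assert h == pytest.approx(h_o, abs=1e-12)
            assert lam == pytest.approx(lam_o, abs=1e-12)
            assert m.entropy_sg(counts) == pytest.approx(oracle_sg(counts), abs=1e-12)

    def test_miller_madow_never_below_empirical(self):
        for counts in random_tables(seed=99):
            assert m.entropy_miller_madow(counts) >= m.entropy_empirical(counts)

    def test_large_sample_estimators_approach_empirical(self):
        """Scaling a fixed table up to N = 1e6 shrinks the corrections away."""
        base = np.array([3, 1, 5, 2])
        big = base * 100_000  # N = 1.1e6
        h_emp = m.entropy_empirical(big)
        assert abs(m.entropy_shrink(big)[0] - h_emp) < 1e-3
        assert abs(m.entropy_sg(big) - h_emp) < 1e-3
        assert abs(m.entropy_miller_madow(big) - h_emp) < 1e-3


class TestMutualInformation:
    def test_identical_vectors_give_marginal_entropy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        s = m.BinningScheme("equal_frequency", 5)
        lab = m.discretize_pair(x, x, s)[0]
        h = m.entropy_empirical(np.bincount(lab, minlength=6)[1:])
        assert m.mutual_information(x, x, "empirical", s) == pytest.approx(h, abs=1e-12)

    def test_independent_profiles_near_zero(self):
        """Positive plug-in bias is O(B²/N); tiny at B = 10, N = 10000."""
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        mi = m.mutual_information(x, y, "empirical", m.BinningScheme("equal_width", 10))
        assert 0 <= mi < 0.05

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=60), rng.exponential(size=60)
        for method in ("equal_frequency", "equal_width", "global_equal_width"):
            s = m.BinningScheme(method, 4)
            for est in m.ESTIMATORS:
                assert m.mutual_information(x, y, est, s) == pytest.approx(
                    m.mutual_information(y, x, est, s), abs=1e-12
                )

    def test_empirical_mi_nonnegative(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=40), rng.normal(size=40)
            mi = m.mutual_information(x, y, "empirical", m.BinningScheme("equal_width", 5))
            assert mi >= -1e-12


class TestMIMatrix:
    def test_symmetric_zero_diagonal(self):
        cfg = m.SimulationConfig(5, 0.3, 36, n_datasets=1, seed=4)
        _, (ds,) = m.generate_ensemble(cfg)
        mm = m.mi_matrix(ds, "empirical", m.scheme_for("equal_width", 36))
        assert np.array_equal(mm.values, mm.values.T)
        assert np.all(np.diag(mm.values) == 0)

    def test_entries_match_pairwise_calls(self):
        cfg = m.SimulationConfig(4, 0.5, 25, n_datasets=1, seed=9)
        _, (ds,) = m.generate_ensemble(cfg)
        s = m.scheme_for("global_equal_width", 25)
        mm = m.mi_matrix(ds, "shrink", s)
        for i in range(4):
            for j in range(i + 1, 4):
                direct = m.mutual_information(ds.values[i], ds.values[j], "shrink", s)
                assert mm.values[i, j] == pytest.approx(direct, abs=1e-12)

    def test_duplicated_gene_rows_maximize_their_pair(self):
        """A duplicated profile has maximal empirical MI among its row."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        vals = np.vstack([x, x, rng.normal(size=100), rng.normal(size=100)])
        ds = m.ExpressionDataset(("g1", "g2", "g3", "g4"), vals)
        mm = m.mi_matrix(ds, "empirical", m.BinningScheme("equal_frequency", 5))
        assert mm.values[0, 1] == pytest.approx(np.max(mm.values[0]), abs=1e-12)

    def test_mi_matrix_tsv_roundtrip(self, tmp_path):
        cfg = m.SimulationConfig(3, 0.5, 16, n_datasets=1, seed=1)
        _, (ds,) = m.generate_ensemble(cfg)
        mm = m.mi_matrix(ds, "empirical", m.scheme_for("equal_width", 16))
        mm.to_tsv(tmp_path / "mi.tsv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "mi.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), mm.values, atol=1e-9)
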