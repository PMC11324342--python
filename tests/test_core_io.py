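import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from methylboost.core_io import (BetaMatrix, BetaMatrixError, SampleSheet,
                                 benjamini_hochberg, chisq_2x2, mann_whitney,
                                 read_beta_matrix, spearman,
                                 write_beta_matrix)


def bh_bruteforce(p):
    """Literal step-up definition: adj_i = min over p_(j) >= p_(i) of
    m*p_(j)/rank_j, clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    for i in range(m):
        candidates = [m * ranked[j] / (j + 1) for j in range(i, m)]
        adj[i] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj
    return out


class TestBetaMatrixIO:
    def test_round_trip_tsv(self, small_beta, tmp_path):
        path = tmp_path / "beta.tsv"
        write_beta_matrix(small_beta, path, precision=6)
        back = read_beta_matrix(path)
        assert back.probe_ids == small_beta.probe_ids
        assert back.sample_ids == small_beta.sample_ids
        np.testing.assert_allclose(back.values, small_beta.values,
                                   atol=5e-7)

    @given(arrays(np.float64, (4, 3),
                  elements=st.floats(0, 1, allow_nan=False)))
    def test_round_trip_random_matrices(self, tmp_path_factory, values):
        m = BetaMatrix(pd.DataFrame(values,
                                    index=[f"p{i}" for i in range(4)],
                                    columns=[f"s{i}" for i in range(3)]))
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_beta_matrix(m, path, precision=8)
        np.testing.assert_allclose(read_beta_matrix(path).values, values,
                                   atol=5e-9)

    def test_out_of_range_value_names_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\tsampA\tsampB\ncg1\t0.5\t1.2\n"
                        "cg2\t0.1\t0.2\ncg3\t0.3\t0.4\n")
        with pytest.raises(BetaMatrixError, match="cg1.*sampB"):
            read_beta_matrix(path)

    def test_non_numeric_cell_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ncg1\toops\n")
        with pytest.raises(BetaMatrixError, match="cg1"):
            read_beta_matrix(path)

    def test_duplicate_probe_ids_rejected(self):
        df = pd.DataFrame([[0.1], [0.2]], index=["cg1", "cg1"],
                          columns=["s1"])
        with pytest.raises(BetaMatrixError, match="duplicate"):
            BetaMatrix(df)

    def test_na_values_allowed_and_round_trip(self, tmp_path):
        df = pd.DataFrame([[0.1, np.nan], [0.4, 0.5]],
                          index=["cg1", "cg2"], columns=["s1", "s2"])
        m = BetaMatrix(df)
        path = tmp_path / "na.tsv"
        write_beta_matrix(m, path)
        back = read_beta_matrix(path)
        assert np.isnan(back.values[0, 1])
        assert m.drop_incomplete_probes().probe_ids == ["cg2"]


class TestSampleSheet:
    def test_label_must_be_stable_within_subject(self):
        df = pd.DataFrame({
            "sample_id": ["a_T1", "a_T2"], "subject_id": ["a", "a"],
            "timepoint": ["T1", "T2"], "response": ["R", "NR"]})
        with pytest.raises(ValueError, match="response label"):
            SampleSheet(df)

    def test_binary_labels(self):
        df = pd.DataFrame({
            "sample_id": ["a_T1", "b_T1"], "subject_id": ["a", "b"],
            "timepoint": ["T1", "T1"], "response": ["R", "NR"]})
        sheet = SampleSheet(df)
        np.testing.assert_array_equal(
            sheet.labels_for(["b_T1", "a_T1"]), [0, 1])


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.5]), [0.5])

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 25))
            np.testing.assert_allclose(benjamini_hochberg(p),
                                       bh_bruteforce(p), atol=1e-12)

    @given(arrays(np.float64, st.integers(1, 30),
                  elements=st.floats(0, 1, allow_nan=False)))
    def test_adjusted_dominates_raw_and_preserves_order(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestChisq:
    def test_cohort_sex_distribution(self):
        # 8/16 female responders vs 10/15 female non-responders
        stat, p = chisq_2x2([[8, 8], [10, 5]])
        assert p == pytest.approx(0.35, abs=0.005)

    def test_prior_vedolizumab_distribution(self):
        stat, p = chisq_2x2([[10, 6], [4, 11]])
        assert p == pytest.approx(0.05, abs=0.005)

    def test_homogeneous_table(self):
        stat, p = chisq_2x2([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = rng.integers(1, 40, size=(2, 2))
            stat, _ = chisq_2x2(t)
            n = t.sum()
            expected = np.outer(t.sum(1), t.sum(0)) / n
            assert stat == pytest.approx(
                ((t - expected) ** 2 / expected).sum(), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2([[0, 0], [3, 4]])


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p, _ = mann_whitney([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_groups_exact(self):
        # all 20 assignments of ranks enumerate to p = 2/20
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(3, 1, 60)
        _, p, method = mann_whitney(x, y)
        assert method == "asymptotic"
        assert p < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    @pytest.mark.parametrize("y, expected", [
        ([1, 2, 3, 4], 1.0),
        ([-1, -2, -3, -4], -1.0),
        ([1, 3, 2, 4], 0.8),  # hand rank computation: 1 - 6*2/(4*15)
    ])
    def test_known_rank_correlations(self, y, expected):
        assert spearman([1, 2, 3, 4], y) == pytest.approx(expected)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])
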