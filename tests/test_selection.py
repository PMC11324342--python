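import numpy as np
import pandas as pd
import pytest

from methylboost.core_io import BetaMatrix
from methylboost.selection import (SelectionConfig, aggregate_and_select,
                                   shadow_threshold, single_repeat,
                                   stability_select)

FAST = dict(n_outer_repeats=8, n_trees=60, use_cv_early_stopping=False)


def toy_problem(seed=0, n_probes=300, separator=True):
    """Small cohort with one perfectly separating probe among noise."""
    rng = np.random.default_rng(seed)
    n = 30
    y = np.array([1] * 15 + [0] * 15)
    X = rng.uniform(0.2, 0.8, size=(n, n_probes))
    if separator:
        X[:, 0] = np.where(y == 1, rng.uniform(0.7, 0.9, n),
                           rng.uniform(0.1, 0.3, n))
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    beta = BetaMatrix(pd.DataFrame(X.T, index=probes,
                                   columns=[f"s{i}_T1" for i in range(n)]))
    return beta, y, probes


class TestSingleRepeat:
    def test_separating_probe_ranked_first(self):
        beta, y, probes = toy_problem(seed=1)
        X = beta.data.sort_index().to_numpy().T
        cfg = SelectionConfig(seed=0, **FAST)
        firsts = 0
        for r in range(20):
            imp, auroc, _ = single_repeat(X, y, cfg, 1000 + r)
            firsts += int(np.argmax(imp) == 0)
        assert firsts >= 19

    def test_null_test_auroc_centred_at_half(self):
        # chance correlation in any one fixed dataset biases its expected
        # AUROC, so the null centring holds across fresh datasets
        cfg = SelectionConfig(seed=0, **FAST)
        aurocs = []
        for s in range(15):
            beta, y, _ = toy_problem(seed=100 + s, separator=False)
            X = beta.data.to_numpy().T
            aurocs.append(single_repeat(X, y, cfg, 5000 + s)[1])
        assert abs(np.mean(aurocs) - 0.5) < 0.12

    def test_deterministic_given_data_and_seed(self):
        beta, y, _ = toy_problem(seed=3)
        X = beta.data.to_numpy().T
        cfg = SelectionConfig(seed=0, **FAST)
        a = single_repeat(X, y, cfg, 42)
        b = single_repeat(X, y, cfg, 42)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(5, 10))
        with pytest.raises(ValueError, match="per class"):
            single_repeat(X, np.array([1, 0, 0, 0, 0]),
                          SelectionConfig(seed=0), 1)


class TestShadowThreshold:
    def test_shadow_of_constant_column_has_zero_importance(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.full(30, 0.5),
                             rng.uniform(size=(30, 20)).reshape(30, 20)])
        X = X[:, :2]  # constant + one noise feature
        y = np.array([1] * 15 + [0] * 15)
        cfg = SelectionConfig(seed=0, n_outer_repeats=4, n_trees=20,
                              use_cv_early_stopping=False,
                              shadow_protocol="complement", shadow_fits=4)
        out = shadow_threshold(X, y, cfg, rounds=20)
        # the first shadow is a permutation of the constant column
        assert np.all(out[0] == 0.0)

    def test_single_protocol_shape_and_range(self):
        beta, y, _ = toy_problem(seed=5, n_probes=40)
        X = beta.data.to_numpy().T
        cfg = SelectionConfig(seed=1, n_outer_repeats=5, n_trees=20,
                              use_cv_early_stopping=False,
                              shadow_protocol="single", n_permutations=60,
                              shadow_groups=12)
        out = shadow_threshold(X, y, cfg, rounds=20)
        assert out.shape == (12, 5)
        assert np.all((out >= 0) & (out <= 1))


class TestAggregation:
    def test_unanimous_ordering_is_preserved(self):
        per_repeat = np.tile([0.9, 0.5, 0.1], (6, 1))
        shadows = np.zeros((4, 3))
        res = aggregate_and_select(["a", "b", "c"], per_repeat, shadows,
                                   np.full(6, 0.7),
                                   SelectionConfig(seed=0, n_outer_repeats=6))
        assert res.ranking["probe_id"].tolist() == ["a", "b", "c"]

    def test_consistency_beats_sporadic_magnitude(self):
        # probe a: 1.0 in one repeat of 100; probe b: 0.5 in all repeats
        per_repeat = np.zeros((100, 2))
        per_repeat[0, 0] = 1.0
        per_repeat[:, 1] = 0.5
        res = aggregate_and_select(["a", "b"], per_repeat,
                                   np.zeros((4, 3)), np.full(100, 0.6),
                                   SelectionConfig(seed=0,
                                                   n_outer_repeats=100))
        imp = dict(zip(res.ranking["probe_id"], res.ranking["importance"]))
        assert imp["b"] > imp["a"]

    def test_bar_is_max_of_shadow_aggregates(self):
        shadows = np.array([[0.0, 0.2], [0.4, 0.0], [0.0, 0.0]])
        res = aggregate_and_select(["a"], np.zeros((2, 1)), shadows,
                                   np.full(2, 0.5),
                                   SelectionConfig(seed=0,
                                                   n_outer_repeats=2))
        assert res.shadow_bar == pytest.approx(0.2)
        assert res.predictor_set == []


class TestStabilitySelect:
    def test_end_to_end_determinism(self):
        beta, y, _ = toy_problem(seed=6, n_probes=80)
        cfg = SelectionConfig(seed=7, n_outer_repeats=4, n_trees=30,
                              use_cv_early_stopping=False, shadow_fits=4)
        a = stability_select(beta, y, cfg)
        b = stability_select(beta, y, cfg)
        assert a.predictor_set == b.predictor_set
        assert a.shadow_bar == b.shadow_bar
        pd.testing.assert_frame_equal(a.ranking, b.ranking)

    def test_invariant_to_probe_row_order(self):
        beta, y, _ = toy_problem(seed=8, n_probes=60)
        cfg = SelectionConfig(seed=9, n_outer_repeats=4, n_trees=30,
                              use_cv_early_stopping=False, shadow_fits=4)
        shuffled = BetaMatrix(beta.data.sample(frac=1.0, random_state=3))
        a = stability_select(beta, y, cfg)
        b = stability_select(shuffled, y, cfg)
        assert a.predictor_set == b.predictor_set
        pd.testing.assert_frame_equal(a.ranking, b.ranking)

    def test_separator_is_selected(self):
        beta, y, _ = toy_problem(seed=10, n_probes=150)
        cfg = SelectionConfig(seed=11, n_outer_repeats=8, n_trees=40,
                              use_cv_early_stopping=False, shadow_fits=8)
        res = stability_select(beta, y, cfg)
        assert "cg00000000" in res.predictor_set
        assert res.ranking.iloc[0]["probe_id"] == "cg00000000"

    def test_m_value_scale_selects_the_separator_too(self):
        beta, y, _ = toy_problem(seed=14, n_probes=100)
        cfg = SelectionConfig(seed=15, n_outer_repeats=6, n_trees=40,
                              use_cv_early_stopping=False, shadow_fits=6,
                              feature_scale="m")
        res = stability_select(beta, y, cfg)
        assert res.ranking.iloc[0]["probe_id"] == "cg00000000"

    def test_probes_with_missing_values_are_excluded(self):
        beta, y, probes = toy_problem(seed=12, n_probes=50)
        data = beta.data.copy()
        data.iloc[5, 0] = np.nan
        cfg = SelectionConfig(seed=13, n_outer_repeats=3, n_trees=20,
                              use_cv_early_stopping=False, shadow_fits=3)
        res = stability_select(BetaMatrix(data), y, cfg)
        assert probes[5] not in set(res.ranking["probe_id"])
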