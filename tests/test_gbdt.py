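"""Boosted-tree correctness: oracle split search, closed forms, metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatgpc.gbdt import (EvalMetrics, evaluate, feature_importance,
                           fit_cart, fit_gbdt, load_model, predict_gbdt,
                           predict_tree, save_model, split_train_test)


def brute_force_best_split(X, y, min_leaf=1):
    """Independent oracle: enumerate every (feature, midpoint) candidate and
    return the SSE-minimizing split with (feature, threshold)-ascending
    tie-breaks, or None when no split reduces SSE."""
    n, p = X.shape
    sse = lambda v: float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0
    parent = sse(y)
    best = None
    for j in range(p):
        for thr in [(a + b) / 2 for a, b in
                    itertools.pairwise(sorted(set(X[:, j])))]:
            mask = X[:, j] <= thr
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            gain = parent - sse(y[mask]) - sse(y[~mask])
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, j, thr)
    return None if best is None else (best[1], best[2])


class TestFitCart:
    def test_constant_response_is_single_leaf(self):
        t = fit_cart(np.arange(8.0).reshape(-1, 1), np.full(8, 3.0))
        assert t.root.is_leaf
        assert t.root.value == 3.0

    def test_step_function_split_at_midpoint(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        t = fit_cart(X, y, max_depth=1)
        assert t.root.threshold == 1.5
        assert t.root.left.value == 0.0
        assert t.root.right.value == 10.0
        # training SSE zero
        assert np.allclose(t.predict(X), y)

    def test_tie_breaks_lower_feature_then_lower_threshold(self):
        # feature 1 duplicates feature 0 -> identical gains; symmetric y
        # gives two equally good thresholds within a feature
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0.0, 10.0, 0.0, 10.0])
        t = fit_cart(X, y, max_depth=1)
        assert t.root.feature == 0
        oracle = brute_force_best_split(X, y)
        assert (t.root.feature, t.root.threshold) == oracle

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_split_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        p = data.draw(st.integers(1, 3))
        X = np.array(data.draw(st.lists(
            st.lists(st.integers(-5, 5), min_size=p, max_size=p),
            min_size=n, max_size=n)), dtype=float)
        y = np.array(data.draw(st.lists(st.integers(-10, 10),
                                        min_size=n, max_size=n)), dtype=float)
        t = fit_cart(X, y, max_depth=1, min_leaf=1)
        oracle = brute_force_best_split(X, y)
        if oracle is None:
            assert t.root.is_leaf
        else:
            assert (t.root.feature, t.root.threshold) == oracle

    def test_min_leaf_respected(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.array([0.0] * 1 + [10.0] * 9)
        t = fit_cart(X, y, max_depth=1, min_leaf=3)
        # best unrestricted split (0.5) is forbidden; both leaves >= 3
        assert t.root.threshold >= 2.5

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fit_cart(np.array([[np.nan]]), np.array([1.0]))


class TestPredictTree:
    def test_boundary_routes_left(self):
        t = fit_cart(np.array([[0.0], [1.0], [2.0], [3.0]]),
                     np.array([0.0, 0.0, 10.0, 10.0]), max_depth=1)
        assert predict_tree(t, np.array([1.5])) == 0.0
        assert predict_tree(t, np.array([3.0])) == 10.0
        assert predict_tree(t, np.array([-99.0])) == 0.0


class TestFitGbdt:
    def test_zero_trees_predicts_mean(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        m = fit_gbdt(X, y, n_trees=0)
        assert np.allclose(m.predict(X), 3.5)

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_two_sample_geometric_recursion_closed_form(self, k):
        """With two distinct samples, depth-1 trees and alpha = 0.5, round k
        predicts ybar + (1 - 0.5^k) (y_i - ybar)."""
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 4.0])
        m = fit_gbdt(X, y, n_trees=k, learning_rate=0.5, max_depth=1,
                     min_leaf=1)
        expected = y.mean() + (1 - 0.5 ** k) * (y - y.mean())
        np.testing.assert_allclose(m.predict(X), expected, atol=1e-12)

    def test_one_deep_tree_interpolates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 1))
        y = rng.normal(size=8)
        # greedy trees are not balanced: allow up to n-1 levels
        m = fit_gbdt(X, y, n_trees=1, learning_rate=1.0, max_depth=8,
                     min_leaf=1)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-12)

    def test_training_sse_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        m = fit_gbdt(X, y, n_trees=30, learning_rate=0.3, max_depth=2,
                     min_leaf=2)
        pred = np.full(40, m.init_value)
        sses = [float(((y - pred) ** 2).sum())]
        for tree in m.trees:
            pred = pred + m.learning_rate * tree.predict(X)
            sses.append(float(((y - pred) ** 2).sum()))
        assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))

    def test_invalid_hyperparameters(self):
        X, y = np.zeros((3, 1)), np.zeros(3)
        with pytest.raises(ValueError):
            fit_gbdt(X, y, learning_rate=0.0)
        with pytest.raises(ValueError):
            fit_gbdt(X, y, n_trees=-1)

    def test_prediction_permutation_invariant_over_rows(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        m = fit_gbdt(X, y, n_trees=5)
        perm = rng.permutation(10)
        Xq = rng.normal(size=(10, 2))
        np.testing.assert_allclose(m.predict(Xq)[perm], m.predict(Xq[perm]))


class TestFeatureImportance:
    def test_single_informative_feature_takes_all(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.repeat([0.0, 1.0], 10), np.zeros(20)])
        y = np.repeat([0.0, 5.0], 10)
        m = fit_gbdt(X, y, n_trees=10, min_leaf=1)
        imp = feature_importance(m)
        assert imp.iloc[0] == pytest.approx(1.0)
        assert imp.sum() == pytest.approx(1.0)

    def test_normalization_for_any_fitted_model(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        imp = feature_importance(fit_gbdt(X, y, n_trees=20))
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()

    def test_no_split_model_warns_all_zero(self):
        m = fit_gbdt(np.zeros((4, 2)), np.full(4, 2.0), n_trees=3)
        with pytest.warns(UserWarning):
            imp = feature_importance(m)
        assert (imp == 0).all()

    def test_signal_beats_noise_in_seeded_monte_carlo(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x0 = rng.uniform(size=60)
            x1 = rng.uniform(size=60)
            y = (x0 > 0.5).astype(float) + rng.normal(0, 0.3, 60)
            m = fit_gbdt(np.column_stack([x0, x1]), y, n_trees=50)
            imp = feature_importance(m)
            wins += imp.iloc[0] > imp.iloc[1]
        assert wins >= 95

    def test_sklearn_cross_check_on_synthetic_dataset(self):
        """Identically configured scikit-learn gradient boosting must agree:
        same top-3 importance ranking, near-identical prediction means."""
        from sklearn.ensemble import GradientBoostingRegressor
        from wheatgpc.features import FEATURE_COLUMNS
        from wheatgpc.pipeline import build_feature_table
        from wheatgpc.synthetic import generate_dataset
        sites, weather, gpc = generate_dataset(40, [2015, 2016, 2017, 2018],
                                               3, seed=0)
        table = build_feature_table(weather, sites, gpc)
        X, y = table[FEATURE_COLUMNS], table["gpc_pct"]
        ours = fit_gbdt(X, y, n_trees=100, learning_rate=0.1, max_depth=3,
                        min_leaf=5)
        ref = GradientBoostingRegressor(
            n_estimators=100, learning_rate=0.1, max_depth=3,
            min_samples_leaf=5, random_state=0)
        ref.fit(X, y)
        np.testing.assert_allclose(ours.predict(X).mean(),
                                   ref.predict(X).mean(), rtol=1e-6)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X),
                                   atol=0.05)
        ours_rank = list(feature_importance(ours)
                         .sort_values(ascending=False).index[:3])
        ref_rank = list(pd.Series(ref.feature_importances_,
                                  index=FEATURE_COLUMNS)
                        .sort_values(ascending=False).index[:3])
        assert ours_rank == ref_rank


class TestSplitTrainTest:
    def test_sizes_and_exhaustive_disjoint_union(self):
        df = pd.DataFrame({"a": range(10)})
        tr, te = split_train_test(df, seed=0)
        assert (len(tr), len(te)) == (8, 2)
        assert sorted(pd.concat([tr, te])["a"]) == list(range(10))

    def test_seeded_reproducibility(self):
        df = pd.DataFrame({"a": range(20)})
        tr1, _ = split_train_test(df, seed=4)
        tr2, _ = split_train_test(df, seed=4)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(pd.DataFrame({"a": [1]}))


class TestEvaluate:
    def _model_predicting(self, values):
        # n_trees=0 model with chosen constant via init_value
        m = fit_gbdt(np.zeros((2, 1)), np.asarray(values, dtype=float),
                     n_trees=0)
        return m

    def test_hand_arithmetic(self):
        obs = np.array([14.0, 15.0])
        # model predicting (14.5, 15.5): one interpolating depth-1 tree
        m2 = fit_gbdt(np.array([[0.0], [1.0]]), np.array([14.5, 15.5]),
                      n_trees=1, learning_rate=1.0, max_depth=1, min_leaf=1)
        met2 = evaluate(m2, np.array([[0.0], [1.0]]), obs)
        assert met2.mae == pytest.approx(0.5)
        assert met2.accuracy_at_tolerance[0.6] == 1.0
        assert met2.accuracy_at_tolerance[0.3] == 0.0

    def test_perfect_and_mean_predictions(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 3.0])
        perfect = fit_gbdt(X, y, n_trees=1, learning_rate=1.0, max_depth=2,
                           min_leaf=1)
        met = evaluate(perfect, X, y)
        assert met.r_squared == pytest.approx(1.0)
        assert met.mae == pytest.approx(0.0)
        assert all(v == 1.0 for v in met.accuracy_at_tolerance.values())
        mean_only = fit_gbdt(X, y, n_trees=0)
        assert evaluate(mean_only, X, y).r_squared == pytest.approx(0.0)

    def test_zero_variance_test_response_reported_as_undefined(self):
        m = fit_gbdt(np.zeros((2, 1)), np.array([1.0, 2.0]), n_trees=0)
        met = evaluate(m, np.zeros((2, 1)), np.array([2.0, 2.0]))
        assert met.r_squared is None

    def test_accuracy_nonincreasing_as_tolerance_shrinks(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        m = fit_gbdt(X, y, n_trees=10)
        met = evaluate(m, X, y, tolerances=(0.1, 0.2, 0.5, 1.0))
        accs = [met.accuracy_at_tolerance[t] for t in (0.1, 0.2, 0.5, 1.0)]
        assert accs == sorted(accs)


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    y = rng.normal(size=30)
    m = fit_gbdt(X, y, n_trees=7)
    path = tmp_path / "model.json"
    save_model(m, path)
    m2 = load_model(path)
    np.testing.assert_allclose(m.predict(X), m2.predict(X))
    assert m2.feature_names == ["a", "b", "c"]
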