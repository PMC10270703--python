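"""Squared-loss gradient-boosted regression trees, written from first principles.

The model is the forward-stagewise additive expansion

    f_0(x) = mean(y),    f_k(x) = f_{k-1}(x) + alpha * T_k(x),

where each T_k is a CART regression tree fit to the current residuals
(the negative gradient of the squared loss) and alpha is the learning
rate. Trees are grown greedily: at every node the (feature, threshold)
pair maximizing the reduction in residual sum of squares is chosen, with
candidate thresholds at midpoints of consecutive sorted unique feature
values; ``x <= threshold`` routes left. Ties in reduction break by lowest
feature index, then lowest threshold, so fits are fully deterministic.

Feature importance is the impurity-based (Gini) importance: the SSE
reduction of every split, summed per feature within a tree, averaged
over trees, and normalized to sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "RegressionTree", "BoostedModel", "EvalMetrics",
           "fit_cart", "predict_tree", "fit_gbdt", "predict_gbdt",
           "feature_importance", "split_train_test", "evaluate",
           "save_model", "load_model"]

# gains at or below this are treated as zero (guards fp noise on constant y)
_MIN_GAIN = 1e-12


@dataclass
class TreeNode:
    """Internal split node or leaf of a regression tree.

    Leaves have ``feature is None`` and carry ``value`` (the mean response
    of their training samples); internal nodes carry the split
    ``(feature, threshold)``, the SSE reduction ``gain`` achieved by the
    split, and two children.
    """

    value: float
    feature: int | None = None
    threshold: float = np.nan
    gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: TreeNode
    max_depth: int
    min_leaf: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([predict_tree(self, x) for x in np.atleast_2d(X)])

    def feature_gains(self, n_features: int) -> np.ndarray:
        """Summed SSE reduction per feature over this tree's splits."""
        gains = np.zeros(n_features)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                gains[node.feature] += node.gain
                stack.extend([node.left, node.right])
        return gains


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int
                ) -> tuple[float, int, float] | None:
    """Exhaustive best (gain, feature, threshold); None when no split helps.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values. Both children must keep at least ``min_leaf`` samples. Ties
    resolve to the lowest feature index, then the lowest threshold (the
    scan order, kept by strict improvement comparisons).
    """
    n, p = X.shape
    if n < 2 * min_leaf:
        return None
    sse_parent = float(((y - y.mean()) ** 2).sum())
    best: tuple[float, int, float] | None = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cs = np.cumsum(ys)
        css = np.cumsum(ys * ys)
        total, total_sq = cs[-1], css[-1]
        # split after position i: left = ys[:i+1], right = ys[i+1:]
        i = np.arange(min_leaf - 1, n - min_leaf)
        valid = xs[i + 1] > xs[i]
        i = i[valid]
        if i.size == 0:
            continue
        n_left = i + 1.0
        n_right = n - n_left
        sse_left = css[i] - cs[i] ** 2 / n_left
        sse_right = (total_sq - css[i]) - (total - cs[i]) ** 2 / n_right
        gains = sse_parent - (sse_left + sse_right)
        k = int(np.argmax(gains))  # first max -> lowest threshold
        if gains[k] > _MIN_GAIN and (best is None or gains[k] > best[0]):
            thr = float((xs[i[k]] + xs[i[k] + 1]) / 2.0)
            best = (float(gains[k]), j, thr)
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int,
          min_leaf: int) -> TreeNode:
    node = TreeNode(value=float(y.mean()))
    if depth >= max_depth:
        return node
    found = _best_split(X, y, min_leaf)
    if found is None:
        return node
    gain, j, thr = found
    mask = X[:, j] <= thr
    node.feature, node.threshold, node.gain = j, thr, gain
    node.left = _grow(X[mask], y[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf)
    return node


def fit_cart(X: np.ndarray, y: np.ndarray, max_depth: int = 3,
             min_leaf: int = 1) -> RegressionTree:
    """Grow one greedy least-squares regression tree."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be 2-D with one row per response value")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in training data")
    return RegressionTree(_grow(X, y, 0, max_depth, min_leaf),
                          max_depth, min_leaf)


def predict_tree(tree: RegressionTree, x: np.ndarray) -> float:
    """Route one sample down the tree; ``x <= threshold`` goes left."""
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    return node.value


@dataclass
class BoostedModel:
    """Initial constant plus a shrunken sum of regression trees."""

    init_value: float
    trees: list[RegressionTree]
    learning_rate: float
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X) -> np.ndarray:
        return predict_gbdt(self, X)


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return X[feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names and X.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {X.shape[1]}")
    return X


def fit_gbdt(X, y, n_trees: int = 100, learning_rate: float = 0.1,
             max_depth: int = 3, min_leaf: int = 5,
             feature_names: list[str] | None = None) -> BoostedModel:
    """Fit the boosted ensemble by residual fitting.

    ``X`` may be a DataFrame (column names become the model's feature
    names) or an array. Training SSE is non-increasing over rounds for any
    learning rate in (0, 1].
    """
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    if not 0.0 < learning_rate <= 1.0:
        raise ValueError("learning_rate must be in (0, 1]")
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        feature_names = feature_names or [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ValueError("NaN in training data")
    init = float(y.mean())
    pred = np.full(len(y), init)
    trees: list[RegressionTree] = []
    for _ in range(n_trees):
        tree = fit_cart(Xm, y - pred, max_depth=max_depth, min_leaf=min_leaf)
        pred = pred + learning_rate * tree.predict(Xm)
        trees.append(tree)
    return BoostedModel(init, trees, learning_rate, feature_names)


def predict_gbdt(model: BoostedModel, X) -> np.ndarray:
    """init + alpha * sum of tree outputs, per row."""
    Xm = _as_matrix(X, model.feature_names)
    pred = np.full(len(Xm), model.init_value)
    for tree in model.trees:
        pred = pred + model.learning_rate * tree.predict(Xm)
    return pred


def feature_importance(model: BoostedModel) -> pd.Series:
    """Normalized impurity importance: mean per-tree SSE reduction, per feature.

    Sums to one whenever any split exists; a split-free model yields an
    all-zero table with a warning.
    """
    p = len(model.feature_names)
    gains = np.zeros(p)
    for tree in model.trees:
        gains += tree.feature_gains(p)
    if model.n_trees:
        gains /= model.n_trees
    total = gains.sum()
    if total <= 0:
        warnings.warn("model contains no splits; importance is all zero",
                      stacklevel=2)
        values = gains
    else:
        values = gains / total
    return pd.Series(values, index=model.feature_names, name="importance")


def split_train_test(table: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split; train size = round(train_fraction * n)."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = table.iloc[perm[:n_train]].reset_index(drop=True)
    test = table.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


@dataclass
class EvalMetrics:
    """Regression metrics on a held-out set.

    ``r_squared`` is 1 − SSE/SST about the test mean (None when the test
    response has zero variance); ``accuracy_at_tolerance`` maps a
    permissible absolute error (in response units) to the fraction of test
    samples predicted within it.
    """

    r_squared: float | None
    mae: float
    accuracy_at_tolerance: dict[float, float]
    predicted_mean: float
    predicted_sd: float
    observed_mean: float
    observed_sd: float
    n_test: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["accuracy_at_tolerance"] = {str(k): v for k, v
                                      in self.accuracy_at_tolerance.items()}
        return d


def evaluate(model: BoostedModel, X_test, y_test,
             tolerances: tuple[float, ...] = (0.3, 0.6)) -> EvalMetrics:
    """Compute R², MAE and permissible-error accuracy on a test set."""
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = predict_gbdt(model, X_test)
    err = pred - y_test
    sst = float(((y_test - y_test.mean()) ** 2).sum())
    r2 = None if sst == 0 else 1.0 - float((err ** 2).sum()) / sst
    return EvalMetrics(
        r_squared=r2,
        mae=float(np.abs(err).mean()),
        accuracy_at_tolerance={t: float((np.abs(err) <= t).mean())
                               for t in tolerances},
        predicted_mean=float(pred.mean()),
        predicted_sd=float(pred.std(ddof=1)) if len(pred) > 1 else 0.0,
        observed_mean=float(y_test.mean()),
        observed_sd=float(y_test.std(ddof=1)) if len(y_test) > 1 else 0.0,
        n_test=len(y_test),
    )


# -- JSON (de)serialization -------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"value": node.value}
    return {"value": node.value, "feature": node.feature,
            "threshold": node.threshold, "gain": node.gain,
            "left": _node_to_dict(node.left),
            "right": _node_to_dict(node.right)}


def _node_from_dict(d: dict) -> TreeNode:
    if "feature" not in d:
        return TreeNode(value=d["value"])
    return TreeNode(value=d["value"], feature=d["feature"],
                    threshold=d["threshold"], gain=d["gain"],
                    left=_node_from_dict(d["left"]),
                    right=_node_from_dict(d["right"]))


def save_model(model: BoostedModel, path) -> None:
    doc = {
        "model": "gbdt-squared-loss",
        "init_value": model.init_value,
        "learning_rate": model.learning_rate,
        "feature_names": model.feature_names,
        "trees": [{"max_depth": t.max_depth, "min_leaf": t.min_leaf,
                   "root": _node_to_dict(t.root)} for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> BoostedModel:
    with open(path) as fh:
        doc = json.load(fh)
    trees = [RegressionTree(_node_from_dict(t["root"]), t["max_depth"],
                            t["min_leaf"]) for t in doc["trees"]]
    return BoostedModel(doc["init_value"], trees, doc["learning_rate"],
                        doc["feature_names"])
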