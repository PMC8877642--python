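"""Path-dependent TreeSHAP for scikit-learn decision trees and ensembles.

Computes exact Shapley attributions for a tree's prediction under the
conditional-expectation value function estimated from the tree itself:
a feature absent from a coalition is marginalized by descending both
children weighted by their training cover. This is the polynomial-time
path algorithm that tracks, along each root-leaf path, the proportion of
all feature subsets flowing down the path for each path feature.

LightGBM and XGBoost models carry their own exact TreeSHAP
(``pred_contrib``); this module covers the scikit-learn estimators
(DecisionTreeRegressor, RandomForestRegressor, GradientBoostingRegressor).

Local accuracy holds by construction: base value (cover-weighted mean of
the leaves) plus the attributions equals the tree's prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = ["TreeArrays", "tree_shap_values", "sklearn_shap_values", "expected_value"]


@dataclass(frozen=True)
class TreeArrays:
    """Flat-array view of one regression tree.

    children_left/right: child node ids, -1 at leaves; feature/threshold:
    split definition per node; value: leaf prediction per node; cover:
    weighted number of training samples reaching each node.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @classmethod
    def from_sklearn(cls, tree) -> "TreeArrays":
        t = tree.tree_
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=t.value.reshape(-1).astype(float).copy(),
            cover=t.weighted_n_node_samples.astype(float).copy(),
        )


def expected_value(tree: TreeArrays) -> float:
    """Cover-weighted mean leaf value = E[f(x)] over the training data."""

    def rec(node: int) -> float:
        if tree.children_left[node] < 0:
            return tree.value[node]
        left, right = tree.children_left[node], tree.children_right[node]
        wl, wr = tree.cover[left], tree.cover[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


class _Path:
    """One element per unique feature on the current root-leaf path."""

    __slots__ = ("feature", "zero", "one", "weight")

    def __init__(self, feature: int, zero: float, one: float, weight: float):
        self.feature = feature
        self.zero = zero  # fraction of "feature absent" subsets that flow down
        self.one = one  # 1 if the instance's value follows this path else 0
        self.weight = weight  # proportion of subsets of each cardinality

    def copy(self) -> "_Path":
        return _Path(self.feature, self.zero, self.one, self.weight)


def _extend(path: list[_Path], zero: float, one: float, feature: int) -> list[_Path]:
    depth = len(path)
    path = [el.copy() for el in path]
    path.append(_Path(feature, zero, one, 1.0 if depth == 0 else 0.0))
    for i in range(depth - 1, -1, -1):
        path[i + 1].weight += one * path[i].weight * (i + 1) / (depth + 1)
        path[i].weight = zero * path[i].weight * (depth - i) / (depth + 1)
    return path


def _unwind(path: list[_Path], index: int) -> list[_Path]:
    depth = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    path = [el.copy() for el in path]
    carry = path[depth].weight
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = path[i].weight
            path[i].weight = carry * (depth + 1) / ((i + 1) * one)
            carry = tmp - path[i].weight * zero * (depth - i) / (depth + 1)
        else:
            path[i].weight = path[i].weight * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        path[i].feature = path[i + 1].feature
        path[i].zero = path[i + 1].zero
        path[i].one = path[i + 1].one
    return path[:depth]


def _unwound_sum(path: list[_Path], index: int) -> float:
    depth = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    total = 0.0
    if one != 0.0:
        carry = path[depth].weight
        for i in range(depth - 1, -1, -1):
            tmp = carry / ((i + 1) * one)
            total += tmp
            carry = path[i].weight - tmp * zero * (depth - i)
    else:
        for i in range(depth - 1, -1, -1):
            total += path[i].weight / (zero * (depth - i))
    return total * (depth + 1)


def tree_shap_values(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact path-dependent SHAP attributions of one tree for one instance."""
    phi = np.zeros(n_features)

    def recurse(
        node: int,
        path: list[_Path],
        parent_zero: float,
        parent_one: float,
        parent_feature: int,
    ) -> None:
        path = _extend(path, parent_zero, parent_one, parent_feature)
        left = tree.children_left[node]
        if left < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[el.feature] += w * (el.one - el.zero) * tree.value[node]
            return
        right = tree.children_right[node]
        split = int(tree.feature[node])
        hot, cold = (left, right) if x[split] <= tree.threshold[node] else (right, left)
        hot_zero = tree.cover[hot] / tree.cover[node]
        cold_zero = tree.cover[cold] / tree.cover[node]
        incoming_zero = incoming_one = 1.0
        for k, el in enumerate(path):
            if el.feature == split:
                incoming_zero, incoming_one = el.zero, el.one
                path = _unwind(path, k)
                break
        recurse(hot, path, hot_zero * incoming_zero, incoming_one, split)
        recurse(cold, path, cold_zero * incoming_zero, 0.0, split)

    # parent_feature -1 is a dummy slot for the root extension
    recurse(0, [], 1.0, 1.0, -1)
    return phi


def _model_trees(model) -> tuple[list[TreeArrays], np.ndarray, float]:
    """Decompose a sklearn tree model into (trees, per-tree scale, offset)
    such that prediction = offset + sum_i scale_i * tree_i(x)."""
    if isinstance(model, DecisionTreeRegressor):
        return [TreeArrays.from_sklearn(model)], np.ones(1), 0.0
    if isinstance(model, RandomForestRegressor):
        trees = [TreeArrays.from_sklearn(est) for est in model.estimators_]
        return trees, np.full(len(trees), 1.0 / len(trees)), 0.0
    if isinstance(model, GradientBoostingRegressor):
        trees = [TreeArrays.from_sklearn(est) for est in model.estimators_.ravel()]
        offset = float(model.init_.predict(np.zeros((1, model.n_features_in_)))[0])
        return trees, np.full(len(trees), model.learning_rate), offset
    raise TypeError(
        f"not a supported scikit-learn tree model: {type(model).__name__}"
    )


def sklearn_shap_values(model, X) -> tuple[np.ndarray, float]:
    """SHAP attribution matrix and base value for a sklearn tree model.

    Returns (phi, base) with phi of shape (n_instances, n_features) and
    base + phi.sum(axis=1) equal to model.predict(X).
    """
    X = np.asarray(X, dtype=float)
    trees, scales, offset = _model_trees(model)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = offset + sum(s * expected_value(t) for t, s in zip(trees, scales))
    for t, s in zip(trees, scales):
        for i in range(n):
            phi[i] += s * tree_shap_values(t, X[i], p)
    return phi, float(base)
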