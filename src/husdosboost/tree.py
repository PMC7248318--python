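"""Weight-aware CART weak learner.

A small binary classification tree in which every count is replaced by a sum
of example weights: node impurity is the Gini index over weighted class sums,
splits greedily maximize the weighted impurity decrease, and leaves predict
the class with the larger weighted sum. Boosting weights therefore shape the
tree exactly as duplicating examples would.

Split conventions are fixed for bit-reproducibility:

* candidate thresholds are midpoints between consecutive distinct sorted
  values of a variable (binary 0/1 columns thus split at 0.5);
* a point exactly at a threshold routes to the left (<=) branch;
* among equal-gain splits the lowest variable index wins, then the lowest
  threshold;
* a leaf with exactly tied weighted class sums predicts the majority class.

Per-node impurity decreases are kept on the model; their per-variable totals
(each node's gain weighted by the node's share of total example weight) feed
the ensemble-level variable importance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MAJORITY, MINORITY

_GAIN_TOL = 1e-12


def gini_impurity(class_weight_sums: np.ndarray) -> float:
    """Gini index 1 - sum_k (share_k)^2 of a node's weighted class sums."""
    sums = np.asarray(class_weight_sums, dtype=float)
    if (sums < 0).any():
        raise ValueError("class weight sums must be nonnegative")
    total = sums.sum()
    if total <= 0:
        raise ValueError("node has zero total weight; impurity undefined")
    shares = sums / total
    return float(1.0 - (shares * shares).sum())


def split_gain(
    parent_sums: np.ndarray, left_sums: np.ndarray, right_sums: np.ndarray
) -> float:
    """Weighted impurity decrease of a split.

    ``I_G(parent) - sum_l w_l I_G(child_l)`` with ``w_l`` the child's share of
    the parent's weight. An empty child makes the split inadmissible and the
    gain is 0 by convention.
    """
    parent_sums = np.asarray(parent_sums, dtype=float)
    left_sums = np.asarray(left_sums, dtype=float)
    right_sums = np.asarray(right_sums, dtype=float)
    if not np.allclose(left_sums + right_sums, parent_sums):
        raise ValueError("child class sums must add up to the parent's")
    wl, wr = left_sums.sum(), right_sums.sum()
    if wl <= 0 or wr <= 0:
        return 0.0
    total = wl + wr
    gain = (
        gini_impurity(parent_sums)
        - (wl / total) * gini_impurity(left_sums)
        - (wr / total) * gini_impurity(right_sums)
    )
    return float(max(gain, 0.0))


@dataclass
class TreeNode:
    """One node of a fitted tree; a leaf iff it has no children."""

    node_id: int
    class_weight_sums: np.ndarray
    impurity: float
    prediction: int
    weight_fraction: float  # this node's weight / root weight
    depth: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    gain: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass(frozen=True)
class TreeConfig:
    """Stopping rules for the weak learner."""

    max_depth: int = 3
    min_leaf_weight: float = 0.0  # absolute weight a child must retain

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.min_leaf_weight < 0:
            raise ValueError("min_leaf_weight must be >= 0")


def _class_sums(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.array([w[y == MAJORITY].sum(), w[y == MINORITY].sum()])


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, min_leaf_weight: float
) -> tuple[float, int, float] | None:
    """Exhaustive greedy search over (variable, midpoint threshold) pairs."""
    parent_sums = _class_sums(y, w)
    parent_imp = gini_impurity(parent_sums)
    total = parent_sums.sum()
    w1 = w * (y == MINORITY)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cut = np.flatnonzero(xs[:-1] < xs[1:])  # boundaries between distincts
        if len(cut) == 0:
            continue
        cw = np.cumsum(w[order])[cut]
        cw1 = np.cumsum(w1[order])[cut]
        lw0, lw1 = cw - cw1, cw1
        rw0 = parent_sums[0] - lw0
        rw1 = parent_sums[1] - lw1
        lw, rw = lw0 + lw1, rw0 + rw1
        ok = (lw >= max(min_leaf_weight, _GAIN_TOL)) & (
            rw >= max(min_leaf_weight, _GAIN_TOL)
        )
        if not ok.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            gini_l = 1.0 - ((lw0 / lw) ** 2 + (lw1 / lw) ** 2)
            gini_r = 1.0 - ((rw0 / rw) ** 2 + (rw1 / rw) ** 2)
        gains = parent_imp - (lw * gini_l + rw * gini_r) / total
        gains = np.where(ok, gains, -np.inf)
        k = int(np.argmax(gains))  # first max -> lowest threshold wins ties
        if gains[k] <= _GAIN_TOL:
            continue
        thr = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
        if best is None or gains[k] > best[0]:  # strict: lowest variable wins
            best = (float(gains[k]), j, float(thr))
    return best


@dataclass
class TreeModel:
    """A fitted weighted CART with per-node gain accounting."""

    root: TreeNode
    n_features: int
    feature_names: tuple[str, ...]
    config: TreeConfig

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.right, node.left])
        return out

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes())

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = self._validate(X)
        out = np.empty(len(X), dtype=np.int8)
        idx = np.arange(len(X))
        stack = [(self.root, idx)]
        while stack:
            node, rows = stack.pop()
            if node.is_leaf:
                out[rows] = node.prediction
                continue
            go_left = X[rows, node.feature] <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def variable_gains(self) -> dict[str, float]:
        """Per-variable impurity decrease, node-weight weighted.

        Each internal node contributes ``gain * weight_fraction`` to its split
        variable, so a split near the root counts more than an equal-gain
        split over a sliver of the data.
        """
        totals = dict.fromkeys(self.feature_names, 0.0)
        for node in self.nodes():
            if not node.is_leaf:
                totals[self.feature_names[node.feature]] += (
                    node.gain * node.weight_fraction
                )
        return totals

    def _validate(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != list(self.feature_names):
                raise ValueError("feature columns do not match the training schema")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        return X

    # ---- audit serialization ------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(node: TreeNode) -> dict:
            d = {
                "id": node.node_id,
                "class_weight_sums": list(map(float, node.class_weight_sums)),
                "impurity": node.impurity,
                "prediction": int(node.prediction),
                "weight_fraction": node.weight_fraction,
                "depth": node.depth,
            }
            if not node.is_leaf:
                d.update(
                    feature=self.feature_names[node.feature],
                    feature_index=int(node.feature),
                    threshold=node.threshold,
                    gain=node.gain,
                    left=enc(node.left),
                    right=enc(node.right),
                )
            return d

        text = json.dumps(
            {
                "feature_names": list(self.feature_names),
                "config": {"max_depth": self.config.max_depth,
                           "min_leaf_weight": self.config.min_leaf_weight},
                "root": enc(self.root),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        names = tuple(d["feature_names"])

        def dec(e: dict) -> TreeNode:
            node = TreeNode(
                node_id=e["id"],
                class_weight_sums=np.asarray(e["class_weight_sums"], float),
                impurity=e["impurity"],
                prediction=e["prediction"],
                weight_fraction=e["weight_fraction"],
                depth=e["depth"],
            )
            if "left" in e:
                node.feature = e["feature_index"]
                node.threshold = e["threshold"]
                node.gain = e["gain"]
                node.left = dec(e["left"])
                node.right = dec(e["right"])
            return node

        cfg = TreeConfig(**d["config"])
        return cls(dec(d["root"]), len(names), names, cfg)


def fit_weighted_tree(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    example_weights: np.ndarray | None = None,
    config: TreeConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> TreeModel:
    """Grow a depth-limited binary tree by greedy weighted-Gini splits.

    Growth stops at ``max_depth``, at a pure node, when no admissible split
    has positive gain, or when a split would leave a child below
    ``min_leaf_weight``. A single-class training set yields a depth-0 tree
    predicting that class.
    """
    config = config or TreeConfig()
    if isinstance(features, pd.DataFrame):
        if feature_names is None:
            feature_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("features must be a non-empty 2-D array")
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("features and labels differ in length")
    if example_weights is None:
        w = np.full(len(X), 1.0 / len(X))
    else:
        w = np.asarray(example_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative and not all zero")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    total_weight = w.sum()
    counter = iter(range(10 ** 9))

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        sums = _class_sums(y[rows], w[rows])
        node = TreeNode(
            node_id=next(counter),
            class_weight_sums=sums,
            impurity=gini_impurity(sums),
            prediction=int(MINORITY if sums[MINORITY] > sums[MAJORITY] else MAJORITY),
            weight_fraction=float(sums.sum() / total_weight),
            depth=depth,
        )
        if depth >= config.max_depth or node.impurity <= 0.0:
            return node
        found = _best_split(X[rows], y[rows], w[rows], config.min_leaf_weight)
        if found is None:
            return node
        gain, j, thr = found
        node.feature, node.threshold, node.gain = j, thr, gain
        go_left = X[rows, j] <= thr
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    root = grow(np.arange(len(X)), 0)
    return TreeModel(root, X.shape[1], tuple(feature_names), config)


def tree_predict(model: TreeModel, examples: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Route examples through a fitted tree; ties at a threshold go left."""
    return model.predict(examples)


def tree_variable_gains(model: TreeModel) -> dict[str, float]:
    """Per-variable totals of node-weighted impurity decreases."""
    return model.variable_gains()
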