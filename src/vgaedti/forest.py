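"""Random forest scorer for drug-target pairs, written from scratch.

Each (target, drug) pair is featurized by concatenating the target's and
the drug's learned embedding vectors. A forest of CART trees is grown on
bootstrap resamples of the labeled pairs; splits minimize the
Gini-impurity-weighted child sum over candidate thresholds (midpoints of
consecutive sorted unique feature values) within a random feature subset.
A pair's score is the mean positive-class leaf proportion across trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TreeParams:
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: int | str | None = None  # None=all, "sqrt", or an int

    def resolve_max_features(self, n_features: int) -> int:
        if self.max_features is None:
            return n_features
        if self.max_features == "sqrt":
            return int(np.ceil(np.sqrt(n_features)))
        k = int(self.max_features)
        if not 1 <= k <= n_features:
            raise ValueError("max_features out of range")
        return k


@dataclass
class PairFeatureTable:
    """Feature rows for (target, drug) pairs with optional 0/1 labels."""

    features: np.ndarray
    pairs: np.ndarray  # (n_rows, 2) integer (target_index, drug_index)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")
            if len(self.labels) != len(self.features):
                raise ValueError("labels length must match feature rows")


def pair_features(Y_p, Y_r, pairs, encoding: str = "concat") -> np.ndarray:
    """Featurize pairs from embeddings: concatenation (default) or sum."""
    Y_p, Y_r = np.asarray(Y_p), np.asarray(Y_r)
    pairs = np.asarray(pairs, dtype=int)
    ti, di = pairs[:, 0], pairs[:, 1]
    if encoding == "concat":
        return np.hstack([Y_p[ti], Y_r[di]])
    if encoding == "sum":
        if Y_p.shape[1] != Y_r.shape[1]:
            raise ValueError("sum encoding requires equal embedding widths")
        return Y_p[ti] + Y_r[di]
    raise ValueError("encoding must be 'concat' or 'sum'")


def gini(labels) -> float:
    """Gini impurity 1 - sum_i p_i^2 of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - (p**2).sum())


def gini_index_split(features, labels, feature: int, threshold: float) -> float:
    """Size-weighted child Gini sum for a single (feature, threshold) split."""
    x = np.asarray(features, dtype=float)[:, feature]
    y = np.asarray(labels)
    left = x <= threshold
    n_l = int(left.sum())
    if n_l == 0 or n_l == y.size:
        raise ValueError("degenerate split: one child is empty")
    w_l = n_l / y.size
    return w_l * gini(y[left]) + (1 - w_l) * gini(y[~left])


def _best_split_for_feature(x, y, min_leaf):
    """Best (impurity, threshold) along one feature, vectorized.

    Binary labels assumed. Returns (inf, nan) if no valid split exists.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    # split after position i puts i+1 samples left
    pos_left = np.cumsum(ys)[:-1]
    n_left = np.arange(1, n)
    valid = xs[:-1] != xs[1:]
    valid &= (n_left >= min_leaf) & (n - n_left >= min_leaf)
    if not valid.any():
        return np.inf, np.nan
    n_right = n - n_left
    pos_right = pos_left[-1] + ys[-1] - pos_left
    p_l = pos_left / n_left
    p_r = pos_right / n_right
    g_l = 1.0 - p_l**2 - (1.0 - p_l) ** 2
    g_r = 1.0 - p_r**2 - (1.0 - p_r) ** 2
    impurity = (n_left * g_l + n_right * g_r) / n
    impurity = np.where(valid, impurity, np.inf)
    best = int(np.argmin(impurity))  # argmin takes the lowest index on ties
    return float(impurity[best]), float((xs[best] + xs[best + 1]) / 2.0)


@dataclass
class _Node:
    proba: float  # positive-class proportion at this node
    feature: int = -1
    threshold: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


class DecisionTree:
    """CART classifier with Gini-impurity splitting."""

    def __init__(self, params: TreeParams | None = None):
        self.params = params or TreeParams()
        self.root: _Node | None = None
        self.n_features: int | None = None

    def fit(self, X, y, rng=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("need a non-empty 2-D feature matrix")
        rng = rng or np.random.default_rng()
        self.n_features = X.shape[1]
        self._k = self.params.resolve_max_features(self.n_features)
        self.root = self._grow(X, y, depth=0, rng=rng)
        return self

    def _grow(self, X, y, depth, rng):
        node = _Node(proba=float(y.mean()))
        n = y.size
        if (
            n < 2 * self.params.min_samples_leaf
            or node.proba in (0.0, 1.0)
            or (self.params.max_depth is not None and depth >= self.params.max_depth)
        ):
            return node
        if self._k < self.n_features:
            feats = np.sort(rng.choice(self.n_features, size=self._k, replace=False))
        else:
            feats = np.arange(self.n_features)
        best = (np.inf, -1, np.nan)
        for f in feats:
            imp, thr = _best_split_for_feature(
                X[:, f], y, self.params.min_samples_leaf
            )
            if imp < best[0]:
                best = (imp, f, thr)
        if not np.isfinite(best[0]):
            return node
        node.feature, node.threshold = int(best[1]), float(best[2])
        mask = X[:, node.feature] <= node.threshold
        node.left = self._grow(X[mask], y[mask], depth + 1, rng)
        node.right = self._grow(X[~mask], y[~mask], depth + 1, rng)
        return node

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} != fitted width {self.n_features}"
            )
        out = np.empty(X.shape[0])
        self._route(self.root, np.arange(X.shape[0]), X, out)
        return out

    def _route(self, node, idx, X, out):
        if node.is_leaf:
            out[idx] = node.proba
            return
        mask = X[idx, node.feature] <= node.threshold
        self._route(node.left, idx[mask], X, out)
        self._route(node.right, idx[~mask], X, out)


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    params: TreeParams
    seed: int
    bootstrap: bool = True
    oob_indices: list[np.ndarray] = field(default_factory=list)

    def predict_proba(self, X) -> np.ndarray:
        if not self.trees:
            raise ValueError("forest has no trees")
        return np.mean([t.predict_proba(X) for t in self.trees], axis=0)


def fit_forest(
    table: PairFeatureTable,
    n_trees: int = 100,
    params: TreeParams | None = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Grow ``n_trees`` CART trees on with-replacement bootstrap resamples."""
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if table.labels is None:
        raise ValueError("training table must carry labels")
    params = params or TreeParams(max_features="sqrt")
    X, y = table.features, table.labels
    n = X.shape[0]
    root_rng = np.random.default_rng(seed)
    trees, oob = [], []
    for _ in range(n_trees):
        tree_rng = np.random.default_rng(root_rng.integers(2**31))
        if bootstrap:
            idx = tree_rng.integers(n, size=n)
        else:
            idx = np.arange(n)
        oob.append(np.setdiff1d(np.arange(n), idx))
        trees.append(
            DecisionTree(params).fit(X[idx], y[idx], rng=tree_rng)
        )
    return ForestModel(trees, params, seed, bootstrap, oob)


@dataclass
class ScoreMatrix:
    """Predicted association score per (target, drug) pair."""

    values: np.ndarray  # m x n
    target_ids: list[str]
    drug_ids: list[str]
    known: np.ndarray | None = None  # mask of training-known positives


def predict_scores(
    model: ForestModel,
    Y_p: np.ndarray,
    Y_r: np.ndarray,
    target_ids: list[str],
    drug_ids: list[str],
    known: np.ndarray | None = None,
    encoding: str = "concat",
) -> ScoreMatrix:
    """Score every (target, drug) pair and assemble the m x n matrix."""
    m, n = len(target_ids), len(drug_ids)
    ti, di = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    pairs = np.column_stack([ti.ravel(), di.ravel()])
    feats = pair_features(Y_p, Y_r, pairs, encoding)
    scores = model.predict_proba(feats).reshape(m, n)
    return ScoreMatrix(scores, list(target_ids), list(drug_ids), known)
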