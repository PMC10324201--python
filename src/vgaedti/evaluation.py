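"""Cross-validation protocol and ranking metrics for DTI prediction.

Labeled (target, drug) pairs — known interactions as positives, a set of
unknown pairs as negatives — are split into stratified folds. For each
fold the test positives are removed from the association block before the
network is built and trained, the full pipeline (embedding learning +
random forest) is fitted on the training pairs, and the held-out pairs are
scored. Metrics: confusion-matrix ratios, AUROC by trapezoidal threshold
sweep, AUPR by step-wise precision-recall summation, and recall within
the top-k fraction of ranked candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import (
    PairFeatureTable,
    TreeParams,
    fit_forest,
    pair_features,
)
from .hetnet import HeterogeneousNetwork
from .training import TrainConfig, fit

TOPK_FRACTIONS = (0.05, 0.10, 0.20, 0.30)


@dataclass
class FoldPlan:
    k: int
    seed: int
    test_indices: list[np.ndarray]  # per-fold indices into the pair list

    def train_indices(self, fold: int, n: int) -> np.ndarray:
        mask = np.ones(n, dtype=bool)
        mask[self.test_indices[fold]] = False
        return np.flatnonzero(mask)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


@dataclass
class ForestConfig:
    n_trees: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: int | str | None = "sqrt"
    neg_ratio: float | None = None  # negatives per positive; None = all
    encoding: str = "concat"

    def tree_params(self) -> TreeParams:
        return TreeParams(self.max_depth, self.min_samples_leaf, self.max_features)


@dataclass
class EvalReport:
    per_fold: list[dict]
    mean: dict

    def summary(self) -> str:
        lines = ["fold  " + "  ".join(f"{k:>10}" for k in self.mean)]
        for i, fold in enumerate(self.per_fold):
            lines.append(
                f"{i:>4}  "
                + "  ".join(f"{fold[k]:>10.4f}" for k in self.mean)
            )
        lines.append(
            "mean  " + "  ".join(f"{self.mean[k]:>10.4f}" for k in self.mean)
        )
        return "\n".join(lines)


def make_folds(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified random partition of labeled pairs into k folds.

    Positives and negatives are shuffled separately and dealt round-robin
    so each fold preserves the class ratio up to rounding.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} pairs")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return FoldPlan(k, seed, [np.sort(np.array(f, dtype=int)) for f in folds])


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Specificity, sensitivity, accuracy, precision, FPR from counts.

    Metrics with a zero denominator are reported as ``nan`` (undefined),
    never silently as 0.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    specificity = ratio(c.TN, c.TN + c.FP)
    sensitivity = ratio(c.TP, c.TP + c.FN)
    return {
        "specificity": specificity,
        "sensitivity": sensitivity,
        "accuracy": ratio(c.TP + c.TN, c.TP + c.FP + c.TN + c.FN),
        "precision": ratio(c.TP, c.TP + c.FP),
        "fpr": 1.0 - specificity if not np.isnan(specificity) else float("nan"),
    }


def _check_two_class(labels):
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute a curve")
    return labels


def roc_curve(scores, labels):
    """(FPR, TPR) points by descending-threshold sweep; ties move together."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels).astype(float)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tied block
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    P, N = y.sum(), y.size - y.sum()
    return np.r_[0.0, fps / N], np.r_[0.0, tps / P]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoidal rule."""
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise (no interpolation).

    AUPR = sum over threshold steps of precision * (recall increment).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels).astype(float)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    P = y.sum()
    precision = tps / (tps + fps)
    recall = tps / P
    return float(np.sum(precision * np.diff(np.r_[0.0, recall])))


def recall_at_topk(scores, labels, fraction: float) -> float:
    """Fraction of positives ranked within the top ``fraction`` of pairs.

    Ranking is by score descending with a deterministic index tie-break.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    P = labels.sum()
    if P == 0:
        return 0.0
    top = int(np.ceil(fraction * scores.size))
    order = np.argsort(-scores, kind="stable")
    return float(labels[order[:top]].sum() / P)


def _sample_negatives(A_pr, exclude_mask, rng, n_neg):
    """Draw ``n_neg`` unknown pairs (flat indices) outside ``exclude_mask``."""
    candidates = np.flatnonzero((A_pr.ravel() == 0) & ~exclude_mask.ravel())
    if n_neg >= candidates.size:
        return candidates
    return rng.choice(candidates, size=n_neg, replace=False)


def labeled_pairs(
    A_pr: np.ndarray,
    neg_ratio: float | None = None,
    seed: int = 0,
    exclude: np.ndarray | None = None,
):
    """The labeled pair universe: all known positives plus unknown negatives.

    ``neg_ratio`` subsamples negatives at that many per positive; ``None``
    keeps every unknown pair (the class-imbalanced default).
    """
    A_pr = np.asarray(A_pr)
    exclude = (
        np.zeros_like(A_pr, dtype=bool) if exclude is None else exclude.astype(bool)
    )
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero((A_pr.ravel() == 1) & ~exclude.ravel())
    if neg_ratio is None:
        neg = np.flatnonzero((A_pr.ravel() == 0) & ~exclude.ravel())
    else:
        neg = _sample_negatives(A_pr, exclude, rng, int(neg_ratio * pos.size))
    flat = np.r_[pos, neg]
    labels = np.r_[np.ones(pos.size, int), np.zeros(neg.size, int)]
    pairs = np.column_stack(np.unravel_index(flat, A_pr.shape))
    return pairs, labels


def fit_and_score(
    net: HeterogeneousNetwork,
    train_pairs,
    train_labels,
    test_pairs,
    train_config: TrainConfig,
    forest_config: ForestConfig,
    seed: int = 0,
):
    """Train embeddings + forest on training pairs, score test pairs.

    Positives outside the training set are masked from the association
    block before the network is normalized and trained, so held-out labels
    never leak into message passing.
    """
    train_pairs = np.asarray(train_pairs, int)
    test_pairs = np.asarray(test_pairs, int)
    A = net.A_pr.copy()
    keep = np.zeros_like(A, dtype=bool)
    pos = train_pairs[np.asarray(train_labels) == 1]
    keep[pos[:, 0], pos[:, 1]] = True
    A_masked = np.where(keep, A, 0.0)
    if test_pairs.size:
        assert not A_masked[test_pairs[:, 0], test_pairs[:, 1]].any(), (
            "leakage: test pair present in training adjacency"
        )
    state = fit(net.with_dti_block(A_masked), train_config)
    table = PairFeatureTable(
        pair_features(state.Y_p, state.Y_r, train_pairs, forest_config.encoding),
        train_pairs,
        np.asarray(train_labels),
    )
    model = fit_forest(
        table,
        n_trees=forest_config.n_trees,
        params=forest_config.tree_params(),
        seed=seed,
    )
    feats = pair_features(state.Y_p, state.Y_r, test_pairs, forest_config.encoding)
    return model.predict_proba(feats), state, model


def run_recovery(
    data,
    train_config: TrainConfig,
    forest_config: ForestConfig,
    seed: int = 0,
):
    """Masked-positive recovery benchmark on a synthetic bundle.

    Trains on the observed (masked) association block, scores every pair,
    and evaluates the ranking of held-out true interactions against pairs
    unknown in both the clean truth and the observed block. Returns the
    trained state, the score matrix and a metric dict.
    """
    from .forest import predict_scores

    net = data.network()
    mask = data.truth.eval_cells(net.A_pr)
    y = data.truth.A_pr_full[mask]
    pairs, labels = labeled_pairs(
        net.A_pr, neg_ratio=forest_config.neg_ratio, seed=seed,
        exclude=data.truth.test_mask,
    )
    state = fit(net, train_config)
    table = PairFeatureTable(
        pair_features(state.Y_p, state.Y_r, pairs, forest_config.encoding),
        pairs,
        labels,
    )
    model = fit_forest(
        table, n_trees=forest_config.n_trees,
        params=forest_config.tree_params(), seed=seed,
    )
    scores = predict_scores(
        model, state.Y_p, state.Y_r, state.target_ids, state.drug_ids,
        known=net.A_pr.astype(bool), encoding=forest_config.encoding,
    )
    s = scores.values[mask]
    metrics = {
        "auroc": roc_auc(s, y),
        "aupr": pr_auc(s, y),
        "prevalence": float(y.mean()),
        "n_eval_pairs": int(mask.sum()),
        "n_masked_positives": int(data.truth.test_mask.sum()),
    }
    for frac in TOPK_FRACTIONS:
        metrics[f"recall@{int(frac * 100)}%"] = recall_at_topk(s, y, frac)
    return state, scores, metrics


def cross_validate(
    net: HeterogeneousNetwork,
    train_config: TrainConfig | None = None,
    forest_config: ForestConfig | None = None,
    k: int = 5,
    seed: int = 0,
    split_by: str = "pair",
) -> EvalReport:
    """Fivefold (by default) cross-validation of the full pipeline.

    ``split_by="pair"`` (default) partitions labeled pairs stratified by
    class; ``split_by="drug"`` holds out whole drug columns per fold.
    """
    train_config = train_config or TrainConfig()
    forest_config = forest_config or ForestConfig()
    pairs, labels = labeled_pairs(
        net.A_pr, neg_ratio=forest_config.neg_ratio, seed=seed
    )
    if split_by == "pair":
        plan = make_folds(labels, k=k, seed=seed)
    elif split_by == "drug":
        rng = np.random.default_rng(seed)
        drug_fold = rng.permutation(net.n_drugs) % k
        plan = FoldPlan(
            k, seed,
            [
                np.flatnonzero(drug_fold[pairs[:, 1]] == fold)
                for fold in range(k)
            ],
        )
    else:
        raise ValueError("split_by must be 'pair' or 'drug'")
    per_fold = []
    for fold in range(k):
        test_idx = plan.test_indices[fold]
        train_idx = plan.train_indices(fold, labels.size)
        scores, _, _ = fit_and_score(
            net,
            pairs[train_idx],
            labels[train_idx],
            pairs[test_idx],
            train_config,
            forest_config,
            seed=seed + fold,
        )
        y = labels[test_idx]
        pred = (scores >= 0.5).astype(int)
        counts = ConfusionCounts(
            TP=int(((pred == 1) & (y == 1)).sum()),
            FP=int(((pred == 1) & (y == 0)).sum()),
            TN=int(((pred == 0) & (y == 0)).sum()),
            FN=int(((pred == 0) & (y == 1)).sum()),
        )
        if y.min() == y.max():  # single-class fold (possible for drug splits)
            row = {"auroc": float("nan"), "aupr": float("nan")}
        else:
            row = {"auroc": roc_auc(scores, y), "aupr": pr_auc(scores, y)}
        row.update(confusion_metrics(counts))
        for frac in TOPK_FRACTIONS:
            row[f"recall@{int(frac * 100)}%"] = recall_at_topk(scores, y, frac)
        per_fold.append(row)
    mean = {
        key: float(np.nanmean([f[key] for f in per_fold])) for key in per_fold[0]
    }
    return EvalReport(per_fold, mean)
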