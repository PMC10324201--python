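"""From-scratch CART / random forest: impurity, splits, bootstrap, scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vgaedti.forest import (
    DecisionTree,
    PairFeatureTable,
    TreeParams,
    fit_forest,
    gini,
    gini_index_split,
    pair_features,
    predict_scores,
)


def brute_force_best_split(X, y, min_leaf=1):
    """Exhaustive search over all (feature, midpoint) candidates."""
    best = (np.inf, -1, np.nan)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, f] <= thr
            nl = left.sum()
            if nl < min_leaf or y.size - nl < min_leaf:
                continue
            imp = (
                nl * gini(y[left]) + (y.size - nl) * gini(y[~left])
            ) / y.size
            if imp < best[0]:
                best = (imp, f, thr)
    return best


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini([1, 1, 1]) == 0.0

    def test_balanced_binary(self):
        assert gini([0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_k_class_closed_form(self, k):
        labels = np.repeat(np.arange(k), 4)
        assert gini(labels) == pytest.approx(1 - 1 / k)

    def test_invariant_to_label_names_and_order(self, rng):
        labels = rng.integers(0, 3, size=40)
        renamed = np.array([10, 20, 30])[labels]
        assert gini(labels) == pytest.approx(gini(rng.permutation(renamed)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gini([])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=50))
    def test_bounds_and_duplication_invariance(self, labels):
        """0 <= gini < 1 - 1/k, and duplicating the multiset changes nothing."""
        g = gini(labels)
        k = len(set(labels))
        assert 0.0 <= g <= 1 - 1 / k + 1e-12
        assert gini(labels + labels) == pytest.approx(g)


class TestGiniIndexSplit:
    def test_pure_children_zero(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        assert gini_index_split(X, y, 0, 5.0) == 0.0

    def test_parent_distribution_preserving_split(self):
        # both children 50/50 -> weighted sum equals parent impurity
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        assert gini_index_split(X, y, 0, 0.5) == pytest.approx(gini(y))

    def test_three_one_split_hand_value(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0]])
        y = np.array([1, 1, 0, 0])
        # {+,+,-} | {-}: 0.75 * (1 - 4/9 - 1/9) + 0.25 * 0 = 1/3
        assert gini_index_split(X, y, 0, 5.0) == pytest.approx(1 / 3)

    def test_degenerate_split_rejected(self):
        X = np.array([[1.0], [2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            gini_index_split(X, np.array([0, 1]), 0, 5.0)


class TestBuildTree:
    def test_constant_labels_single_leaf(self, rng):
        X = rng.random((10, 3))
        tree = DecisionTree().fit(X, np.ones(10))
        assert tree.root.is_leaf
        assert tree.root.proba == 1.0

    def test_separable_1d_depth_one(self):
        X = np.array([[0.1], [0.2], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        tree = DecisionTree(TreeParams(max_depth=1)).fit(X, y)
        assert not tree.root.is_leaf
        assert np.array_equal(tree.predict_proba(X), y.astype(float))

    def test_root_split_matches_brute_force(self, rng):
        """Chosen root split impurity equals exhaustive search (100 tables)."""
        for _ in range(100):
            n = int(rng.integers(5, 51))
            X = rng.standard_normal((n, 3))
            y = rng.integers(0, 2, size=n).astype(float)
            if y.min() == y.max():
                continue
            tree = DecisionTree(TreeParams(max_depth=1)).fit(X, y, rng=rng)
            imp, f, thr = brute_force_best_split(X, y)
            if tree.root.is_leaf:
                assert not np.isfinite(imp)
                continue
            chosen = gini_index_split(X, y, tree.root.feature, tree.root.threshold)
            assert chosen == pytest.approx(imp, abs=1e-12)

    def test_training_error_nonincreasing_in_depth(self, rng):
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] * X[:, 1] > 0).astype(float)
        errors = []
        for depth in (1, 2, 4, 8):
            tree = DecisionTree(TreeParams(max_depth=depth)).fit(X, y)
            errors.append(np.mean((tree.predict_proba(X) >= 0.5) != y))
        assert all(a >= b for a, b in zip(errors, errors[1:]))


class TestForest:
    def _table(self, rng, n=80):
        X = rng.standard_normal((n, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        pairs = np.column_stack([np.arange(n), np.arange(n)])
        return PairFeatureTable(X, pairs, y)

    def test_single_tree_no_bootstrap_equals_cart(self, rng):
        table = self._table(rng)
        forest = fit_forest(table, n_trees=1, seed=3, bootstrap=False,
                            params=TreeParams())
        tree = DecisionTree(TreeParams()).fit(
            table.features, table.labels, rng=np.random.default_rng(0)
        )
        assert np.allclose(
            forest.predict_proba(table.features), tree.predict_proba(table.features)
        )

    def test_same_seed_identical_forests(self, rng):
        table = self._table(rng)
        s1 = fit_forest(table, n_trees=5, seed=7).predict_proba(table.features)
        s2 = fit_forest(table, n_trees=5, seed=7).predict_proba(table.features)
        assert np.array_equal(s1, s2)

    def test_out_of_bag_fraction_near_1_over_e(self, rng):
        table = self._table(rng, n=200)
        forest = fit_forest(table, n_trees=60, seed=1)
        frac = np.mean([oob.size / 200 for oob in forest.oob_indices])
        assert abs(frac - np.exp(-1)) < 0.02

    def test_scores_average_tree_votes(self):
        t_hi, t_lo = DecisionTree(), DecisionTree()
        X = np.array([[0.0], [1.0]])
        t_hi.fit(X, np.array([1.0, 1.0]))
        t_lo.fit(X, np.array([0.0, 0.0]))
        from vgaedti.forest import ForestModel

        model = ForestModel([t_hi, t_lo], TreeParams(), 0)
        assert np.allclose(model.predict_proba(X), 0.5)

    def test_separable_toy_perfect_training_ranking(self, rng):
        from vgaedti.evaluation import roc_auc

        X = np.vstack([rng.normal(-2, 0.5, (50, 2)), rng.normal(2, 0.5, (50, 2))])
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        table = PairFeatureTable(X, np.zeros((100, 2), int), y)
        model = fit_forest(table, n_trees=20, seed=5)
        assert roc_auc(model.predict_proba(X), y) == 1.0

    def test_null_labels_give_chance_level_cv_auroc(self, rng):
        """Permuted labels carry no signal: held-out AUROC stays near 0.5."""
        from vgaedti.evaluation import make_folds, roc_auc

        aurocs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((120, 4))
            y = r.integers(0, 2, size=120)
            plan = make_folds(y, k=4, seed=seed)
            scores = np.empty(120)
            for fold in range(4):
                te = plan.test_indices[fold]
                tr = plan.train_indices(fold, 120)
                table = PairFeatureTable(X[tr], np.zeros((tr.size, 2), int), y[tr])
                model = fit_forest(table, n_trees=25, seed=seed)
                scores[te] = model.predict_proba(X[te])
            aurocs.append(roc_auc(scores, y))
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_matches_sklearn_on_shared_task(self, rng):
        """Independent cross-check: comparable held-out accuracy to sklearn's
        forest on the same data (same number of trees)."""
        from sklearn.ensemble import RandomForestClassifier

        X = rng.standard_normal((300, 5))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        Xte = rng.standard_normal((200, 5))
        yte = ((Xte[:, 0] > 0) ^ (Xte[:, 1] > 0)).astype(int)
        table = PairFeatureTable(X, np.zeros((300, 2), int), y)
        ours = fit_forest(table, n_trees=40, seed=2,
                          params=TreeParams(max_features="sqrt"))
        acc_ours = np.mean((ours.predict_proba(Xte) >= 0.5) == yte)
        sk = RandomForestClassifier(n_estimators=40, random_state=2).fit(X, y)
        acc_sk = sk.score(Xte, yte)
        assert acc_ours > 0.8
        assert abs(acc_ours - acc_sk) < 0.1


class TestPairFeatures:
    def test_concat_layout(self):
        Yp = np.array([[1.0, 2], [3, 4]])
        Yr = np.array([[5.0, 6]])
        out = pair_features(Yp, Yr, [[1, 0]])
        assert np.array_equal(out, [[3, 4, 5, 6]])

    def test_sum_encoding(self):
        Yp = np.array([[1.0, 2]])
        Yr = np.array([[5.0, 6]])
        assert np.array_equal(pair_features(Yp, Yr, [[0, 0]], "sum"), [[6, 8]])

    def test_predict_scores_shape_and_range(self, rng):
        Yp, Yr = rng.standard_normal((6, 3)), rng.standard_normal((4, 3))
        pairs = np.array([[i, j] for i in range(6) for j in range(4)])
        labels = rng.integers(0, 2, size=24)
        labels[:2] = [0, 1]
        table = PairFeatureTable(pair_features(Yp, Yr, pairs), pairs, labels)
        model = fit_forest(table, n_trees=5, seed=0)
        sm = predict_scores(model, Yp, Yr, list("abcdef"), list("wxyz"))
        assert sm.values.shape == (6, 4)
        assert (sm.values >= 0).all() and (sm.values <= 1).all()

    def test_width_mismatch_rejected(self, rng):
        Yp, Yr = rng.standard_normal((2, 3)), rng.standard_normal((2, 3))
        pairs = np.array([[0, 0], [1, 1]])
        table = PairFeatureTable(pair_features(Yp, Yr, pairs), pairs, [0, 1])
        model = fit_forest(table, n_trees=2, seed=0)
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(np.zeros((2, 5)))
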