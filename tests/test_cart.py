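import itertools

import numpy as np
import pytest

from threetrees import (
    best_split,
    grow_cart,
    node_risk,
    predict_tree,
    prune_cost_complexity,
)
from threetrees.tree import Node

from conftest import xor_dataset


def brute_force_best_split(X, y, nmin, n_total=None):
    """Independent exhaustive scan over all midpoint splits of every column."""
    if n_total is None:
        n_total = len(y)
    best = None
    for var in range(X.shape[1]):
        values = np.unique(X[:, var])
        for a, b in zip(values[:-1], values[1:]):
            s = 0.5 * (a + b)
            left = X[:, var] <= s
            if left.sum() < nmin or (~left).sum() < nmin:
                continue
            gain = (
                node_risk(y, n_total)
                - node_risk(y[left], n_total)
                - node_risk(y[~left], n_total)
            )
            if best is None or gain > best[0] + 1e-12:
                best = (gain, var, s)
    if best is None or best[0] <= 0:
        return None
    return best


class TestNodeRisk:
    def test_constant_response_has_zero_risk(self):
        assert node_risk(np.full(7, 3.3)) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self):
        # y = (0, 2) over the whole sample: deviations +-1, N = 2 -> risk 1
        assert node_risk(np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_children_never_exceed_parent(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.normal(size=25)
            cut = rng.integers(1, 24)
            parent = node_risk(y, 25)
            child = node_risk(y[:cut], 25) + node_risk(y[cut:], 25)
            assert child <= parent + 1e-12

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            node_risk(np.array([]))


class TestBestSplit:
    def test_hand_example_step(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        rule, gain = best_split(X, y, [0], nmin=1)
        assert rule.threshold == pytest.approx(2.5)
        assert gain == pytest.approx(25.0)  # N = 4

    def test_constant_target_gives_no_split(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        assert best_split(X, np.zeros(20), [0], nmin=1) is None

    def test_tie_breaks_to_lowest_variable_then_threshold(self):
        # two identical covariates -> equal max gain on both; var 0 must win
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, x])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        rule, _ = best_split(X, y, [0, 1], nmin=1)
        assert rule.variable == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        X = np.column_stack(
            [rng.normal(size=n), rng.integers(0, 2, n).astype(float), rng.normal(size=n)]
        )
        y = rng.normal(size=n) + 2.0 * (X[:, 0] > 0)
        nmin = int(rng.integers(1, 4))
        oracle = brute_force_best_split(X, y, nmin)
        found = best_split(X, y, [0, 1, 2], nmin=nmin)
        if oracle is None:
            assert found is None
        else:
            gain_o, var_o, s_o = oracle
            rule, gain = found
            assert gain == pytest.approx(gain_o, rel=1e-10)
            assert rule.variable == var_o
            assert rule.threshold == pytest.approx(s_o)


class TestGrowCart:
    def test_maxdepth_bounds_leaves(self, m1_split):
        _, _, train, _ = m1_split
        tree = grow_cart(train.X, train.y, maxdepth=3, nmin=10, cp=0.0)
        assert tree.n_leaves <= 8 and tree.depth <= 3

    def test_large_cp_gives_root_only_tree(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = X[:, 0] + rng.normal(size=100)
        assert grow_cart(X, y, maxdepth=3, nmin=5, cp=1.0).n_leaves == 1

    def test_maxdepth_zero_returns_global_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 1))
        y = rng.normal(size=30)
        tree = grow_cart(X, y, maxdepth=0, nmin=1)
        assert tree.n_leaves == 1
        np.testing.assert_allclose(tree.predict(X), np.full(30, y.mean()))

    def test_xor_recovered_at_depth_two(self):
        X, y = xor_dataset(0)
        tree = grow_cart(X, y, maxdepth=2, nmin=5, cp=0.0)
        if tree.n_leaves == 4:
            # the four cell means are recovered
            pred = tree.predict(X)
            for a in (0, 1):
                for b in (0, 1):
                    cell = (X[:, 0] == a) & (X[:, 1] == b)
                    np.testing.assert_allclose(
                        pred[cell], np.full(cell.sum(), y[cell].mean())
                    )

    def test_training_mse_monotone_in_depth_and_cp(self, m1_split):
        _, _, train, _ = m1_split
        X, y = train.X, train.y

        def mse(tree):
            return float(np.mean((y - tree.predict(X)) ** 2))

        by_depth = [mse(grow_cart(X, y, maxdepth=d, nmin=10, cp=0.0)) for d in range(4)]
        assert all(b <= a + 1e-12 for a, b in zip(by_depth, by_depth[1:]))
        by_cp = [mse(grow_cart(X, y, maxdepth=3, nmin=10, cp=c)) for c in (0.1, 0.01, 0.0)]
        assert all(b <= a + 1e-12 for a, b in zip(by_cp, by_cp[1:]))

    def test_partition_property(self, m2_split):
        _, _, train, _ = m2_split
        C = np.column_stack([train.X, train.Z])
        tree = grow_cart(C, train.y, maxdepth=3, nmin=10)
        routed = tree.route(C)
        assert routed.min() >= 0 and routed.max() == tree.n_leaves - 1
        counts = np.bincount(routed, minlength=tree.n_leaves)
        assert counts.sum() == train.n_total and (counts >= 10).all()


def enumerate_pruned_subtrees(node):
    """All pruned subtrees of a node as (risk, n_leaves) pairs."""
    collapsed = (node.risk, 1)
    if node.is_leaf:
        return [collapsed]
    out = [collapsed]
    for lr, ll in enumerate_pruned_subtrees(node.left):
        for rr, rl in enumerate_pruned_subtrees(node.right):
            out.append((lr + rr, ll + rl))
    return out


class TestPruning:
    @pytest.fixture()
    def six_leaf_tree(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 3))
        y = (
            2.0 * (X[:, 0] > 0)
            + 1.0 * (X[:, 1] > 0.5)
            - 1.5 * (X[:, 2] > -0.3)
            + rng.normal(0, 0.4, 300)
        )
        tree = grow_cart(X, y, maxdepth=3, nmin=20, cp=0.0)
        assert tree.n_leaves >= 6
        return tree

    def test_alpha_zero_leaves_tree_unchanged(self, six_leaf_tree):
        assert prune_cost_complexity(six_leaf_tree, 0.0).n_leaves == six_leaf_tree.n_leaves

    def test_huge_alpha_collapses_to_root(self, six_leaf_tree):
        assert prune_cost_complexity(six_leaf_tree, 1e9).n_leaves == 1

    def test_matches_exhaustive_subtree_minimisation(self, six_leaf_tree):
        candidates = enumerate_pruned_subtrees(six_leaf_tree.root)
        for alpha in np.linspace(0.0, 2.0, 21):
            best = min(r + alpha * m for r, m in candidates)
            pruned = prune_cost_complexity(six_leaf_tree, float(alpha))
            cost = pruned.training_risk() + alpha * pruned.n_leaves
            assert cost == pytest.approx(best, abs=1e-10)

    def test_nested_over_increasing_alpha(self, six_leaf_tree):
        sizes = [
            prune_cost_complexity(six_leaf_tree, a).n_leaves
            for a in np.linspace(0.0, 3.0, 31)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))


class TestPredict:
    def test_training_mse_at_most_target_variance(self, m1_split):
        _, _, train, _ = m1_split
        tree = grow_cart(train.X, train.y, maxdepth=3, nmin=10)
        mse = np.mean((train.y - predict_tree(tree, train.X)) ** 2)
        assert mse <= np.var(train.y) + 1e-12

    def test_routing_agrees_with_independent_interpreter(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 3))
        y = X[:, 0] ** 2 + rng.normal(size=400)
        tree = grow_cart(X, y, maxdepth=3, nmin=15)
        X_new = rng.normal(size=(1000, 3))

        def interpret(row, node):
            while not node.is_leaf:
                node = (
                    node.left
                    if row[node.split.variable] <= node.split.threshold
                    else node.right
                )
            return node.mean

        expected = np.array([interpret(r, tree.root) for r in X_new])
        np.testing.assert_allclose(tree.predict(X_new), expected)

    def test_serialization_roundtrip_preserves_predictions(self):
        from threetrees.tree import TreeModel

        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 2))
        y = 3 * (X[:, 0] > 0) + rng.normal(size=200)
        tree = grow_cart(X, y, maxdepth=2, nmin=10, feature_names=["a", "b"])
        back = TreeModel.from_json(tree.to_json())
        np.testing.assert_allclose(back.predict(X), tree.predict(X))
        assert back.engine == "cart"
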