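import numpy as np
import pytest

from threetrees import (
    ThreeTreesConfig,
    encode_regions,
    fit_3trees,
    fit_mixed,
    grow_cart,
    make_setting,
    predict_3trees,
    predict_mixed,
    select_trees,
    split_within_cluster,
)
from threetrees.data import HierarchicalDataset


@pytest.fixture(scope="module")
def m1_cart_fit(m1_split):
    _, _, train, _ = m1_split
    return train, fit_3trees(train, ThreeTreesConfig(engine="cart", cp=0.0, seed=1))


class TestEncodeRegions:
    def test_root_only_tree_emits_no_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        tree = grow_cart(X, np.zeros(50), maxdepth=3, nmin=5)
        D, names = encode_regions(tree, X)
        assert D.shape == (50, 0) and names == []

    def test_reference_coding_shape_and_row_sums(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        y = 2 * (X[:, 0] > 0) + 3 * (X[:, 1] > 0) + rng.normal(0, 0.2, 300)
        tree = grow_cart(X, y, maxdepth=2, nmin=20)
        D, names = encode_regions(tree, X)
        m = tree.n_leaves
        assert D.shape == (300, m - 1) and len(names) == m - 1
        assert set(np.unique(D.sum(axis=1))) <= {0.0, 1.0}

    def test_columns_match_routing_one_hot(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + (X[:, 1] > 0) * 2 + rng.normal(size=200)
        tree = grow_cart(X, y, maxdepth=3, nmin=10)
        D, _ = encode_regions(tree, X)
        routed = tree.route(X)
        onehot = np.eye(tree.n_leaves)[routed][:, 1:]
        np.testing.assert_array_equal(D, onehot)


class TestSelectTrees:
    def test_loop_contract_and_monotone_trajectory(self, m1_split):
        _, _, train, _ = m1_split
        cfg = ThreeTreesConfig(engine="cart", cp=0.0, max_backfit_iterations=20, seed=3)
        t1, t2, t3, traj = select_trees(train, cfg)
        assert 1 <= len(traj) <= 20
        # after the first two iterations the MSE may not rise beyond tolerance
        for a, b in zip(traj[1:], traj[2:]):
            assert b - a <= cfg.mse_tolerance * a

    def test_covariate_space_discipline(self):
        for seed in range(3):
            data, _ = make_setting("M2", "high", "high", 40, 30, seed=seed)
            train, _ = split_within_cluster(data, 0.5, seed=seed)
            cfg = ThreeTreesConfig(engine="cart", cp=0.0, seed=seed)
            t1, t2, t3, _ = select_trees(train, cfg)
            p1 = train.p1
            assert all(v < p1 for v in t1.split_variables())
            assert all(v >= p1 for v in t2.split_variables())

    def test_linear_truth_keeps_combined_fit_near_plain_lmm(self):
        """On purely linear data the trees add little; the combined training
        fit tracks the plain mixed model within a few percent."""
        ratios = []
        for seed in range(5):
            data, _ = make_setting("M1", "high", "high", 70, 50, seed=100 + seed)
            train, _ = split_within_cluster(data, 0.5, seed=seed)
            cfg = ThreeTreesConfig(engine="ctree", seed=seed)
            *_, traj = select_trees(train, cfg)
            W = np.column_stack([np.ones(train.n_total), train.X, train.Z])
            lmm = fit_mixed(W, train.y, train.cluster)
            pred = predict_mixed(lmm, W, train.cluster, include_random=True)
            lmm_mse = np.mean((train.y - pred) ** 2)
            ratios.append(traj[-1] / lmm_mse)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_m2_interaction_splits_recovered(self):
        """The step structure at X1>0 and the Z3 cell shift are found by the
        selected trees in semilinear data."""
        found_x1 = found_z3 = 0
        for seed in range(5):
            data, _ = make_setting("M2", "high", "high", 70, 50, seed=200 + seed)
            train, _ = split_within_cluster(data, 0.5, seed=seed)
            t1, t2, t3, _ = select_trees(
                train, ThreeTreesConfig(engine="cart", cp=0.0, seed=seed)
            )
            p1 = train.p1
            x1_thresholds = [
                n.split.threshold
                for t in (t1, t3)
                for n in t.internal_nodes()
                if n.split.variable == 0
            ]
            found_x1 += any(abs(s) < 0.25 for s in x1_thresholds)
            z3_vars = [
                v for t in (t2, t3) for v in t.split_variables() if v == p1 + 2
            ]
            found_z3 += len(z3_vars) > 0
        assert found_x1 >= 4 and found_z3 >= 4


class TestFit3Trees:
    def test_variance_components_recovered_on_m1(self, m1_cart_fit):
        _, fit = m1_cart_fit
        assert fit.final_fit.sigma_u2 == pytest.approx(3.0, abs=1.0)
        assert fit.final_fit.sigma_e2 == pytest.approx(1.0, abs=0.25)

    def test_fit_metadata(self, m1_cart_fit):
        _, fit = m1_cart_fit
        assert fit.n_iterations == len(fit.mse_trajectory)
        assert fit.n_iterations <= fit.config.max_backfit_iterations
        assert isinstance(fit.converged, bool)
        # coefficient table covers linear and tree-region terms
        terms = list(fit.final_fit.params.index)
        assert "(Intercept)" in terms and "x1" in terms
        assert any(t.startswith("T1.R") or t.startswith("T3.R") for t in terms)

    def test_evtree_produces_fewer_regions_than_cart_on_m2(self):
        """The penalised evolutionary search prefers compact trees; greedy
        CART at cp=0 grows to the depth limit."""
        from threetrees.evaluate import STUDY_EVOLUTION

        cart_sizes, ev_sizes = [], []
        for seed in range(3):
            data, _ = make_setting("M2", "high", "high", 40, 30, seed=300 + seed)
            train, _ = split_within_cluster(data, 0.5, seed=seed)
            cart = fit_3trees(train, ThreeTreesConfig(engine="cart", cp=0.0, seed=seed))
            ev = fit_3trees(
                train,
                ThreeTreesConfig(engine="evtree", evolution=STUDY_EVOLUTION, seed=seed),
            )
            cart_sizes.append(sum(t.n_leaves for t in cart.trees))
            ev_sizes.append(sum(t.n_leaves for t in ev.trees))
        assert np.median(ev_sizes) < np.median(cart_sizes)

    def test_serialization_roundtrip(self, m1_cart_fit):
        import json

        _, fit = m1_cart_fit
        bundle = json.loads(fit.to_json())
        assert len(bundle["trees"]) == 3
        assert bundle["sigma_u2"] == pytest.approx(fit.final_fit.sigma_u2)
        assert bundle["coefficients"]["term"] == list(fit.final_fit.params.index)


class TestPredict3Trees:
    def test_random_effects_lower_training_error_at_high_icc(self, m1_cart_fit):
        train, fit = m1_cart_fit
        fixed = predict_3trees(fit, train)
        mixed = predict_3trees(fit, train, include_random=True)
        assert np.mean((train.y - mixed) ** 2) < np.mean((train.y - fixed) ** 2)

    def test_degenerate_trees_reduce_to_linear_mixed_model(self):
        # constant response in the trees' targets: all trees are root-only
        rng = np.random.default_rng(0)
        J, nj = 20, 12
        cl = np.repeat(np.arange(J), nj)
        X = rng.normal(size=(J * nj, 2))
        Z = np.repeat(rng.normal(size=(J, 1)), nj, axis=0)
        y = 1.0 + X @ [2.0, 0.0] + Z[:, 0] + np.repeat(rng.normal(0, 1, J), nj)
        y = y + rng.normal(0, 0.5, J * nj)
        data = HierarchicalDataset(y=y, cluster=cl, X=X, Z=Z)
        fit = fit_3trees(
            data, ThreeTreesConfig(engine="ctree", alpha=1e-9, maxdepth=0, seed=0)
        )
        assert all(t.n_leaves == 1 for t in fit.trees)
        W = np.column_stack([np.ones(len(y)), X, Z])
        lmm = fit_mixed(W, y, cl)
        pred_tt = predict_3trees(fit, data, include_random=True)
        pred_lmm = predict_mixed(lmm, W, cl, include_random=True)
        np.testing.assert_allclose(pred_tt, pred_lmm, atol=1e-6)

    def test_invariant_to_cluster_relabelling(self):
        data, _ = make_setting("M1", "high", "high", 15, 10, seed=6)
        relabeled = HierarchicalDataset(
            y=data.y,
            cluster=np.array([f"site-{c}" for c in data.cluster]),
            X=data.X,
            Z=data.Z,
        )
        cfg = ThreeTreesConfig(engine="cart", cp=0.0, seed=4)
        f1 = fit_3trees(data, cfg)
        f2 = fit_3trees(relabeled, cfg)
        np.testing.assert_allclose(
            predict_3trees(f1, data, include_random=True),
            predict_3trees(f2, relabeled, include_random=True),
            atol=1e-8,
        )

    def test_unseen_cluster_gets_zero_blup(self, m1_cart_fit):
        train, fit = m1_cart_fit
        sub = train.subset(np.arange(10))
        other = HierarchicalDataset(
            y=sub.y, cluster=np.full(10, "brand-new"), X=sub.X, Z=sub.Z
        )
        np.testing.assert_allclose(
            predict_3trees(fit, other, include_random=True),
            predict_3trees(fit, other, include_random=False),
        )
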