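"""Tree-structure analytics against hand enumeration and planted truth."""

import numpy as np
import pytest
from scipy import stats

from nanophyto.forest import ForestSpec, ForestStructure, FittedForest, fit_forest
from nanophyto.interpret import (
    interaction_network,
    multiway_importance,
    partial_dependence,
    shapley_drivers,
    similarity_network,
)
from nanophyto.model import PlantResponseForest
from nanophyto.simulate import EffectSpec, generate_experiment_table


def _as_fitted(structure, X, y=None):
    y = np.zeros(len(X)) if y is None else y
    return FittedForest(structure, ForestSpec(ntree=structure.ntree, seed=0), X, y)


class TestOracleEquivalence:
    """Exhaustive hand enumeration on the 2-tree / 6-row / 3-feature forest."""

    def test_cooccurrence_counts(self, oracle_forest):
        st, X = oracle_forest
        net = interaction_network(st, top_k=50)
        assert len(net.edges) == 1
        edge = net.edges.iloc[0]
        assert {edge.feature_a, edge.feature_b} == {"x0", "x1"}
        assert edge["count"] == 1

    def test_minimal_depths(self, oracle_forest):
        st, X = oracle_forest
        rep = multiway_importance(_as_fitted(st, X), seed=0)
        # x0: depth 0 in tree A, absent from tree B (max depth 1 -> 2)
        assert rep.loc["x0", "mean_minimal_depth"] == pytest.approx(1.0)
        # x1: depth 1 in tree A, absent from tree B -> 2
        assert rep.loc["x1", "mean_minimal_depth"] == pytest.approx(1.5)
        # x2: absent from tree A (max depth 2 -> 3), depth 0 in tree B
        assert rep.loc["x2", "mean_minimal_depth"] == pytest.approx(1.5)

    def test_purity_increases(self, oracle_forest):
        st, X = oracle_forest
        rep = multiway_importance(_as_fitted(st, X), seed=0)
        # tree A root on x0: 6*5 - 3*2 - 3*1 = 21
        assert rep.loc["x0", "node_purity_increase"] == pytest.approx(21.0)
        # tree A node on x1: 3*2 - 2*0.5 - 1*0 = 5
        assert rep.loc["x1", "node_purity_increase"] == pytest.approx(5.0)
        # tree B root on x2: 6*4 - 4*1 - 2*0 = 20
        assert rep.loc["x2", "node_purity_increase"] == pytest.approx(20.0)

    def test_split_count_p_values(self, oracle_forest):
        st, X = oracle_forest
        rep = multiway_importance(_as_fitted(st, X), seed=0)
        # each feature: 1 of 3 splits, null probability 1/3
        # one-sided P(X >= 1), X ~ Binomial(3, 1/3) = 1 - (2/3)^3 = 19/27
        for col in ("x0", "x1", "x2"):
            assert rep.loc[col, "split_count"] == 1
            assert rep.loc[col, "p_value"] == pytest.approx(19 / 27)

    def test_proximity_matrix_by_hand(self, oracle_forest):
        st, X = oracle_forest
        sim = similarity_network(_as_fitted(st, X), threshold_multiple=1.0)
        expected = np.array([
            [1.0, 0.5, 0.5, 0.0, 0.5, 0.5],
            [0.5, 1.0, 0.5, 0.0, 0.0, 0.5],
            [0.5, 0.5, 1.0, 0.5, 0.0, 1.0],
            [0.0, 0.0, 0.5, 1.0, 0.5, 0.5],
            [0.5, 0.0, 0.0, 0.5, 1.0, 0.0],
            [0.5, 0.5, 1.0, 0.5, 0.0, 1.0],
        ])
        np.testing.assert_allclose(sim.proximity, expected)

    def test_forest_predictions_by_hand(self, oracle_forest):
        st, X = oracle_forest
        # row 0: tree A leaf -1, tree B leaf 0 -> -0.5
        # row 3: tree A leaf +2, tree B leaf +3 -> +2.5
        np.testing.assert_allclose(st.predict(X[[0, 3]]), [-0.5, 2.5])

    def test_depth1_trees_give_empty_network(self, oracle_forest):
        st, _ = oracle_forest
        single = ForestStructure([st.trees[1]], [st.inbag[1]], 6,
                                 st.columns, "stub")
        net = interaction_network(single, top_k=50)
        assert len(net.edges) == 0


class TestImportanceRecovery:
    def test_dominant_feature_ranks_first_by_mse_increase(self):
        hits = 0
        for seed in range(10):
            spec = EffectSpec(
                n=400,
                effects={"total_dose": -40.0, "duration": 20.0},
                interactions=[("total_dose", "duration", 15.0)],
                noise_sd=5.0,
                seed=200 + seed,
            )
            table = generate_experiment_table(spec)
            res = PlantResponseForest.from_dataframe(
                table, "dry_weight", ForestSpec(ntree=60, seed=seed)
            ).fit()
            rep = res.importance(seed=seed)
            if rep["mse_increase"].idxmax() == "total_dose":
                hits += 1
        assert hits >= 9

    def test_planted_features_fill_top_ranks(self, planted_results):
        rep = planted_results.importance(seed=0)
        top2 = set(rep["mse_increase"].nlargest(2).index)
        assert top2 == {"total_dose", "duration"}

    def test_noise_feature_p_value_usually_insignificant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = rng.uniform(-1, 1, size=(150, 6))
            y = 3.0 * X[:, 0] + rng.normal(0, 0.3, 150)
            forest = fit_forest(X, y, ForestSpec(ntree=30, seed=seed))
            rep = multiway_importance(forest, seed=seed)
            if rep.loc["x5", "p_value"] > 0.05:
                hits += 1
        assert hits >= 8

    def test_constant_column_flagged_zero(self, small_xy):
        X, y = small_xy
        Xc = X.copy()
        Xc[:, 4] = 1.0
        forest = fit_forest(Xc, y, ForestSpec(ntree=15, seed=0))
        rep = multiway_importance(forest, seed=0)
        assert rep.loc["x4", "constant"]
        assert rep.loc["x4", "mse_increase"] == 0.0

    def test_purity_conservation(self, small_xy):
        """Summed per-feature purity equals total forest impurity reduction."""
        X, y = small_xy
        forest = fit_forest(X, y, ForestSpec(ntree=10, seed=1))
        rep = multiway_importance(forest, seed=0)
        total = 0.0
        for tree in forest.structure.trees:
            internal = ~tree.is_leaf()
            total += float(np.sum(
                tree.n_node[internal] * tree.impurity[internal]
                - tree.n_node[tree.left[internal]] * tree.impurity[tree.left[internal]]
                - tree.n_node[tree.right[internal]] * tree.impurity[tree.right[internal]]
            ))
        assert rep["node_purity_increase"].sum() == pytest.approx(total, rel=1e-9)


class TestInteractionNetwork:
    def test_edge_cap(self, planted_results):
        net = planted_results.interaction_network(top_k=5)
        assert len(net.edges) <= 5

    def test_counts_symmetric_and_bounded(self, planted_results):
        net = planted_results.interaction_network(top_k=50)
        assert (net.edges["count"] <= planted_results.forest.ntree).all()
        pairs = {frozenset((r.feature_a, r.feature_b))
                 for _, r in net.edges.iterrows()}
        assert len(pairs) == len(net.edges)          # no duplicated pair
        assert all(len(p) == 2 for p in pairs)       # no self-edge

    def test_planted_interaction_in_top_edges(self):
        hits = 0
        for seed in range(10):
            spec = EffectSpec(
                n=400,
                effects={"total_dose": -40.0, "duration": 20.0},
                interactions=[("total_dose", "duration", 15.0)],
                noise_sd=5.0,
                seed=400 + seed,
            )
            table = generate_experiment_table(spec)
            res = PlantResponseForest.from_dataframe(
                table, "dry_weight",
                ForestSpec(ntree=100, seed=seed, max_depth=3),
            ).fit()
            net = res.interaction_network(top_k=5)
            pairs = [frozenset((r.feature_a, r.feature_b))
                     for _, r in net.edges.iterrows()]
            if frozenset(("total_dose", "duration")) in pairs:
                hits += 1
        assert hits >= 8

    def test_graph_export(self, planted_results, tmp_path):
        net = planted_results.interaction_network(top_k=10)
        g = net.to_networkx()
        assert g.number_of_edges() == len(net.edges)
        net.write_graphml(tmp_path / "net.graphml")
        net.write_csv(tmp_path / "net.csv")
        assert (tmp_path / "net.graphml").exists()


class TestSimilarityNetwork:
    def test_diagonal_and_range(self, planted_results):
        sim = planted_results.similarity_network()
        prox = sim.proximity
        np.testing.assert_allclose(np.diag(prox), 1.0)
        assert (prox >= 0).all() and (prox <= 1).all()
        np.testing.assert_allclose(prox, prox.T)

    def test_duplicated_row_has_unit_proximity(self, small_xy):
        X, y = small_xy
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        forest = fit_forest(Xd, yd, ForestSpec(ntree=20, seed=0))
        sim = similarity_network(forest)
        assert sim.proximity[0, len(Xd) - 1] == pytest.approx(1.0)

    def test_two_regimes_cluster_internally(self):
        """Two well-separated response regimes: within-regime proximity
        exceeds between-regime proximity."""
        rng = np.random.default_rng(5)
        n = 120
        X = rng.uniform(-1, 1, size=(n, 4))
        regime = (X[:, 0] > 0).astype(int)
        y = np.where(regime == 1, 5.0, -5.0) + rng.normal(0, 0.2, n)
        forest = fit_forest(X, y, ForestSpec(ntree=30, seed=0))
        sim = similarity_network(forest)
        same = sim.proximity[np.ix_(regime == 1, regime == 1)]
        cross = sim.proximity[np.ix_(regime == 1, regime == 0)]
        assert same.mean() > cross.mean()

    def test_cluster_density_summary(self, planted_results):
        sim = planted_results.similarity_network()
        classes = planted_results.model.records["np_type"].tolist()
        dens = sim.cluster_density(classes)
        assert (dens["density"] >= 0).all() and (dens["density"] <= 1).all()


class TestPartialDependence:
    def test_grid_step_counts(self, planted_results):
        grid = planted_results.partial_dependence(["total_dose"], [(0, 50, 100)])
        assert grid.shape == (100,)
        assert grid.axes[0][0] == 0.0
        assert grid.axes[0][1] - grid.axes[0][0] == pytest.approx(0.5)

    def test_two_way_grid_full_cross_product(self, planted_results):
        grid = planted_results.partial_dependence(
            ["total_dose", "duration"], [(0, 50, 25), (0, 50, 25)]
        )
        assert grid.shape == (25, 25)
        assert len(grid.to_frame()) == 625

    def test_constant_model_gives_flat_surface(self, oracle_forest):
        st, X = oracle_forest
        const_tree = st.trees[0]
        flat = ForestStructure(
            [type(const_tree)(
                feature=np.array([-1]), threshold=np.array([0.0]),
                left=np.array([-1]), right=np.array([-1]),
                value=np.array([2.5]), impurity=np.array([0.0]),
                n_node=np.array([6.0]),
            )],
            [np.ones(6, dtype=int)], 6, st.columns, "const",
        )
        grid = partial_dependence(_as_fitted(flat, X), ["x0"], [(0, 1, 10)])
        np.testing.assert_allclose(grid.values, 2.5)

    def test_null_feature_is_flat(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, size=(300, 3))
        y = 2.0 * X[:, 0]
        forest = fit_forest(X, y, ForestSpec(ntree=20, mtry=3, seed=0))
        grid = partial_dependence(forest, ["x1"], [(-1, 1, 20)], seed=0)
        # zero-gain tie splits may still touch x1; flat within MC tolerance
        # relative to the response range of 4
        assert np.ptp(grid.values) < 0.02

    def test_additive_slope_recovered(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, size=(600, 3))
        y = 2.0 * X[:, 0] + 1.0 * X[:, 1]
        forest = fit_forest(X, y, ForestSpec(ntree=60, mtry=3, seed=0))
        # interior grid avoids edge bias of tree ensembles
        grid = partial_dependence(forest, ["x0"], [(-0.6, 0.6, 40)], seed=0)
        slope = stats.linregress(grid.axes[0], grid.values).slope
        assert slope == pytest.approx(2.0, rel=0.10)

    def test_unknown_feature_rejected(self, planted_results):
        with pytest.raises(KeyError):
            planted_results.partial_dependence(["warp"], [(0, 1, 5)])


@pytest.fixture(scope="module")
def env_forest():
    rng = np.random.default_rng(31)
    X = rng.uniform(-1, 1, size=(300, 5))
    y = 5.0 * X[:, 3] + 0.5 * X[:, 4] + rng.normal(0, 0.1, 300)
    return fit_forest(X, y, ForestSpec(ntree=30, seed=0)), X


class TestShapleyDrivers:

    def test_singleton_candidate_gets_everything(self, env_forest):
        forest, X = env_forest
        out = shapley_drivers(forest, X[:5], ["x3"], max_background=40, seed=0)
        np.testing.assert_allclose(
            out["x3"] + out["baseline"], out["prediction"], atol=1e-9
        )
        assert (out["main_driver"] == "x3").all()

    def test_additivity_axiom_exact_mode(self, env_forest):
        forest, X = env_forest
        cands = ["x0", "x1", "x2", "x3"]
        out = shapley_drivers(forest, X[:4], cands, max_background=30, seed=0)
        total = out[cands].sum(axis=1) + out["baseline"]
        np.testing.assert_allclose(total, out["prediction"], atol=1e-6)

    def test_varying_feature_is_main_driver(self, env_forest):
        """Records differing only in the signal feature among candidates."""
        forest, X = env_forest
        base = X.mean(axis=0)
        records = np.tile(base, (40, 1))
        records[:, 3] = np.linspace(-0.95, 0.95, 40)
        out = shapley_drivers(forest, records, ["x0", "x1", "x2", "x3"],
                              max_background=40, seed=0)
        share = (out["main_driver"] == "x3").mean()
        assert share >= 0.95

    def test_sampled_mode_additivity(self, env_forest):
        """Above 6 candidates the sampler still satisfies additivity."""
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(150, 8))
        y = 4.0 * X[:, 0] - 3.0 * X[:, 7]
        forest = fit_forest(X, y, ForestSpec(ntree=15, seed=0))
        cands = [f"x{i}" for i in range(8)]
        out = shapley_drivers(forest, X[:2], cands, max_background=25,
                              n_permutations=32, seed=0)
        total = out[cands].sum(axis=1) + out["baseline"]
        np.testing.assert_allclose(total, out["prediction"], atol=1e-9)

    def test_empty_candidate_set_rejected(self, env_forest):
        forest, X = env_forest
        with pytest.raises(ValueError):
            shapley_drivers(forest, X[:1], [])
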