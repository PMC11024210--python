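"""Diffusion maps, bootstrapped-MST distances, MDS, principal trees,
projection and depth-associated genes."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from qglia.ordering import TreeDistance, bootstrap_mst_distances, diffusion_map, mds_embed
from qglia.principal_graph import (
    depth_associated_genes,
    diameter_root,
    fit_principal_graph,
    project_and_order,
    prune_same_cluster_paths,
)


class TestDiffusionMap:
    def test_curve_parameter_recovered(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, 300))
        X = np.c_[np.cos(2 * t), np.sin(2 * t), t] + rng.normal(0, 0.02, (300, 3))
        dm = diffusion_map(X, n_components=2)
        rho = spearmanr(dm[:, 0], t).statistic
        assert abs(rho) >= 0.9

    def test_duplicated_cell_identical_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        X[10] = X[3]
        dm = diffusion_map(X, n_components=3)
        assert np.allclose(dm[10], dm[3], atol=1e-8)

    def test_zero_components_error(self):
        with pytest.raises(ValueError):
            diffusion_map(np.random.default_rng(2).normal(size=(20, 3)), n_components=0)


class TestBootstrapMst:
    def test_collinear_path_additivity(self):
        pts = np.array([[0.0, 0], [1.0, 0], [3.0, 0]])
        td = bootstrap_mst_distances(pts, n_trees=1, frac=1.0, seed=0)
        assert td.D[0, 2] == pytest.approx(td.D[0, 1] + td.D[1, 2])

    def test_single_tree_matches_exhaustive_spanning_tree_oracle(self):
        from qglia.evaluation import mst_distance_exactness

        out = mst_distance_exactness(seed=3)
        assert out["max_abs_diff"] < 1e-12

    def test_metric_properties(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(40, 3))
        td = bootstrap_mst_distances(pts, n_trees=50, frac=2 / 3, seed=5)
        assert np.allclose(td.D, td.D.T)
        assert np.all(np.diag(td.D) == 0)
        assert np.all(td.D >= 0)
        assert np.all(np.isfinite(td.D))
        # tree distances dominate Euclidean distances
        assert np.all(td.D + 1e-9 >= squareform(pdist(pts)) - 1e-9)

    def test_parameter_validation(self):
        pts = np.random.default_rng(6).normal(size=(10, 2))
        with pytest.raises(ValueError):
            bootstrap_mst_distances(pts, n_trees=0)
        with pytest.raises(ValueError):
            bootstrap_mst_distances(pts, n_trees=1, frac=0.1)  # frac*n < 2


class TestMds:
    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        D = squareform(pdist(X))
        coords, stress = mds_embed(TreeDistance(D=D, copresence=np.ones_like(D, dtype=int), n_trees=1, subsample_frac=1.0), dim=3)
        # Procrustes: distances match up to rigid transform
        assert np.allclose(squareform(pdist(coords)), D, atol=1e-8)
        assert stress < 1e-8

    def test_dim_one_preserves_order(self):
        x = np.sort(np.random.default_rng(8).uniform(0, 10, 25))
        D = np.abs(x[:, None] - x[None, :])
        coords, _ = mds_embed(D, dim=1)
        c = coords[:, 0]
        assert np.all(np.diff(c) > 0) or np.all(np.diff(c) < 0)

    def test_rank_deficit_zero_padded(self):
        x = np.linspace(0, 1, 20)
        D = np.abs(x[:, None] - x[None, :])
        with pytest.warns(UserWarning):
            coords, _ = mds_embed(D, dim=3)
        assert np.allclose(coords[:, 1:], 0)


class TestPrincipalGraph:
    def test_line_yields_path(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(0, 1, 200)
        pts = np.c_[t, np.zeros(200), np.zeros(200)] + rng.normal(0, 0.01, (200, 3))
        g = fit_principal_graph(pts, max_nodes=20)
        deg = g.degrees()
        assert (deg >= 3).sum() == 0
        assert (deg == 1).sum() == 2
        # node order along the line is monotone
        order = np.argsort(g.nodes[:, 0])
        adj = {tuple(sorted(e)) for e in g.edges}
        for a, b in zip(order[:-1], order[1:]):
            assert (min(a, b), max(a, b)) in adj

    def test_y_shape_single_branch_node(self):
        rng = np.random.default_rng(10)
        arm = rng.uniform(0, 1, 300)
        b = rng.integers(0, 3, 300)
        dirs = np.array([[1, 0, 0], [-0.5, 0.87, 0], [-0.5, -0.87, 0]])
        pts = arm[:, None] * dirs[b] + rng.normal(0, 0.02, (300, 3))
        g = fit_principal_graph(pts, max_nodes=30)
        deg = g.degrees()
        assert (deg == 3).sum() == 1
        assert (deg > 3).sum() == 0

    def test_two_nodes_align_with_pc1(self):
        rng = np.random.default_rng(11)
        pts = np.c_[rng.normal(0, 3, 300), rng.normal(0, 0.3, 300), rng.normal(0, 0.3, 300)]
        g = fit_principal_graph(pts, max_nodes=2)
        seg = g.nodes[1] - g.nodes[0]
        cos = abs(seg[0]) / np.linalg.norm(seg)
        assert cos > 0.99

    def test_nonfinite_points_rejected(self):
        pts = np.zeros((50, 3))
        pts[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_principal_graph(pts, max_nodes=10)


class TestPruning:
    def _line_graph_with_spur(self):
        # hand-built: path 0-1-2-3-4 plus spur 2-5-6 looping back into the
        # middle cluster's territory
        from qglia.principal_graph import PrincipalGraph

        nodes = np.array(
            [[0, 0], [1, 0], [2, 0], [3, 0], [4, 0], [2.2, 0.5], [2.4, 1.0]], dtype=float
        )
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6)]
        return PrincipalGraph(nodes=nodes, edges=edges)

    def test_linear_graph_ordered_clusters_nothing_pruned(self):
        from qglia.principal_graph import PrincipalGraph

        nodes = np.c_[np.arange(5.0), np.zeros(5)]
        g = PrincipalGraph(nodes=nodes, edges=[(i, i + 1) for i in range(4)])
        pts = nodes.repeat(10, axis=0) + np.random.default_rng(12).normal(0, 0.05, (50, 2))
        labels = np.repeat([0, 0, 1, 2, 2], 10)
        out = prune_same_cluster_paths(g, pts, labels)
        assert len(out.edges) == 4

    def test_same_cluster_spur_removed(self):
        g = self._line_graph_with_spur()
        rng = np.random.default_rng(13)
        pts = np.vstack(
            [g.nodes[[0, 1]].repeat(15, axis=0), g.nodes[[2, 3, 4]].repeat(15, axis=0), g.nodes[[5, 6]].repeat(2, axis=0)]
        ) + rng.normal(0, 0.05, (79, 2))
        labels = np.array([0] * 30 + [1] * 45 + [1] * 4)  # minor spur in cluster 1
        out = prune_same_cluster_paths(g, pts, labels)
        assert out.n_nodes == 5
        assert (out.degrees() >= 3).sum() == 0

    def test_single_cluster_guard_keeps_graph(self):
        g = self._line_graph_with_spur()
        pts = g.nodes.repeat(5, axis=0)
        labels = np.zeros(len(pts), dtype=int)
        out = prune_same_cluster_paths(g, pts, labels)
        assert out.n_nodes >= 5  # at most the spur goes; never infinite pruning
        assert len(out.edges) == out.n_nodes - 1


class TestProjection:
    def _path_graph(self):
        from qglia.principal_graph import PrincipalGraph

        nodes = np.c_[np.arange(6.0), np.zeros(6)]
        return PrincipalGraph(nodes=nodes, edges=[(i, i + 1) for i in range(5)])

    def test_cell_at_node_gets_node_distance(self):
        g = self._path_graph()
        pts = g.nodes.copy()
        proj = project_and_order(g, pts, root=0)
        assert np.allclose(proj.pseudo_order, np.linspace(0, 1, 6), atol=1e-12)

    def test_root_reversal_reverses_ranks(self):
        g = self._path_graph()
        rng = np.random.default_rng(14)
        pts = np.c_[rng.uniform(0, 5, 80), rng.normal(0, 0.1, 80)]
        p1 = project_and_order(g, pts, root=0)
        p2 = project_and_order(g, pts, root=5)
        rho = spearmanr(p1.pseudo_order, p2.pseudo_order).statistic
        assert rho == pytest.approx(-1.0, abs=1e-9)

    def test_invalid_root(self):
        g = self._path_graph()
        with pytest.raises(ValueError):
            project_and_order(g, g.nodes, root=99)

    def test_planted_depth_recovered_small(self):
        """End-to-end pseudo-ordering at reduced size (400 cells, 100
        trees); the bound is looser than the full-size run because fewer
        bootstrapped trees leave more distance noise."""
        from qglia.evaluation import pseudo_order_eval

        out = pseudo_order_eval(seed=2, n_cells=400, n_trees=100, max_nodes=60)
        assert out["abs_spearman"] >= 0.85


class TestDepthGenes:
    def _fixture(self):
        from qglia.de import normalize_log
        from qglia.simulate import SimConfig, generate_trajectory_counts

        cfg = SimConfig(n_cells=500, n_genes=600, trajectory=True, seed=15)
        adata, truth = generate_trajectory_counts(cfg)
        return normalize_log(adata), list(adata.var_names), truth

    def test_planted_modules_recovered(self):
        logX, genes, truth = self._fixture()
        res = depth_associated_genes(logX, genes, truth.depth)
        sig = set(res[res["q"] < 0.05]["gene"])
        planted = set(truth.depth_genes["gene"])
        sens = len(sig & planted) / len(planted)
        assert sens >= 0.9

    def test_permuted_order_controls_fdr(self):
        logX, genes, truth = self._fixture()
        rng = np.random.default_rng(16)
        res = depth_associated_genes(logX, genes, rng.permutation(truth.depth))
        fpr = (res["q"] < 0.05).mean()
        assert fpr <= 1.5 * 0.05

    def test_rank_invariance_under_monotone_transform(self):
        logX, genes, truth = self._fixture()
        r1 = depth_associated_genes(logX, genes, truth.depth)
        r2 = depth_associated_genes(logX, genes, np.exp(3 * truth.depth))
        m = r1.merge(r2, on="gene")
        assert np.allclose(m["rho_x"], m["rho_y"], atol=1e-12)

    def test_constant_gene_null_result(self):
        rng = np.random.default_rng(17)
        logX = rng.normal(size=(100, 3))
        logX[:, 1] = 7.0
        res = depth_associated_genes(logX, ["a", "b", "c"], np.arange(100.0))
        row = res[res["gene"] == "b"].iloc[0]
        assert row["rho"] == 0.0
        assert row["p"] == 1.0
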