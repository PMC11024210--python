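"""Generator contracts: planted structure, conservation laws, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, spearmanr

from qglia.simulate import (
    SimConfig,
    generate_clone_table,
    generate_counts,
    generate_ortholog_table,
    generate_trajectory_counts,
    inject_doublets,
)


def test_empty_matrix():
    adata, truth = generate_counts(SimConfig(n_cells=0))
    assert adata.n_obs == 0
    assert truth.cluster_label.size == 0


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(lowq_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(libsize_mean=-1).validate()
    with pytest.raises(ValueError):
        SimConfig(n_genes=10, n_clusters=3, n_markers_per_cluster=5).validate()
    with pytest.raises(ValueError):
        SimConfig(trajectory=True, depth_module_size=0).validate()


def test_null_marker_effect_means_equal_across_clusters():
    cfg = SimConfig(n_cells=600, n_genes=400, n_clusters=3, marker_logfc=0.0, seed=1)
    adata, truth = generate_counts(cfg)
    X = adata.X.toarray()
    lib = X.sum(axis=1, keepdims=True)
    norm = X / lib
    for c, genes in truth.marker_sets.items():
        gi = [list(adata.var_names).index(g) for g in genes[:5]]
        in_c = truth.cluster_label == c
        m_in = norm[in_c][:, gi].mean()
        m_out = norm[~in_c][:, gi].mean()
        assert abs(np.log(m_in / m_out)) < 0.25  # within sampling error


def test_bimodal_ngene_modes_recovered_by_mixture():
    from sklearn.mixture import GaussianMixture

    cfg = SimConfig(n_cells=1000, lowq_fraction=0.1, seed=3)
    adata, truth = generate_counts(cfg)
    ngene = np.asarray((adata.X > 0).sum(axis=1)).ravel()
    gm = GaussianMixture(n_components=2, random_state=0).fit(np.log(ngene[:, None]))
    fitted = np.sort(np.exp(gm.means_.ravel()))
    planted = np.sort(
        [np.median(ngene[truth.is_lowq]), np.median(ngene[~truth.is_lowq])]
    )
    assert np.all(np.abs(fitted - planted) / planted < 0.15)


def test_seed_reproducibility():
    cfg = SimConfig(n_cells=100, n_genes=200, seed=7)
    a1, t1 = generate_counts(cfg)
    a2, t2 = generate_counts(cfg)
    assert (a1.X != a2.X).nnz == 0
    assert np.array_equal(t1.cluster_label, t2.cluster_label)
    a3, _ = generate_counts(SimConfig(n_cells=100, n_genes=200, seed=8))
    assert (a1.X != a3.X).nnz > 0


class TestDoublets:
    def test_zero_rate_identity(self, small_planted):
        adata, truth = small_planted
        out, _ = inject_doublets(adata, 0.0, seed=1, truth=truth)
        assert out.n_obs == adata.n_obs

    def test_rate_rejected(self, small_planted):
        adata, truth = small_planted
        with pytest.raises(ValueError):
            inject_doublets(adata, 1.0, seed=1, truth=truth)

    def test_count_and_sum_conservation(self, small_planted):
        adata, truth = small_planted
        out, t2 = inject_doublets(adata, 0.05, seed=1, truth=truth)
        n_doub = round(0.05 * adata.n_obs)
        assert out.n_obs == adata.n_obs + n_doub
        X = adata.X.toarray()
        Xo = out.X.toarray()
        for i, (p, q) in enumerate(t2.doublet_parents):
            assert np.array_equal(Xo[adata.n_obs + i], X[p] + X[q])

    def test_doublet_scores_reflect_both_parents(self, small_planted):
        adata, truth = small_planted
        out, t2 = inject_doublets(adata, 0.05, seed=2, truth=truth)
        X = out.X.toarray().astype(float)
        lib = X.sum(axis=1, keepdims=True)
        logX = np.log1p(X / lib * 1e4)
        gi = {g: i for i, g in enumerate(out.var_names)}
        # mean marker expression per cluster program, recomputed directly
        scores = {
            c: logX[:, [gi[g] for g in genes]].mean(axis=1)
            for c, genes in truth.marker_sets.items()
        }
        for i, (p, q) in enumerate(t2.doublet_parents):
            ca, cb = truth.cluster_label[p], truth.cluster_label[q]
            if ca == cb:
                continue
            row = adata.n_obs + i
            others = [c for c in scores if c not in (ca, cb)]
            for parent_c in (ca, cb):
                other_median = np.median([scores[c][row] for c in others])
                assert scores[parent_c][row] >= other_median


class TestTrajectory:
    def test_depth_drives_deep_module(self):
        cfg = SimConfig(n_cells=800, n_genes=1000, trajectory=True, depth_module_size=40, seed=5)
        adata, truth = generate_trajectory_counts(cfg)
        gi = {g: i for i, g in enumerate(adata.var_names)}
        deep = [gi[g] for g in truth.marker_sets["deep"]]
        tot = adata.X.toarray()[:, deep].sum(axis=1) / adata.X.toarray().sum(axis=1)
        rho = spearmanr(tot, truth.depth).statistic
        assert rho >= 0.8

    def test_zero_module_independent_of_depth(self):
        cfg = SimConfig(
            n_cells=300, n_genes=400, trajectory=True, depth_module_size=1, marker_logfc=0.0, seed=6
        )
        adata, truth = generate_trajectory_counts(cfg)
        tot = np.asarray(adata.X.sum(axis=1)).ravel()
        rho = spearmanr(tot, truth.depth).statistic
        assert abs(rho) < 0.15

    def test_branch_modules_separate_terminal_states(self):
        cfg = SimConfig(n_cells=900, n_genes=1000, trajectory=True, branching=True, seed=7)
        adata, truth = generate_trajectory_counts(cfg)
        gi = {g: i for i, g in enumerate(adata.var_names)}
        X = adata.X.toarray().astype(float)
        X = X / X.sum(axis=1, keepdims=True)
        terminal = truth.depth > 0.8
        a_mean = {
            b: X[terminal & (truth.branch == b)][:, [gi[g] for g in truth.marker_sets["branch_a"]]].mean()
            for b in (1, 2)
        }
        assert a_mean[1] > 2 * a_mean[2]  # arm-A module elevated only on arm A


class TestCloneTable:
    def test_all_rg_only(self):
        t = generate_clone_table(5, 6, 1.0, [10], seed=0)
        assert (t["composition"] == "RG_only").all()

    def test_proportion_within_binomial_interval(self):
        t = generate_clone_table(50, 10, 0.43, [10], seed=1)
        n = len(t)
        k = (t["composition"] == "RG_only").sum()
        lo, hi = binom.ppf([0.005, 0.995], n, 0.43)
        assert lo <= k <= hi

    def test_clones_per_hemisphere_range(self):
        t = generate_clone_table(9, (4, 11), 0.5, [6, 507], seed=2)
        counts = t.groupby("hemisphere_id").size()
        assert counts.between(4, 11).all()

    def test_empty_chase_days_rejected(self):
        with pytest.raises(ValueError):
            generate_clone_table(5, 6, 0.5, [], seed=0)


class TestOrthologTable:
    def test_bijection_without_duplicates(self):
        t = generate_ortholog_table(50, 0.0, 0.0, seed=0)
        a = t[t["species"] == "zebrafish"]
        b = t[t["species"] == "mouse"]
        assert len(a) == len(b) == 50
        assert set(a["group_id"]) == set(b["group_id"])

    def test_exact_one2many_count(self):
        t = generate_ortholog_table(100, 0.3, 0.0, seed=1)
        a = t[t["species"] == "zebrafish"]
        dup = a.groupby("group_id").size()
        assert (dup == 2).sum() == 30

    def test_every_gene_in_exactly_one_group(self):
        t = generate_ortholog_table(80, 0.25, 0.1, seed=2)
        assert not t.duplicated(["species", "gene_id"]).any()
        per_gene = t.groupby(["species", "gene_id"])["group_id"].nunique()
        assert (per_gene == 1).all()

    def test_fraction_constraints(self):
        with pytest.raises(ValueError):
            generate_ortholog_table(10, 0.7, 0.5)
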