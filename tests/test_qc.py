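"""QC metric arithmetic, loess outlier flagging, threshold boundaries,
variable-gene and PC selection."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from qglia.qc import (
    QCThresholds,
    compute_cell_qc,
    loess_complexity_filter,
    scale_and_pca,
    select_pcs,
    select_variable_genes,
    threshold_filter,
)
from qglia.simulate import SimConfig, generate_counts


def _adata(counts, genes):
    return ad.AnnData(
        X=sp.csr_matrix(np.asarray(counts, dtype=np.int64)),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


class TestCellQC:
    def test_simple_arithmetic(self):
        a = _adata([[3, 1], [0, 0]], ["geneA", "mt-1"])
        qc = compute_cell_qc(a)
        assert qc.loc[qc.index[0], "nUMI"] == 4
        assert qc.loc[qc.index[0], "nGene"] == 2
        assert qc.loc[qc.index[0], "percent_mito"] == 25.0
        # all-zero cell
        assert qc.iloc[1].tolist() == [0, 0, 0.0]

    def test_no_genes_error(self):
        with pytest.raises(ValueError):
            compute_cell_qc(ad.AnnData(X=sp.csr_matrix((3, 0))))

    def test_lowq_cells_have_higher_mito(self):
        adata, truth = generate_counts(SimConfig(n_cells=400, lowq_fraction=0.15, seed=9))
        qc = compute_cell_qc(adata)
        assert (
            qc["percent_mito"][truth.is_lowq].mean()
            > qc["percent_mito"][~truth.is_lowq].mean()
        )


class TestLoessFilter:
    def test_linear_data_all_kept(self):
        rng = np.random.default_rng(0)
        numi = rng.uniform(1000, 5000, 200)
        qc = pd.DataFrame({"nUMI": numi, "nGene": 0.3 * numi})
        keep, resid = loess_complexity_filter(qc)
        assert keep.all()
        assert np.max(np.abs(resid)) < 1e-6

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(1)
        numi = rng.uniform(1000, 5000, 500)
        ngene = 0.3 * numi + rng.normal(0, 10, 500)
        numi = np.append(numi, 3000.0)
        ngene = np.append(ngene, 0.3 * 3000 * 5)  # 5x expected complexity
        qc = pd.DataFrame({"nUMI": numi, "nGene": ngene})
        # oracle: global linear-fit residual z-score flags the same cell
        beta = np.polyfit(numi, ngene, 1)
        z = (ngene - np.polyval(beta, numi)) / np.std(ngene - np.polyval(beta, numi))
        assert np.argmax(np.abs(z)) == 500
        keep, _ = loess_complexity_filter(qc)
        assert not keep[500]
        assert keep[:500].mean() > 0.98

    def test_infinite_cut_keeps_all(self):
        rng = np.random.default_rng(2)
        numi = rng.uniform(1000, 5000, 100)
        qc = pd.DataFrame({"nUMI": numi, "nGene": 0.3 * numi + rng.normal(0, 50, 100)})
        keep, _ = loess_complexity_filter(qc, QCThresholds(sd_cut=np.inf))
        assert keep.all()

    def test_constant_numi_errors(self):
        qc = pd.DataFrame({"nUMI": np.full(50, 100.0), "nGene": np.arange(50.0)})
        with pytest.raises(ValueError):
            loess_complexity_filter(qc)

    def test_scale_equivariance(self):
        adata, _ = generate_counts(SimConfig(n_cells=500, seed=11))
        qc = compute_cell_qc(adata)
        keep1, _ = loess_complexity_filter(qc)
        qc10 = qc.copy()
        qc10["nUMI"] = qc10["nUMI"] * 10  # same complexity relation, rescaled depth
        keep2, _ = loess_complexity_filter(qc10)
        assert (keep1 != keep2).mean() < 0.01


class TestThresholdFilter:
    def test_boundary_conventions(self):
        # one cell at nGene=199 (removed, strict <200), one at 200 (kept)
        rng = np.random.default_rng(3)
        n_genes = 250
        rows = []
        for ngene in (199, 200, 240):
            row = np.zeros(n_genes, dtype=int)
            row[rng.choice(n_genes, ngene, replace=False)] = 1
            rows.append(row)
        # pad cells so genes survive the 10-cell filter
        pad = np.ones((20, n_genes), dtype=int)
        X = np.vstack(rows + [pad])
        a = _adata(X, [f"g{i}" for i in range(n_genes)])
        out = threshold_filter(a, thresholds=QCThresholds(gene_min_cells=0))
        kept = set(out.obs_names)
        assert a.obs_names[0] not in kept
        assert a.obs_names[1] in kept

    def test_gene_cell_count_boundary(self):
        n_cells = 30
        X = np.ones((n_cells, 3), dtype=int) * 5
        X[:, 1] = 0
        X[:10, 1] = 1  # exactly 10 cells
        X[:, 2] = 0
        X[:9, 2] = 1  # 9 cells -> dropped
        a = _adata(X, ["g_all", "g_ten", "g_nine"])
        out = threshold_filter(a, thresholds=QCThresholds(min_genes=0, gene_min_cells=10))
        assert "g_ten" in out.var_names
        assert "g_nine" not in out.var_names

    def test_trivial_thresholds_identity_and_idempotence(self):
        adata, _ = generate_counts(SimConfig(n_cells=200, seed=4))
        th = QCThresholds(min_genes=0, max_mito_pct=np.inf, gene_min_cells=0)
        out = threshold_filter(adata, thresholds=th)
        assert out.shape == adata.shape
        # idempotence with real thresholds
        once = threshold_filter(adata)
        twice = threshold_filter(once)
        assert once.shape == twice.shape
        assert (once.X != twice.X).nnz == 0

    def test_all_removed_errors(self):
        a = _adata(np.ones((12, 5), dtype=int), [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            threshold_filter(a, thresholds=QCThresholds(min_genes=100))


class TestVariableGenes:
    def test_planted_markers_recovered(self):
        cfg = SimConfig(n_cells=500, n_genes=800, n_clusters=4, n_markers_per_cluster=25, seed=5)
        adata, truth = generate_counts(cfg)
        markers = {g for genes in truth.marker_sets.values() for g in genes}
        top, _ = select_variable_genes(adata, n_top=2 * len(markers))
        recall = len(markers & set(top)) / len(markers)
        assert recall >= 0.8

    def test_zero_top_empty(self, small_planted):
        adata, _ = small_planted
        top, _ = select_variable_genes(adata, n_top=0)
        assert top == []

    def test_constant_matrix_empty(self):
        a = _adata(np.ones((20, 10), dtype=int), [f"g{i}" for i in range(10)])
        top, _ = select_variable_genes(a, n_top=5)
        assert top == []


class TestPCSelection:
    def test_pure_noise_has_no_significant_pcs(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 120))
        n_sig, _ = select_pcs(X, n_max=20, jackstraw_reps=30, seed=0)
        assert n_sig <= 1  # within JackStraw type-I tolerance

    def test_planted_clusters_yield_significant_pcs(self):
        cfg = SimConfig(n_cells=400, n_genes=500, n_clusters=6, seed=7)
        adata, _ = generate_counts(cfg)
        from qglia.de import normalize_log

        logX = normalize_log(adata)
        top, _ = select_variable_genes(adata, n_top=200)
        gi = {g: i for i, g in enumerate(adata.var_names)}
        n_sig, table = select_pcs(logX[:, [gi[g] for g in top]], n_max=20, jackstraw_reps=30, seed=0)
        assert n_sig >= 3

    def test_full_variance_threshold_kills_all(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 40))
        n_sig, _ = select_pcs(X, n_max=10, var_threshold=1.0, jackstraw_reps=5, seed=0)
        assert n_sig == 0
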