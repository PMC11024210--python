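"""Module scores, population gating, signed AUROC, preranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from qglia.de import normalize_log
from qglia.gsea import gsea_preranked
from qglia.scoring import (
    gate_populations,
    gene_signed_auroc,
    module_score,
    ribosomal_genes,
)
from qglia.simulate import SimConfig, generate_counts


@pytest.fixture(scope="module")
def scored_fixture():
    adata, truth = generate_counts(SimConfig(n_cells=400, n_genes=800, n_clusters=4, seed=30))
    return adata, truth, normalize_log(adata)


class TestModuleScore:
    def test_all_genes_set_scores_exactly_zero(self, scored_fixture):
        adata, _, logX = scored_fixture
        genes = list(adata.var_names)
        s = module_score(logX, genes, genes, n_background=10**9, seed=0)
        assert np.max(np.abs(s)) <= 1e-12  # zero to machine precision

    def test_planted_module_separates_cluster(self, scored_fixture):
        adata, truth, logX = scored_fixture
        s = module_score(logX, list(adata.var_names), truth.marker_sets[1], seed=1)
        in_c = truth.cluster_label == 1
        assert s[in_c].mean() - s[~in_c].mean() > 0.5

    def test_uniform_housekeeping_scores_near_zero(self):
        rng = np.random.default_rng(2)
        logX = rng.normal(5, 0.1, size=(200, 300))  # uniformly high everywhere
        genes = [f"g{i}" for i in range(300)]
        s = module_score(logX, genes, genes[:20], seed=3)
        assert abs(s.mean()) < 0.05

    def test_per_cell_shift_invariance(self, scored_fixture):
        adata, _, logX = scored_fixture
        genes = list(adata.var_names)
        s1 = module_score(logX, genes, genes[:30], seed=4)
        shifted = logX + np.arange(logX.shape[0])[:, None] * 0.1
        s2 = module_score(shifted, genes, genes[:30], seed=4)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_missing_set_errors(self, scored_fixture):
        adata, _, logX = scored_fixture
        with pytest.raises(ValueError, match="absent|missing"):
            module_score(logX, list(adata.var_names), ["NOT_A_GENE"], seed=0)

    def test_matches_scanpy_reference(self, scored_fixture):
        """Independent cross-check against scanpy's binned-control score."""
        sc = pytest.importorskip("scanpy")
        adata, truth, logX = scored_fixture
        ours = module_score(logX, list(adata.var_names), truth.marker_sets[0], seed=5)
        ref = adata.copy()
        ref.X = logX
        sc.tl.score_genes(ref, truth.marker_sets[0], ctrl_size=50, n_bins=25, random_state=0)
        r = np.corrcoef(ours, ref.obs["score"])[0, 1]
        assert r > 0.95


class TestGating:
    def _scores(self):
        # 50 cells per gated population over a 150-cell background, so the
        # 0.7/0.3 score quantiles fall between populations and background
        rng = np.random.default_rng(8)
        base = rng.normal(0, 0.1, size=(300, 3))
        truth = np.array(["qRG"] * 50 + ["paRG"] * 50 + ["NB"] * 50 + ["other"] * 150)
        base[:50] += [2, -2, -2]
        base[50:100] += [2, 2, -2]
        base[100:150] += [-2, 2, 2]
        return (
            pd.DataFrame(base, columns=["glial_score", "ribo_score", "nb_score"]),
            truth,
        )

    def test_extreme_cell_is_qrg(self):
        df, _ = self._scores()
        pops = gate_populations(df)
        i = df["glial_score"].idxmax()
        assert pops.iloc[i] in ("qRG", "paRG")

    def test_three_state_accuracy(self):
        df, truth = self._scores()
        pops = gate_populations(df)
        acc = (pops.to_numpy() == truth).mean()
        assert acc >= 0.8

    def test_cover_exhaustive_exclusive(self):
        df, _ = self._scores()
        pops = gate_populations(df)
        assert pops.isin(["qRG", "paRG", "NB", "other"]).all()
        assert len(pops) == len(df)

    def test_excluded_cells_marked(self):
        df, _ = self._scores()
        mask = np.zeros(len(df), dtype=bool)
        mask[:10] = True
        pops = gate_populations(df, exclude=mask)
        assert (pops.iloc[:10] == "excluded").all()

    def test_degenerate_scores_error(self):
        df = pd.DataFrame(
            {"glial_score": np.zeros(50), "ribo_score": np.ones(50), "nb_score": np.arange(50.0)}
        )
        with pytest.raises(ValueError):
            gate_populations(df)

    def test_ribosomal_name_pattern(self):
        genes = ["rps7", "rpl13a", "Rps2", "RPL9", "gfap", "mt-1"]
        assert set(ribosomal_genes(genes)) == {"rps7", "rpl13a", "Rps2", "RPL9"}


class TestSignedAuroc:
    def test_exclusive_expression_gives_plus_one(self):
        X = np.zeros((20, 1))
        target = np.zeros(20, dtype=bool)
        target[:8] = True
        X[target, 0] = 5.0
        assert gene_signed_auroc(X, target)[0] == 1.0

    def test_antisymmetry_under_target_swap(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(3, size=(50, 10)).astype(float)
        target = rng.random(50) < 0.5
        a = gene_signed_auroc(X, target)
        b = gene_signed_auroc(X, ~target)
        assert np.allclose(a, -b, atol=1e-12)

    def test_matches_exhaustive_pair_oracle(self):
        from qglia.evaluation import signed_auroc_exactness

        out = signed_auroc_exactness(seed=10)
        assert out["max_abs_diff"] <= 1e-12

    def test_empty_group_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            gene_signed_auroc(X, np.ones(5, dtype=bool))


class TestGsea:
    def test_top_ranked_set_maximally_significant(self):
        rng = np.random.default_rng(11)
        ranking = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        top = list(ranking.sort_values(ascending=False).index[:20])
        res = gsea_preranked(ranking, {"top": top}, n_perm=200, seed=0)
        assert res.loc[0, "es"] > 0
        assert res.loc[0, "pval"] <= 1 / (200 + 1) + 1e-12

    def test_reversed_ranking_flips_sign(self):
        rng = np.random.default_rng(12)
        ranking = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        genes = list(rng.choice(ranking.index, 30, replace=False))
        res1 = gsea_preranked(ranking, {"s": genes}, n_perm=50, seed=1)
        res2 = gsea_preranked(-ranking, {"s": genes}, n_perm=50, seed=1)
        assert res1.loc[0, "es"] == pytest.approx(-res2.loc[0, "es"], abs=1e-9)

    def test_small_sets_skipped(self):
        ranking = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        res = gsea_preranked(ranking, {"tiny": ["g1", "g2"]}, n_perm=20, seed=0)
        assert np.isnan(res.loc[0, "es"])

    def test_null_pvalues_uniform(self):
        from qglia.evaluation import gsea_null_calibration

        out = gsea_null_calibration(seed=13, n_draws=100, n_perm=200)
        assert out["ks_p"] > 0.01

    def test_missing_values_rejected(self):
        ranking = pd.Series([1.0, np.nan], index=["a", "b"])
        with pytest.raises(ValueError):
            gsea_preranked(ranking, {"s": ["a"]})
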