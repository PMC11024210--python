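"""CSPA consensus matrix, robust cuts, DE merging, gates, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from qglia.cluster import Labeling
from qglia.consensus import (
    cspa_consensus,
    cut_consensus,
    find_marker_gate,
    merge_by_de,
    validate_cluster_auroc,
)


def _lab(labels, method="m", seed=0):
    return Labeling(method=method, labels=np.asarray(labels), seed=seed)


class TestCspa:
    def test_identical_partitions_give_block_matrix(self):
        labels = np.array([0, 0, 1, 1, 2])
        M = cspa_consensus([_lab(labels), _lab(labels), _lab(labels)])
        expected = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(M, expected)

    def test_bruteforce_pair_counting(self):
        rng = np.random.default_rng(0)
        runs = [_lab(rng.integers(0, 4, size=50)) for _ in range(6)]
        M = cspa_consensus(runs)
        for i in range(50):
            for j in range(50):
                expected = np.mean([r.labels[i] == r.labels[j] for r in runs])
                assert M[i, j] == pytest.approx(expected)

    def test_mismatched_cell_sets_rejected(self):
        with pytest.raises(ValueError):
            cspa_consensus([_lab([0, 1]), _lab([0, 1, 2])])

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=6, max_size=12))
    def test_label_permutation_invariance(self, labels):
        labels = np.asarray(labels)
        other = np.zeros_like(labels)
        M1 = cspa_consensus([_lab(labels), _lab(other)])
        # relabel run 1 by permuting cluster ids
        remap = {0: 3, 1: 2, 2: 1, 3: 0}
        relabeled = np.array([remap[v] for v in labels])
        M2 = cspa_consensus([_lab(relabeled), _lab(other)])
        assert np.array_equal(M1, M2)


class TestCut:
    def test_block_diagonal_recovered_any_height(self):
        labels = np.repeat([0, 1, 2], 10)
        M = (labels[:, None] == labels[None, :]).astype(float)
        for h in (0.1, 0.5, 0.9):
            cut, _ = cut_consensus(M, height=h)
            assert adjusted_rand_score(labels, cut) == 1.0

    def test_height_near_one_single_cluster(self):
        rng = np.random.default_rng(1)
        M = np.clip(rng.uniform(0.3, 0.9, (20, 20)), 0, 1)
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1)
        cut, _ = cut_consensus(M, height=0.99)
        assert cut.max() == 0

    def test_bad_inputs(self):
        M = np.eye(3)
        with pytest.raises(ValueError):
            cut_consensus(M, height=1.5)
        M2 = M.copy()
        M2[0, 1] = np.nan
        with pytest.raises(ValueError):
            cut_consensus(M2, height=0.2)


class TestMergeByDe:
    def test_oversplit_cluster_remerged(self):
        from qglia.evaluation import oversplit_merge_check

        out = oversplit_merge_check(seed=3, n_cells=400)
        assert out["K_after_merge"] == out["planted_K"]
        assert out["ari_after_merge"] >= 0.99
        assert out["distinct_preserved"]

    def test_zero_min_de_identity(self, small_planted):
        adata, truth = small_planted
        merged = merge_by_de(adata, truth.cluster_label, min_de_genes=0)
        assert np.array_equal(merged, truth.cluster_label)

    def test_contraction_property(self, small_planted):
        adata, truth = small_planted
        rng = np.random.default_rng(4)
        random_labels = rng.integers(0, 6, size=adata.n_obs)
        merged = merge_by_de(adata, random_labels, min_de_genes=10)
        assert merged.max() <= random_labels.max()


class TestMarkerGates:
    def test_bimodal_marker_single_term_perfect_gate(self):
        import anndata as ad
        import pandas as pd
        import scipy.sparse as sp

        rng = np.random.default_rng(5)
        n = 200
        labels = (np.arange(n) < 60).astype(int)
        X = rng.poisson(1.0, size=(n, 20))
        X[labels == 1, 0] += 50  # perfectly separating marker
        a = ad.AnnData(
            X=sp.csr_matrix(X), var=pd.DataFrame(index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"))
        )
        gate = find_marker_gate(a, labels, cluster=1)
        assert gate.f1 == 1.0
        assert len(gate.terms) == 1
        assert gate.terms[0][0] == "g0"

    def test_planted_clusters_gate_f1(self, small_planted):
        adata, truth = small_planted
        for c in range(3):
            gate = find_marker_gate(adata, truth.cluster_label, cluster=c)
            assert gate.f1 >= 0.8

    def test_shuffled_labels_gate_near_prevalence(self, small_planted):
        adata, truth = small_planted
        rng = np.random.default_rng(6)
        shuffled = rng.permutation(truth.cluster_label)
        gate = find_marker_gate(adata, shuffled, cluster=0)
        prevalence = (shuffled == 0).mean()
        baseline_f1 = 2 * prevalence / (1 + prevalence)  # gate that accepts everything
        assert gate.f1 <= baseline_f1 + 0.15

    def test_empty_cluster_rejected(self, small_planted):
        adata, truth = small_planted
        with pytest.raises(ValueError):
            find_marker_gate(adata, truth.cluster_label, cluster=99)


class TestValidation:
    def test_planted_clusters_pass_and_shuffled_fail(self, small_planted):
        adata, truth = small_planted
        gates = {c: find_marker_gate(adata, truth.cluster_label, cluster=c) for c in range(3)}
        res = validate_cluster_auroc(adata, truth.cluster_label, gates)
        assert res["passed"].all()
        assert (res["auroc"] > 0.95).all()
        rng = np.random.default_rng(7)
        shuffled = rng.permutation(truth.cluster_label)
        res_null = validate_cluster_auroc(adata, shuffled, gates)
        assert (res_null["auroc"] < 0.65).all()
        assert not res_null["passed"].any()

    def test_impossible_threshold_fails_most(self, small_planted):
        adata, truth = small_planted
        gates = {0: find_marker_gate(adata, truth.cluster_label, cluster=0)}
        res = validate_cluster_auroc(adata, truth.cluster_label, gates, auroc_min=1.0)
        assert not res["passed"].any() or (res["auroc"] == 1.0).all()
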