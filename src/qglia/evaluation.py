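"""Benchmark evaluations of every pipeline stage on planted fixtures.

Each function generates its fixture from a seed, runs the relevant stage
of the pipeline under the standard study conditions, and returns the
measured quantities as a flat dict.  The test suite, the acceptance
script and the analysis drivers all call these functions, so the numbers
they report are always recomputed from scratch.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import kstest, norm, spearmanr
from sklearn.metrics import adjusted_rand_score

from .simulate import SimConfig, generate_counts, generate_trajectory_counts, inject_doublets

__all__ = [
    "planted_cluster_recovery",
    "oversplit_merge_check",
    "qc_recovery",
    "doublet_detection",
    "signed_auroc_exactness",
    "module_score_checks",
    "pseudo_order_eval",
    "y_branch_topology",
    "mst_distance_exactness",
    "homology_eval",
    "exact_test_checks",
    "gsea_null_calibration",
]


def _cluster_pipeline(adata, seed, n_hvg=500, n_pcs=20, k=15, height=0.2, min_de=10):
    from .cluster import run_base_clusterings
    from .consensus import cspa_consensus, cut_consensus, merge_by_de
    from .de import normalize_log
    from .neighbors import build_knn_graph
    from .qc import scale_and_pca, select_variable_genes

    logX = normalize_log(adata)
    hvg, _ = select_variable_genes(adata, n_top=n_hvg)
    gi = {g: i for i, g in enumerate(adata.var_names)}
    pcs, _, _ = scale_and_pca(logX[:, [gi[g] for g in hvg]], n_comps=n_pcs, seed=seed)
    graph = build_knn_graph(pcs, k=k)
    labelings = run_base_clusterings(graph, pcs, seeds=(seed,))
    M = cspa_consensus(labelings)
    cut, _ = cut_consensus(M, height=height)
    labels = merge_by_de(adata, cut, M, min_de_genes=min_de, logX=logX)
    return labels, M, logX, pcs


def planted_cluster_recovery(seed: int = 0, n_cells: int = 1500) -> dict:
    """Full consensus pipeline on the standard planted fixture
    (6 clusters, 30 markers each, logFC 2): recovered K and ARI."""
    cfg = SimConfig(n_cells=n_cells, n_clusters=6, n_markers_per_cluster=30, marker_logfc=2.0, seed=seed)
    adata, truth = generate_counts(cfg)
    from .qc import threshold_filter

    filtered = threshold_filter(adata)
    keep = np.isin(adata.obs_names, filtered.obs_names)
    labels, _, _, _ = _cluster_pipeline(filtered, seed)
    ari = adjusted_rand_score(truth.cluster_label[keep], labels)
    return {"K": int(labels.max()) + 1, "planted_K": 6, "ari": float(ari), "n": int(filtered.n_obs)}


def oversplit_merge_check(seed: int = 0, n_cells: int = 600) -> dict:
    """Artificially split a planted cluster and let DE-merging repair it;
    verify genuinely distinct clusters are never merged."""
    from .consensus import merge_by_de

    cfg = SimConfig(n_cells=n_cells, n_clusters=3, n_markers_per_cluster=30, marker_logfc=2.0, seed=seed)
    adata, truth = generate_counts(cfg)
    rng = np.random.default_rng(seed)
    labels = truth.cluster_label.copy()
    # split cluster 0 at random into two pseudo-clusters
    zero = np.where(labels == 0)[0]
    half = rng.permutation(zero)[: zero.size // 2]
    split = labels.copy()
    split[half] = 3
    merged = merge_by_de(adata, split, min_de_genes=10)
    ari_after = adjusted_rand_score(truth.cluster_label, merged)
    # distinct planted clusters must survive merging of the true labeling
    merged_true = merge_by_de(adata, truth.cluster_label.copy(), min_de_genes=10)
    return {
        "K_after_merge": int(merged.max()) + 1,
        "planted_K": 3,
        "ari_after_merge": float(ari_after),
        "distinct_preserved": bool(int(merged_true.max()) + 1 == 3),
        "n": n_cells,
    }


def qc_recovery(seed: int = 0, n_cells: int = 1000) -> dict:
    """Low-quality cell removal on the bimodal-nGene fixture."""
    from .qc import QCThresholds, compute_cell_qc, loess_complexity_filter, threshold_filter

    cfg = SimConfig(n_cells=n_cells, lowq_fraction=0.1, seed=seed)
    adata, truth = generate_counts(cfg)
    th = QCThresholds()
    qc = compute_cell_qc(adata)
    keep_loess, _ = loess_complexity_filter(qc, th)
    filtered = threshold_filter(adata, qc, th, keep_loess)
    kept = np.isin(adata.obs_names, filtered.obs_names)
    lowq = truth.is_lowq
    return {
        "lowq_removed_frac": float(1 - kept[lowq].mean()) if lowq.any() else np.nan,
        "good_removed_frac": float(1 - kept[~lowq].mean()),
        "n": n_cells,
    }


def doublet_detection(seed: int = 0, n_cells: int = 1000, rate: float = 0.05) -> dict:
    """Mock-doublet detection of injected doublets on the 6-cluster
    fixture, with one mock per cell."""
    from .doublets import detect_doublets_mock

    cfg = SimConfig(n_cells=n_cells, n_clusters=6, seed=seed)
    adata, truth = generate_counts(cfg)
    adata, truth = inject_doublets(adata, rate, seed=seed + 1, truth=truth)
    _, flags = detect_doublets_mock(adata, n_mock=adata.n_obs, seed=seed + 2)
    t = truth.is_doublet
    tp = int((flags & t).sum())
    return {
        "recall": tp / int(t.sum()),
        "precision": tp / max(int(flags.sum()), 1),
        "n": int(adata.n_obs),
    }


def signed_auroc_exactness(seed: int = 0, n_cells: int = 40, n_genes: int = 25) -> dict:
    """Max |difference| between the rank-based signed AUROC and brute-force
    pair counting over all (target, non-target) cell pairs."""
    from .scoring import gene_signed_auroc

    rng = np.random.default_rng(seed)
    X = rng.poisson(2.0, size=(n_cells, n_genes)).astype(float)
    target = rng.random(n_cells) < 0.4
    if target.sum() == 0 or (~target).sum() == 0:
        target[:2] = [True, False]
    fast = gene_signed_auroc(X, target)
    tt = np.where(target)[0]
    cc = np.where(~target)[0]
    slow = np.empty(n_genes)
    for j in range(n_genes):
        conc = ties = 0
        for i in tt:
            for k in cc:
                if X[i, j] > X[k, j]:
                    conc += 1
                elif X[i, j] == X[k, j]:
                    ties += 1
        auc = (conc + 0.5 * ties) / (len(tt) * len(cc))
        slow[j] = 2 * auc - 1
    return {"max_abs_diff": float(np.max(np.abs(fast - slow))), "n": n_cells}


def module_score_checks(seed: int = 0, n_cells: int = 500) -> dict:
    """All-genes module score is identically zero; a planted up-module
    separates its cluster from the rest (normal-approximated permutation
    test on the group-mean difference)."""
    from .de import normalize_log
    from .scoring import module_score

    cfg = SimConfig(n_cells=n_cells, n_genes=1000, n_clusters=4, seed=seed)
    adata, truth = generate_counts(cfg)
    logX = normalize_log(adata)
    genes = list(adata.var_names)
    allgenes = module_score(logX, genes, genes, n_background=10**9, seed=seed)
    planted = module_score(logX, genes, truth.marker_sets[0], seed=seed)
    in_a = truth.cluster_label == 0
    diff = planted[in_a].mean() - planted[~in_a].mean()
    # permutation null of the mean difference (analytic moments)
    n1, n = int(in_a.sum()), planted.size
    mu = 0.0
    var = planted.var(ddof=1) * (1 / n1 + 1 / (n - n1))
    z = (diff - mu) / np.sqrt(var)
    p = float(norm.sf(z))
    return {"allgenes_max_abs": float(np.max(np.abs(allgenes))), "score_gap": float(diff), "perm_p": p, "n": n_cells}


def _pseudo_order_run(adata, depth, seed, n_trees, frac, max_nodes, cluster_labels=None):
    from .de import normalize_log
    from .ordering import bootstrap_mst_distances, diffusion_map, mds_embed
    from .principal_graph import (
        diameter_root,
        fit_principal_graph,
        project_and_order,
        prune_same_cluster_paths,
    )
    from .qc import select_variable_genes

    logX = normalize_log(adata)
    hvg, _ = select_variable_genes(adata, n_top=300)
    gi = {g: i for i, g in enumerate(adata.var_names)}
    dm = diffusion_map(logX[:, [gi[g] for g in hvg]], n_components=3)
    td = bootstrap_mst_distances(dm, n_trees=n_trees, frac=frac, seed=seed)
    coords, _ = mds_embed(td, dim=3)
    graph = fit_principal_graph(coords, max_nodes=max_nodes)
    if cluster_labels is not None:
        graph = prune_same_cluster_paths(graph, coords, cluster_labels)
    proj = project_and_order(graph, coords, root=diameter_root(graph))
    return graph, proj


def pseudo_order_eval(
    seed: int = 0,
    n_cells: int = 800,
    n_trees: int = 1000,
    frac: float = 2 / 3,
    max_nodes: int = 100,
) -> dict:
    """Pseudo-order vs planted quiescence depth on the linear fixture."""
    cfg = SimConfig(n_cells=n_cells, n_genes=1000, trajectory=True, seed=seed)
    adata, truth = generate_trajectory_counts(cfg)
    _, proj = _pseudo_order_run(adata, truth.depth, seed + 1, n_trees, frac, max_nodes, truth.cluster_label)
    rho = spearmanr(proj.pseudo_order, truth.depth).statistic
    return {"abs_spearman": float(abs(rho)), "n": n_cells, "n_trees": n_trees}


def y_branch_topology(seed: int = 0, n_cells: int = 600, max_nodes: int = 60) -> dict:
    """Branch-point count of the fitted skeleton on the Y-shaped fixture."""
    cfg = SimConfig(n_cells=n_cells, n_genes=1000, trajectory=True, branching=True, seed=seed)
    adata, truth = generate_trajectory_counts(cfg)
    graph, _ = _pseudo_order_run(adata, truth.depth, seed + 1, 100, 2 / 3, max_nodes, truth.cluster_label)
    deg = graph.degrees()
    return {"n_degree3": int((deg == 3).sum()), "n_degree4plus": int((deg > 3).sum()), "n": n_cells}


def mst_distance_exactness(seed: int = 0, n_points: int = 7) -> dict:
    """Single-tree (frac=1) along-tree distances vs an exhaustive
    spanning-tree oracle (minimum over all Prufer-enumerated spanning
    trees of the complete graph)."""
    from scipy.spatial.distance import pdist, squareform

    from .ordering import bootstrap_mst_distances

    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    td = bootstrap_mst_distances(pts, n_trees=1, frac=1.0, seed=seed)
    D = squareform(pdist(pts))

    best_w, best_edges = np.inf, None
    for pruefer in itertools.product(range(n_points), repeat=n_points - 2):
        edges = _pruefer_to_edges(list(pruefer), n_points)
        w = sum(D[a, b] for a, b in edges)
        if w < best_w - 1e-12:
            best_w, best_edges = w, edges
    paths = _tree_path_lengths(best_edges, D, n_points)
    return {"max_abs_diff": float(np.max(np.abs(td.D - paths))), "n": n_points}


def _pruefer_to_edges(seq: list[int], n: int) -> list[tuple[int, int]]:
    import heapq

    degree = [1] * n
    for v in seq:
        degree[v] += 1
    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[leaf] -= 1
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, w = [v for v in range(n) if degree[v] == 1]
    edges.append((u, w))
    return edges


def _tree_path_lengths(edges, D, n):
    import scipy.sparse as sp
    from scipy.sparse.csgraph import shortest_path

    W = sp.lil_matrix((n, n))
    for a, b in edges:
        W[a, b] = W[b, a] = D[a, b]
    return shortest_path(W.tocsr(), directed=False)


def homology_eval(seed: int = 0, n_cells: int = 500, n_shuffles: int = 20) -> dict:
    """Neighbour-voting AUROC on the same dataset duplicated as two
    species (diagonal should be ~1) and with shuffled labels (~0.5)."""
    from .homology import neighbor_voting_auroc

    cfg = SimConfig(n_cells=n_cells, n_genes=800, n_clusters=4, seed=seed)
    adata, truth = generate_counts(cfg)
    labels = truth.cluster_label
    H = neighbor_voting_auroc(adata, labels, adata, labels)
    diag = np.diag(H.to_numpy())
    rng = np.random.default_rng(seed + 1)
    means = []
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        Hp = neighbor_voting_auroc(adata, labels, adata, perm)
        means.append(Hp.to_numpy().mean())
    return {
        "diag_min": float(diag.min()),
        "diag_mean": float(diag.mean()),
        "shuffled_mean": float(np.mean(means)),
        "n": n_cells,
    }


def exact_test_checks(seed: int = 0) -> dict:
    """Hand-verifiable exact-test values: the two-sided binomial p for
    k=1, n=10, p0=0.5 and the Cliff's delta / U identity on random
    fixtures."""
    from scipy.stats import mannwhitneyu

    from .clonal import _cliffs_delta, binomial_two_sided

    p = binomial_two_sided(1, 10, 0.5)
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(20):
        x = rng.integers(0, 6, size=rng.integers(3, 15)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(3, 15)).astype(float)
        delta = _cliffs_delta(x, y)
        U = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        max_dev = max(max_dev, abs(delta - (2 * U / (x.size * y.size) - 1)))
    return {"binom_p_1_10_half": float(p), "cliffs_identity_max_dev": float(max_dev), "n": 20}


def gsea_null_calibration(seed: int = 0, n_draws: int = 200, n_genes: int = 600, set_size: int = 25, n_perm: int = 500) -> dict:
    """Uniformity of GSEA p-values for random gene sets against a fixed
    ranking (Kolmogorov-Smirnov test vs Uniform(0,1))."""
    from .gsea import gsea_preranked

    rng = np.random.default_rng(seed)
    ranking = pd.Series(rng.normal(size=n_genes), index=[f"g{i}" for i in range(n_genes)])
    sets = {
        f"random{i}": list(rng.choice(ranking.index, size=set_size, replace=False))
        for i in range(n_draws)
    }
    res = gsea_preranked(ranking, sets, n_perm=n_perm, seed=seed + 1)
    pvals = res["pval"].dropna().to_numpy()
    ks = kstest(pvals, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue), "n": n_draws}
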