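"""Cross-species harmonization and cluster homology mapping.

Genes are collapsed onto ortholog groups (paralogs summed, preserving the
count nature of the data, with an audit of every many-to-one collapse);
cluster homology across species is scored by neighbour voting: a
cell-cell Spearman-correlation network over shared variable groups
propagates training-cluster labels to the held-out species and the votes
are scored by AUROC per test cluster, symmetrically averaged over both
directions.  Gene-set co-expression per species is called "co-expressed",
"spread" or "absent" from permutation nulls of the module score.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .de import normalize_log
from .scoring import module_score

__all__ = [
    "collapse_to_groups",
    "neighbor_voting_auroc",
    "geneset_enrichment_by_cluster",
]


def collapse_to_groups(
    adata: ad.AnnData, table: pd.DataFrame, species: str
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Sum each cell's counts over the ortholog groups of one species.

    Teleost one-to-many groups collapse by summation; groups absent from
    the species are dropped.  Returns the group-space matrix and an audit
    table listing every gene -> group assignment (n_paralogs > 1 marks
    collapses).
    """
    sub = table[table["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} absent from ortholog table")
    gene_to_group = dict(zip(sub["gene_id"], sub["group_id"]))
    genes = [g for g in adata.var_names if g in gene_to_group]
    if not genes:
        raise ValueError("no genes of the matrix map to ortholog groups")
    groups = sorted({gene_to_group[g] for g in genes})
    group_pos = {gr: i for i, gr in enumerate(groups)}
    rows, cols = [], []
    for j, g in enumerate(adata.var_names):
        if g in gene_to_group:
            rows.append(j)
            cols.append(group_pos[gene_to_group[g]])
    ind = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(adata.n_vars, len(groups))
    )
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    Xg = (X @ ind).tocsr()
    out = ad.AnnData(
        X=Xg,
        obs=adata.obs.copy(),
        var=pd.DataFrame(index=pd.Index(groups, name="group_id")),
    )
    audit = pd.DataFrame(
        {"gene_id": genes, "group_id": [gene_to_group[g] for g in genes]}
    )
    audit["n_paralogs"] = audit.groupby("group_id")["gene_id"].transform("count")
    return out, audit


def _rank_network(logX: np.ndarray) -> np.ndarray:
    """Cell-cell Spearman correlation network, rank-standardized to [0,1]
    and row-normalized to voting weights (MetaNeighbor construction)."""
    R = rankdata(logX, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1))
    norm[norm == 0] = 1.0
    C = (R @ R.T) / np.outer(norm, norm)
    np.fill_diagonal(C, 0.0)
    # rank-standardize the whole network
    flat = rankdata(C.ravel()) / C.size
    N = flat.reshape(C.shape)
    np.fill_diagonal(N, 0.0)
    N /= N.sum(axis=1, keepdims=True)
    return N


def neighbor_voting_auroc(
    adata_a: ad.AnnData,
    labels_a: np.ndarray,
    adata_b: ad.AnnData,
    labels_b: np.ndarray,
    variable_groups: list[str] | None = None,
    n_top: int = 500,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Neighbour-voting AUROC map between cluster systems of two species.

    Both matrices must live in the shared ortholog-group space.  Variable
    groups default to a variance-stabilizing selection on the combined
    data.  Returns a train-cluster x test-cluster DataFrame of AUROCs
    (symmetric average of the two voting directions).
    """
    shared = [g for g in adata_a.var_names if g in set(adata_b.var_names)]
    if not shared:
        raise ValueError("no shared groups between the two matrices")
    A = adata_a[:, shared]
    B = adata_b[:, shared]
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    for lab, name in ((labels_a, "A"), (labels_b, "B")):
        vals, cnt = np.unique(lab, return_counts=True)
        if (cnt < min_cluster_size).any():
            raise ValueError(f"species {name} has clusters below {min_cluster_size} cells")
    logA = normalize_log(A)
    logB = normalize_log(B)
    if variable_groups is None:
        from .qc import select_variable_genes

        combined = ad.AnnData(
            X=sp.vstack([sp.csr_matrix(A.X), sp.csr_matrix(B.X)]),
            var=pd.DataFrame(index=pd.Index(shared, name="group_id")),
        )
        variable_groups, _ = select_variable_genes(combined, n_top=min(n_top, len(shared)))
    vg_idx = [i for i, g in enumerate(shared) if g in set(variable_groups)]
    if not vg_idx:
        raise ValueError("no variable groups selected")
    X = np.vstack([logA[:, vg_idx], logB[:, vg_idx]])
    if np.any(X.std(axis=1) == 0):
        raise ValueError("all-constant cells break the Spearman network")
    n_a = A.n_obs
    net = _rank_network(X)
    ka = np.unique(labels_a)
    kb = np.unique(labels_b)
    # votes from A's labels onto B's cells, and vice versa
    votes_b = np.stack([net[n_a:, :n_a][:, labels_a == c].sum(axis=1) for c in ka], axis=1)
    votes_a = np.stack([net[:n_a, n_a:][:, labels_b == c].sum(axis=1) for c in kb], axis=1)
    H = np.zeros((ka.size, kb.size))
    for i, ca in enumerate(ka):
        for j, cb in enumerate(kb):
            auc_b = _auroc(votes_b[:, i], labels_b == cb)
            auc_a = _auroc(votes_a[:, j], labels_a == ca)
            H[i, j] = 0.5 * (auc_b + auc_a)
    return pd.DataFrame(H, index=pd.Index(ka, name="train_cluster"), columns=pd.Index(kb, name="test_cluster"))


def _auroc(score: np.ndarray, positive: np.ndarray) -> float:
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n2 = positive.size - n1
    if n1 == 0:
        return np.nan
    if n2 == 0:
        return 1.0  # degenerate single-cluster contract
    r = rankdata(score)
    return float((r[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def geneset_enrichment_by_cluster(
    adata: ad.AnnData,
    labels: np.ndarray,
    gene_set: list[str],
    null_quantile: float = 0.99,
    n_perm: int = 200,
    min_coverage: int = 3,
    marker_log2fc: float = 1.0,
    seed: int = 0,
) -> dict:
    """Score a gene set per cluster and call its species-level status.

    "co-expressed": some cluster's mean module score exceeds the
    ``null_quantile`` of random same-size sets AND at least half the set's
    genes are individually enriched in that same cluster (cluster of
    maximal mean, log2FC vs rest above threshold).  "spread": genes are
    individually enriched but across >= 2 disjoint clusters with no
    single qualifying cluster.  "absent" otherwise; "not evaluable" when
    fewer than ``min_coverage`` set genes are present.
    """
    labels = np.asarray(labels)
    gene_names = list(adata.var_names)
    present = [g for g in gene_set if g in set(gene_names)]
    if len(present) < min_coverage:
        return {"call": "not evaluable", "n_present": len(present), "cluster_scores": {}}
    logX = normalize_log(adata)
    rng = np.random.default_rng(seed)
    ks = np.unique(labels)
    score = module_score(logX, gene_names, present, seed=seed)
    cluster_means = {int(k): float(score[labels == k].mean()) for k in ks}
    # permutation null of per-cluster mean scores
    null_max = {int(k): [] for k in ks}
    for p in range(n_perm):
        rnd = list(rng.choice(gene_names, size=len(present), replace=False))
        s = module_score(logX, gene_names, rnd, seed=seed + 1 + p)
        for k in ks:
            null_max[int(k)].append(s[labels == k].mean())
    thresholds = {k: float(np.quantile(v, null_quantile)) for k, v in null_max.items()}

    # individual enrichment: the module DE test, positive side, per cluster
    from .de import wilcoxon_de

    gidx = {g: i for i, g in enumerate(gene_names)}
    sub = logX[:, [gidx[g] for g in present]]
    gene_best: dict[str, int] = {}
    best_lfc: dict[str, float] = {}
    for k in ks:
        de = wilcoxon_de(sub, labels == k, present, min_abs_log2fc=marker_log2fc)
        for _, row in de[de["significant"] & (de["log2fc"] > 0)].iterrows():
            g = row["gene"]
            if g not in gene_best or row["log2fc"] > best_lfc[g]:
                gene_best[g] = int(k)
                best_lfc[g] = float(row["log2fc"])

    qualifying = [
        int(k)
        for k in ks
        if cluster_means[int(k)] > thresholds[int(k)]
        and sum(1 for g in present if gene_best.get(g) == int(k)) >= len(present) / 2
    ]
    if qualifying:
        call = "co-expressed"
        top = max(qualifying, key=lambda k: cluster_means[k])
    else:
        enriched_clusters = set(gene_best.values())
        if len(gene_best) >= len(present) / 2 and len(enriched_clusters) >= 2:
            call = "spread"
        else:
            call = "absent"
        top = max(cluster_means, key=cluster_means.get)
    return {
        "call": call,
        "top_cluster": int(top),
        "cluster_scores": cluster_means,
        "null_thresholds": thresholds,
        "gene_enriched_in": gene_best,
        "n_present": len(present),
    }
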