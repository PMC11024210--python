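"""CSPA consensus clustering, robust cuts, DE merging and marker gates.

The Cluster-based Similarity Partitioning Algorithm turns an ensemble of
labelings into a co-clustering frequency matrix M (M[i,j] = fraction of
runs placing i and j together).  Average-linkage hierarchical clustering
on 1 - M cut at a conservative height (default 0.2, i.e. cores that
co-cluster in >= 80% of runs) gives robust clusters; dendrogram-adjacent
cluster pairs are then iteratively merged when the standard DE test finds
fewer than ``min_de_genes`` significant genes between them.  Final
clusters are validated by greedy boolean marker gates (hypergate-style)
and a cross-validated linear classifier's AUROC (pass above 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster import Labeling
from .de import normalize_log, wilcoxon_de

__all__ = [
    "cspa_consensus",
    "cut_consensus",
    "merge_by_de",
    "find_marker_gate",
    "validate_cluster_auroc",
    "MarkerGate",
]


def cspa_consensus(labelings: list[Labeling]) -> np.ndarray:
    """Co-clustering frequency matrix over an ensemble of labelings."""
    runs = [lab for lab in labelings if lab.labels.size]
    if len(runs) < 2:
        raise ValueError("need at least 2 labelings")
    n = runs[0].labels.size
    for lab in runs:
        if lab.labels.size != n:
            raise ValueError("labelings cover different cell sets")
    M = np.zeros((n, n))
    for lab in runs:
        L = lab.labels
        M += (L[:, None] == L[None, :]).astype(float)
    M /= len(runs)
    np.fill_diagonal(M, 1.0)
    return M


def cut_consensus(M: np.ndarray, height: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage cut of the consensus matrix at distance ``height``.

    Returns (labels, linkage matrix).  ``height`` in (0,1): 0.2 requires
    cluster cores to co-cluster in at least 80% of ensemble runs.
    """
    if not 0 < height < 1:
        raise ValueError("height must lie in (0, 1)")
    if not np.all(np.isfinite(M)):
        raise ValueError("consensus matrix contains non-finite entries")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=height, criterion="distance")
    _, labels = np.unique(raw, return_inverse=True)
    return labels.astype(int), Z


def merge_by_de(
    adata: ad.AnnData,
    labels: np.ndarray,
    M: np.ndarray | None = None,
    min_de_genes: int = 10,
    fdr: float = 0.05,
    min_abs_log2fc: float = 0.25,
    logX: np.ndarray | None = None,
) -> np.ndarray:
    """Iteratively merge neighbouring clusters that lack DE support.

    Neighbouring pairs are taken in ascending order of mean consensus
    distance (dendrogram-sibling order); a pair with fewer than
    ``min_de_genes`` significant genes (Wilcoxon + BH + log2FC filter)
    merges, and the scan restarts until a fixed point.  Cluster count
    never increases.
    """
    labels = np.asarray(labels).copy()
    if min_de_genes <= 0:
        return labels
    if logX is None:
        logX = normalize_log(adata)
    while True:
        ks = np.unique(labels)
        if ks.size < 2:
            break
        # candidate order: ascending mean pairwise consensus distance
        pairs = []
        for ia, a in enumerate(ks):
            for b in ks[ia + 1 :]:
                if M is not None:
                    d = 1.0 - M[np.ix_(labels == a, labels == b)].mean()
                else:
                    ca = logX[labels == a].mean(axis=0)
                    cb = logX[labels == b].mean(axis=0)
                    d = float(np.linalg.norm(ca - cb))
                pairs.append((d, a, b))
        pairs.sort()
        merged = False
        for d, a, b in pairs:
            sub = np.isin(labels, [a, b])
            de = wilcoxon_de(logX[sub], labels[sub] == a, adata.var_names, fdr, min_abs_log2fc)
            if int(de["significant"].sum()) < min_de_genes:
                labels[labels == b] = a
                merged = True
                break
        if not merged:
            break
    _, dense = np.unique(labels, return_inverse=True)
    return dense.astype(int)


@dataclass
class MarkerGate:
    cluster: int
    terms: list = field(default_factory=list)  # (gene, direction '+'/'-', threshold)
    f1: float = 0.0
    auroc: float = float("nan")

    def apply(self, logX: np.ndarray, gene_index: dict) -> np.ndarray:
        mask = np.ones(logX.shape[0], dtype=bool)
        for gene, direction, thr in self.terms:
            x = logX[:, gene_index[gene]]
            mask &= (x >= thr) if direction == "+" else (x <= thr)
        return mask


def _f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = float((pred & truth).sum())
    if tp == 0:
        return 0.0
    prec = tp / pred.sum()
    rec = tp / truth.sum()
    return 2 * prec * rec / (prec + rec)


def find_marker_gate(
    adata: ad.AnnData,
    labels: np.ndarray,
    cluster: int,
    max_terms: int = 4,
    min_gain: float = 0.01,
    n_candidate_genes: int = 200,
    logX: np.ndarray | None = None,
) -> MarkerGate:
    """Greedy boolean marker gate for one cluster (hypergate-style).

    At each step the (gene, direction, threshold) term maximizing the
    gate's F1 against the cluster-vs-rest labels is added, thresholds
    searched over expression deciles, until the gain drops below
    ``min_gain`` or ``max_terms`` is reached.  Candidate genes are the
    ``n_candidate_genes`` with the largest |signed AUROC| for the cluster.
    """
    labels = np.asarray(labels)
    target = labels == cluster
    if target.sum() == 0:
        raise ValueError(f"cluster {cluster} is empty")
    if logX is None:
        logX = normalize_log(adata)
    from .scoring import gene_signed_auroc

    signed = gene_signed_auroc(logX, target)
    cand = np.argsort(-np.abs(signed), kind="stable")[: min(n_candidate_genes, logX.shape[1])]
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    gate = MarkerGate(cluster=int(cluster))
    current = np.ones(logX.shape[0], dtype=bool)
    current_f1 = _f1(current, target)
    deciles = np.linspace(0.1, 0.9, 9)
    for _ in range(max_terms):
        best = None
        for j in cand:
            x = logX[:, j]
            thrs = np.unique(np.quantile(x, deciles))
            for thr in thrs:
                for direction in ("+", "-"):
                    pred = current & ((x >= thr) if direction == "+" else (x <= thr))
                    f1 = _f1(pred, target)
                    if best is None or f1 > best[0]:
                        best = (f1, int(j), direction, float(thr))
        if best is None or best[0] - current_f1 < min_gain:
            break
        f1, j, direction, thr = best
        gene = adata.var_names[j]
        gate.terms.append((gene, direction, thr))
        current = current & ((logX[:, j] >= thr) if direction == "+" else (logX[:, j] <= thr))
        current_f1 = f1
    gate.f1 = current_f1
    return gate


def validate_cluster_auroc(
    adata: ad.AnnData,
    labels: np.ndarray,
    gates: dict[int, MarkerGate],
    auroc_min: float = 0.7,
    n_folds: int = 5,
    seed: int = 0,
    logX: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-validated re-identification AUROC per cluster.

    A regularized logistic score trained only on each cluster's gate genes
    must separate the cluster from the rest with held-out AUROC above
    ``auroc_min``.  Clusters smaller than 10 cells reduce the fold count
    with a warning recorded in the table.
    """
    import warnings

    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    labels = np.asarray(labels)
    if logX is None:
        logX = normalize_log(adata)
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for cluster, gate in gates.items():
        target = (labels == cluster).astype(int)
        genes = [g for g, _, _ in gate.terms]
        note = ""
        if not genes:
            rows.append({"cluster": cluster, "auroc": 0.5, "passed": False, "note": "empty gate"})
            continue
        Xg = logX[:, [gene_index[g] for g in genes]]
        folds = n_folds
        if target.sum() < 10:
            folds = max(2, min(n_folds, int(target.sum())))
            note = f"small cluster, {folds} folds"
            warnings.warn(f"cluster {cluster} has <10 cells; using {folds} folds")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        clf = LogisticRegression(C=1.0, max_iter=1000)
        scores = cross_val_predict(clf, Xg, target, cv=skf, method="decision_function")
        auroc = float(roc_auc_score(target, scores))
        rows.append({"cluster": cluster, "auroc": auroc, "passed": auroc > auroc_min, "note": note})
    return pd.DataFrame(rows)
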