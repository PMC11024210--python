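"""Doublet detection: mock-doublet co-embedding and mixture-cluster tests.

Two complementary strategies:

- :func:`detect_doublets_mock` scores every real cell by how often mock
  doublets (sums of random cell pairs, depth-rescaled) appear among its
  nearest neighbours in a joint embedding;
- :func:`doublet_cluster_test` asks, for each cluster, whether it looks
  like a mixture of two other clusters: few genes distinguish it from the
  pooled pair beyond what distinguishes the parents, and its centroid
  lies on the segment between the parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .de import normalize_log, wilcoxon_de
from .qc import scale_and_pca, select_variable_genes

__all__ = ["detect_doublets_mock", "doublet_cluster_test", "default_embedding"]


def default_embedding(counts: np.ndarray, n_pcs: int = 20, n_hvg: int = 1000, seed: int = 0) -> np.ndarray:
    """CP10K + log1p, VST variable genes, scaled PCA; the stock embedding
    used when no custom embedding function is supplied."""
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    logX = np.log1p(counts / lib * 1e4)
    var = logX.var(axis=0)
    order = np.argsort(-var, kind="stable")[: min(n_hvg, counts.shape[1])]
    scores, _, _ = scale_and_pca(logX[:, order], n_comps=n_pcs, seed=seed)
    return scores


def detect_doublets_mock(
    adata: ad.AnnData,
    n_mock: int | None = None,
    k: int = 30,
    neighbor_frac_threshold: float | None = None,
    expected_rate: float = 0.075,
    embedding_fn=default_embedding,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mock-doublet kNN scores and flags for every real cell.

    ``n_mock`` artificial doublets (default: one per real cell) are built
    as gene-wise sums of two distinct random cells, rescaled to the mean
    parental depth, and co-embedded with the data.  A cell's score is the
    fraction of its ``k`` nearest neighbours that are mocks.  Flags are
    either scores above ``neighbor_frac_threshold``, or (default) the top
    ``round(expected_rate * n)`` scores - the usual practice of flagging
    as many cells as the experiment's expected doublet load.
    """
    n = adata.n_obs
    if n_mock is None:
        n_mock = n
    if n_mock < 1:
        raise ValueError("n_mock must be >= 1")
    if n_mock >= n * n:
        raise ValueError("n_mock must be smaller than n_cells^2")
    rng = np.random.default_rng(seed)
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    X = X.astype(float)
    pa = np.empty((n_mock, 2), dtype=int)
    for i in range(n_mock):
        pa[i] = rng.choice(n, 2, replace=False)
    lib = X.sum(axis=1)
    mock = X[pa[:, 0]] + X[pa[:, 1]]
    scale = 0.5 * (lib[pa[:, 0]] + lib[pa[:, 1]]) / np.maximum(mock.sum(axis=1), 1)
    mock = mock * scale[:, None]
    combined = np.vstack([X, mock])
    emb = embedding_fn(combined, seed=seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]
    scores = (idx >= n).mean(axis=1)
    if neighbor_frac_threshold is not None:
        flags = scores > neighbor_frac_threshold
    else:
        n_flag = int(round(expected_rate * n))
        flags = np.zeros(n, dtype=bool)
        if n_flag > 0:
            order = np.argsort(-scores, kind="stable")[:n_flag]
            flags[order] = True
    return scores, flags


@dataclass
class DoubletClusterReport:
    cluster: int
    parent_a: int
    parent_b: int
    n_unique_de: int
    projection: float  # centroid position on the parent segment
    candidate: bool


def doublet_cluster_test(
    adata: ad.AnnData,
    labels: np.ndarray,
    max_unique_de: int = 5,
    fdr: float = 0.05,
    min_abs_log2fc: float = 0.25,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Report clusters that look like mixtures of two other clusters.

    For every cluster C and pair (A, B), genes DE between C and A+B that
    are not DE between A and B in the same direction are counted; C is a
    candidate doublet cluster when its best pair leaves at most
    ``max_unique_de`` unique DE genes and its centroid projects inside
    the A-B segment.  With fewer than 3 clusters the report is empty.
    """
    labels = np.asarray(labels)
    ks = np.unique(labels)
    logX = normalize_log(adata)
    rows = []
    if ks.size < 3:
        return pd.DataFrame(
            columns=["cluster", "parent_a", "parent_b", "n_unique_de", "projection", "candidate"]
        )
    sizes = {k: int((labels == k).sum()) for k in ks}
    centroids = {k: logX[labels == k].mean(axis=0) for k in ks}
    for c in ks:
        if sizes[c] < min_cluster_size:
            continue
        best = None
        for ia, a in enumerate(ks):
            for b in ks[ia + 1 :]:
                if c in (a, b) or sizes[a] < min_cluster_size or sizes[b] < min_cluster_size:
                    continue
                sub = np.isin(labels, [c, a, b])
                subX = logX[sub]
                sub_labels = labels[sub]
                de_c = wilcoxon_de(subX, sub_labels == c, adata.var_names, fdr, min_abs_log2fc)
                mask_ab = np.isin(sub_labels, [a, b])
                de_ab = wilcoxon_de(subX[mask_ab], sub_labels[mask_ab] == a, adata.var_names, fdr, min_abs_log2fc)
                sig_c = de_c["significant"].to_numpy()
                # a C-vs-(A+B) gene is explained when it separates A from B
                explained = de_ab["significant"].to_numpy()
                n_unique = int((sig_c & ~explained).sum())
                seg = centroids[b] - centroids[a]
                denom = float(seg @ seg)
                t = float((centroids[c] - centroids[a]) @ seg / denom) if denom > 0 else np.inf
                cand = (n_unique <= max_unique_de) and (0.0 <= t <= 1.0)
                rec = (n_unique, a, b, t, cand)
                if best is None or rec[0] < best[0]:
                    best = rec
        if best is None:
            continue
        n_unique, a, b, t, cand = best
        rows.append(
            DoubletClusterReport(
                cluster=int(c),
                parent_a=int(a),
                parent_b=int(b),
                n_unique_de=n_unique,
                projection=t,
                candidate=bool(cand),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
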