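"""Weighted k-nearest-neighbour graphs for graph-based clustering.

Edges connect mutual/union kNN pairs in the PCA (or other) embedding and
are weighted either by the Jaccard overlap of the two cells' neighbour
sets (Phenograph style) or by shared-neighbour rank (SNN-Cliq style):
``1 - mean(rank_i(v), rank_j(v)) / k`` for the best shared neighbour
``v``, where each cell occupies rank 0 of its own list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = ["NeighborGraph", "build_knn_graph"]


@dataclass
class NeighborGraph:
    weights: sp.csr_matrix  # symmetric, zero diagonal, entries in [0,1]
    k: int
    weighting: str
    neighbor_indices: np.ndarray  # (n, k) kNN lists excluding self

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.weights, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def snn_cliq_weight(nbr: np.ndarray, i: int, j: int, k: int) -> float:
    """Shared-neighbour-rank weight between cells i and j.

    Rank lists include the cell itself at rank 0 followed by its kNN at
    ranks 1..k; the weight is 1 - s/k with s the smallest average rank of
    a shared list member, or 0 if the lists are disjoint."""
    ranks_i = {i: 0}
    for r, v in enumerate(nbr[i], start=1):
        ranks_i[int(v)] = r
    best = None
    for r_j, v in enumerate([j] + list(nbr[j]), start=0):
        v = int(v)
        if v in ranks_i:
            s = 0.5 * (ranks_i[v] + r_j)
            best = s if best is None else min(best, s)
    if best is None:
        return 0.0
    return max(0.0, 1.0 - best / k)


def jaccard_weight(nbr: np.ndarray, i: int, j: int, k: int) -> float:
    si = set(nbr[i].tolist())
    sj = set(nbr[j].tolist())
    inter = len(si & sj)
    union = len(si | sj)
    return inter / union if union else 0.0


def build_knn_graph(embedding: np.ndarray, k: int, weighting: str = "phenograph_jaccard") -> NeighborGraph:
    """Build the weighted kNN graph of an embedding.

    Edges exist between pairs (i, j) with j in kNN(i) (union-symmetrized);
    weights follow ``weighting`` in {"phenograph_jaccard", "snn_cliq"} and
    the graph is symmetrized by the maximum of the two directed weights.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    if weighting not in ("phenograph_jaccard", "snn_cliq"):
        raise ValueError(f"unknown weighting {weighting!r}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    nbr = idx[:, 1:]  # drop self

    weight_fn = jaccard_weight if weighting == "phenograph_jaccard" else snn_cliq_weight
    rows, cols, vals = [], [], []
    for i in range(n):
        for j in nbr[i]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            rows.append(a)
            cols.append(b)
            vals.append(weight_fn(nbr, i, j, k))
    # duplicate (i,j)/(j,i) entries collapse to their maximum
    W = _dedup_max(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    W = W + W.T
    W.setdiag(0)
    W.eliminate_zeros()
    return NeighborGraph(weights=W.tocsr(), k=k, weighting=weighting, neighbor_indices=nbr)


def _dedup_max(coo: sp.coo_matrix) -> sp.csr_matrix:
    order = np.lexsort((coo.col, coo.row))
    r, c, v = coo.row[order], coo.col[order], coo.data[order]
    out_r, out_c, out_v = [], [], []
    i = 0
    while i < len(r):
        j = i
        best = v[i]
        while j + 1 < len(r) and r[j + 1] == r[i] and c[j + 1] == c[i]:
            j += 1
            best = max(best, v[j])
        out_r.append(r[i])
        out_c.append(c[i])
        out_v.append(best)
        i = j + 1
    return sp.csr_matrix((out_v, (out_r, out_c)), shape=coo.shape)
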