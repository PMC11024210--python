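"""Quiescence-depth pseudo-ordering: diffusion map, bootstrapped-MST
distances and classical MDS.

The pseudo-ordering cascade runs: diffusion-map embedding of normalized
variable genes -> average along-tree distances over minimum spanning
trees of repeated 2/3 subsamples -> classical multidimensional scaling to
3-D -> elastic principal tree (see :mod:`qglia.principal_graph`).
Averaging over bootstrapped trees suppresses short-circuits that a single
MST through noisy data would create.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import pdist, squareform

__all__ = ["TreeDistance", "diffusion_map", "bootstrap_mst_distances", "mds_embed"]


def diffusion_map(
    logX: np.ndarray,
    n_components: int = 10,
    k_local: int = 7,
) -> np.ndarray:
    """Diffusion-map embedding with locally adaptive Gaussian kernel.

    The kernel bandwidth at cell i is its distance to the ``k_local``-th
    neighbour; K[i,j] = exp(-d_ij^2 / (sigma_i * sigma_j)).  The embedding
    takes eigenvectors 2..n_components+1 of the row-normalized transition
    matrix, scaled by their eigenvalues.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n = logX.shape[0]
    if n < n_components + 2:
        raise ValueError("too few cells for the requested components")
    D = squareform(pdist(logX))
    sigma = np.sort(D, axis=1)[:, min(k_local, n - 1)]
    sigma[sigma == 0] = D[D > 0].min() if (D > 0).any() else 1.0
    K = np.exp(-(D**2) / (sigma[:, None] * sigma[None, :]))
    d = K.sum(axis=1)
    # symmetric normalization shares the transition matrix's spectrum
    A = K / np.sqrt(d[:, None] * d[None, :])
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / np.sqrt(d)[:, None]
    comps = psi[:, 1 : n_components + 1] * vals[1 : n_components + 1][None, :]
    # sign convention: first nonzero coordinate of each component positive
    for j in range(comps.shape[1]):
        nz = np.nonzero(comps[:, j])[0]
        if nz.size and comps[nz[0], j] < 0:
            comps[:, j] *= -1
    return comps


@dataclass
class TreeDistance:
    D: np.ndarray  # averaged along-tree path lengths
    copresence: np.ndarray  # number of trees containing both cells
    n_trees: int
    subsample_frac: float
    n_imputed: int = 0


def bootstrap_mst_distances(
    embedding: np.ndarray,
    n_trees: int = 1000,
    frac: float = 2 / 3,
    seed: int = 0,
) -> TreeDistance:
    """Average along-tree distances over bootstrapped MSTs.

    Each tree: subsample ``floor(frac * n)`` cells without replacement,
    build the Euclidean MST, record all pairwise path lengths along the
    tree.  D[i,j] averages over the trees containing both cells; pairs
    never co-sampled (only possible at small ``n_trees``) are imputed by
    shortest paths through the observed-entry graph.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    n = embedding.shape[0]
    m = int(np.floor(frac * n))
    if m < 2:
        raise ValueError("frac * n must be at least 2")
    rng = np.random.default_rng(seed)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int32)
    for _ in range(n_trees):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        sub = embedding[idx]
        D = squareform(pdist(sub))
        mst = minimum_spanning_tree(D)
        paths = shortest_path(mst, method="D", directed=False)
        ix = np.ix_(idx, idx)
        total[ix] += paths
        count[ix] += 1
    with np.errstate(invalid="ignore"):
        D_avg = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(D_avg, 0.0)
    n_missing = int(np.isnan(D_avg).sum())
    if n_missing:
        observed = np.where(np.isnan(D_avg), 0.0, D_avg)
        g = sp.csr_matrix(observed)
        filled = shortest_path(g, method="D", directed=False)
        D_avg = np.where(np.isnan(D_avg), filled, D_avg)
    D_avg = 0.5 * (D_avg + D_avg.T)
    return TreeDistance(
        D=D_avg,
        copresence=count,
        n_trees=n_trees,
        subsample_frac=frac,
        n_imputed=n_missing // 2,
    )


def mds_embed(tree_dist: TreeDistance | np.ndarray, dim: int = 3) -> tuple[np.ndarray, float]:
    """Classical MDS (principal coordinates) of an averaged tree distance.

    Double-centers -D^2/2 and takes the top ``dim`` eigenvectors scaled by
    sqrt(eigenvalue); dimensions beyond the matrix rank are zero-padded
    with a warning.  Returns (coordinates, stress) where stress is the
    relative Frobenius mismatch between input and embedded distances.
    """
    import warnings

    D = tree_dist.D if isinstance(tree_dist, TreeDistance) else np.asarray(tree_dist, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite (impute first)")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    rank = int(pos.sum())
    if dim > rank:
        warnings.warn(f"requested dim {dim} exceeds rank {rank}; zero-padding")
    coords = np.zeros((n, dim))
    use = min(dim, rank)
    coords[:, :use] = vecs[:, :use] * np.sqrt(vals[:use])[None, :]
    emb_D = squareform(pdist(coords))
    denom = np.linalg.norm(D)
    stress = float(np.linalg.norm(emb_D - D) / denom) if denom > 0 else 0.0
    return coords, stress
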