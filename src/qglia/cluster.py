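"""The base-clusterer ensemble.

Six families feed the consensus stage: SLM-style modularity partitioning
(Leiden, RBConfiguration), multilevel Louvain, walktrap, spinglass (all on
the weighted kNN graph) plus density peaks and a Gaussian mixture with
BIC component-count selection (both on the embedding).  Spinglass is
available but not in the default set (slow, per-component annealing).

Each run returns a :class:`Labeling`; a failing method is recorded in the
labeling's params rather than aborting the ensemble.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .neighbors import NeighborGraph

__all__ = [
    "Labeling",
    "run_base_clusterings",
    "density_peaks",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("leiden", "louvain", "walktrap", "density_peaks", "gmm")


@dataclass
class Labeling:
    method: str
    labels: np.ndarray  # dense 0..K-1
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _densify_labels(labels: np.ndarray) -> np.ndarray:
    _, dense = np.unique(labels, return_inverse=True)
    return dense.astype(int)


def _to_igraph(graph: NeighborGraph) -> ig.Graph:
    coo = graph.weights.tocoo()
    mask = coo.row < coo.col
    edges = list(zip(coo.row[mask].tolist(), coo.col[mask].tolist()))
    g = ig.Graph(n=graph.n_cells, edges=edges)
    g.es["weight"] = coo.data[mask].tolist()
    return g


def density_peaks(
    embedding: np.ndarray,
    dc_quantile: float = 0.02,
    outlier_sd: float = 3.0,
) -> np.ndarray:
    """Density-peaks clustering with an automated decision-graph cut.

    Local density rho uses a Gaussian kernel at bandwidth d_c (the
    ``dc_quantile`` quantile of pairwise distances); delta is the distance
    to the nearest point of higher density.  Centers are the points whose
    gamma = rho * delta is more than ``outlier_sd`` standard deviations
    above the mean (the original method's manual decision graph replaced
    by an outlier rule); remaining points inherit the label of their
    nearest denser neighbour.
    """
    n = embedding.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    D = squareform(pdist(embedding))
    tri = D[np.triu_indices(n, k=1)]
    dc = np.quantile(tri, dc_quantile)
    if dc == 0:
        dc = tri[tri > 0].min() if (tri > 0).any() else 1.0
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1.0
    order = np.argsort(-rho, kind="stable")
    delta = np.zeros(n)
    nearest_denser = np.full(n, -1)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = D[i].max()
            continue
        higher = order[:pos]
        j = higher[np.argmin(D[i, higher])]
        delta[i] = D[i, j]
        nearest_denser[i] = j
    gamma = rho * delta
    thr = gamma.mean() + outlier_sd * gamma.std(ddof=0)
    centers = np.where(gamma > thr)[0]
    if centers.size == 0:
        centers = np.array([order[0]])
    labels = np.full(n, -1)
    for c_id, c in enumerate(centers):
        labels[c] = c_id
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nearest_denser[i]]
    return _densify_labels(labels)


def _gmm_bic(embedding: np.ndarray, seed: int, k_max: int = 15) -> tuple[np.ndarray, int]:
    from sklearn.mixture import GaussianMixture

    best, best_bic, best_k = None, np.inf, 1
    k_max = min(k_max, embedding.shape[0])
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            random_state=seed,
            n_init=2,
            reg_covar=1e-4,
        ).fit(embedding)
        bic = gm.bic(embedding)
        if bic < best_bic:
            best, best_bic, best_k = gm, bic, k
    return _densify_labels(best.predict(embedding)), best_k


def run_base_clusterings(
    graph: NeighborGraph | None,
    embedding: np.ndarray | None,
    methods=DEFAULT_METHODS,
    seeds=(0,),
    resolution: float = 1.0,
    gmm_k_max: int = 15,
) -> list[Labeling]:
    """Run every (method, seed) combination and collect labelings.

    Graph methods need ``graph``; embedding methods ("density_peaks",
    "gmm") need ``embedding``.  At least two methods are required.
    Failures of a single method are recorded (params["failed"]) and
    skipped.
    """
    if len(methods) < 2:
        raise ValueError("the ensemble needs at least 2 methods")
    out: list[Labeling] = []
    for method in methods:
        for seed in seeds:
            try:
                labels, params = _run_one(method, graph, embedding, int(seed), resolution, gmm_k_max)
            except Exception as err:  # noqa: BLE001 - single-method failure is not fatal
                out.append(Labeling(method=method, labels=np.zeros(0, dtype=int), seed=int(seed), params={"failed": str(err)}))
                continue
            out.append(Labeling(method=method, labels=labels, seed=int(seed), params=params))
            if method in ("walktrap", "density_peaks"):
                break  # deterministic, seed-independent
    return [lab for lab in out if "failed" not in lab.params or lab.labels.size]


def _run_one(method, graph, embedding, seed, resolution, gmm_k_max):
    if method in ("leiden", "slm", "louvain", "walktrap", "spinglass"):
        if graph is None:
            raise ValueError(f"{method} requires a neighbor graph")
        g = _to_igraph(graph)
        ig.set_random_number_generator(random.Random(seed))
        if method in ("leiden", "slm"):
            # modularity objective, matching the SLM family
            if resolution == 1.0:
                part = leidenalg.find_partition(
                    g, leidenalg.ModularityVertexPartition, weights="weight", seed=seed, n_iterations=2
                )
            else:
                part = leidenalg.find_partition(
                    g,
                    leidenalg.RBConfigurationVertexPartition,
                    weights="weight",
                    resolution_parameter=resolution,
                    seed=seed,
                    n_iterations=2,
                )
            return _densify_labels(np.array(part.membership)), {"resolution": resolution}
        if method == "louvain":
            part = g.community_multilevel(weights="weight")
            return _densify_labels(np.array(part.membership)), {}
        if method == "walktrap":
            dend = g.community_walktrap(weights="weight", steps=4)
            return _densify_labels(np.array(dend.as_clustering().membership)), {"steps": 4}
        if method == "spinglass":
            comps = g.connected_components()
            labels = np.zeros(g.vcount(), dtype=int)
            offset = 0
            for comp in comps:
                sub = g.subgraph(comp)
                if sub.vcount() < 3:
                    membership = [0] * sub.vcount()
                else:
                    membership = sub.community_spinglass(weights="weight").membership
                for v, m in zip(comp, membership):
                    labels[v] = offset + m
                offset = labels.max() + 1
            return _densify_labels(labels), {"per_component": True}
    if method == "density_peaks":
        if embedding is None:
            raise ValueError("density_peaks requires an embedding")
        return density_peaks(embedding), {}
    if method == "gmm":
        if embedding is None:
            raise ValueError("gmm requires an embedding")
        labels, k = _gmm_bic(embedding, seed, k_max=gmm_k_max)
        return labels, {"k_selected": k}
    raise ValueError(f"unknown method {method!r}")
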