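"""Elastic principal trees: skeleton fitting, pruning, cell projection.

A principal tree of up to ``max_nodes`` nodes is fit to the MDS embedding
by alternating minimization of the elastic energy

    E = (1/n) sum_i ||x_i - c_{k(i)}||^2
        + lambda * sum_edges ||c_a - c_b||^2
        + mu * sum_{deg(j) >= 2} ||c_j - mean(neighbours(j))||^2

with hard nearest-node assignment, exact linear solves for the node
positions, and tree topology maintained as the minimum spanning tree of
the current node positions.  The skeleton grows one node at a time
towards the worst-approximated data point.  lambda and mu act on data
standardized to unit overall variance, so their defaults (0.1, 0.5) are
relative to the data scale.  Leaf paths supported by fewer than
``min_branch_frac`` of the cells are treated as density artifacts and
dropped after fitting.

Noisy spurs produced by uneven density are pruned when a maximal path
emerges and terminates in the same cell cluster (and its removal keeps
every cluster represented), after which cells are re-projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PrincipalGraph",
    "fit_principal_graph",
    "diameter_root",
    "prune_same_cluster_paths",
    "project_and_order",
    "depth_associated_genes",
]


@dataclass
class PrincipalGraph:
    nodes: np.ndarray  # (n_nodes, dim)
    edges: list  # [(a, b), ...]
    # per-cell projection, filled by project_and_order
    cell_edge: np.ndarray | None = None  # index into edges
    cell_t: np.ndarray | None = None  # position along edge in [0,1]
    pseudo_order: np.ndarray | None = None
    branch: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> list[list[int]]:
        adj = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


def _mst_edges(nodes: np.ndarray) -> list[tuple[int, int]]:
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(nodes))
    T = minimum_spanning_tree(D).tocoo()
    return [(int(a), int(b)) for a, b in zip(T.row, T.col)]


def _assign(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _solve_positions(
    points: np.ndarray,
    assign: np.ndarray,
    n_nodes: int,
    edges: list,
    lam: float,
    mu: float,
) -> np.ndarray:
    n = points.shape[0]
    counts = np.bincount(assign, minlength=n_nodes).astype(float)
    sums = np.zeros((n_nodes, points.shape[1]))
    np.add.at(sums, assign, points)
    A = np.diag(counts / n)
    for a, b in edges:
        A[a, a] += lam
        A[b, b] += lam
        A[a, b] -= lam
        A[b, a] -= lam
    deg = np.zeros(n_nodes, dtype=int)
    adj = [[] for _ in range(n_nodes)]
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
        adj[a].append(b)
        adj[b].append(a)
    for j in range(n_nodes):
        if deg[j] < 2:
            continue
        row = np.zeros(n_nodes)
        row[j] = 1.0
        for v in adj[j]:
            row[v] -= 1.0 / deg[j]
        A += mu * np.outer(row, row)
    A += 1e-9 * np.eye(n_nodes)
    return np.linalg.solve(A, sums / n)


def fit_principal_graph(
    points: np.ndarray,
    max_nodes: int = 100,
    lam: float = 0.1,
    mu: float = 0.5,
    inner_iters: int = 8,
    final_iters: int = 30,
    tol: float = 1e-4,
    min_branch_frac: float = 0.05,
) -> PrincipalGraph:
    """Fit an elastic principal tree to embedded points.

    Grows from a 2-node principal-component segment to ``max_nodes``,
    adding each node midway between the worst-approximated data point and
    its nearest node, re-solving positions and re-linking the tree (MST
    over nodes) after every step.
    """
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    n, dim = points.shape
    if n < max(10, max_nodes // 2):
        raise ValueError("too few points for the requested node budget")
    scale = points.std()
    if scale == 0:
        raise ValueError("degenerate point cloud")
    X = (points - points.mean(axis=0)) / scale

    # init: segment along the first principal component
    _, _, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    proj = X @ Vt[0]
    lo, hi = np.quantile(proj, [0.05, 0.95])
    nodes = np.vstack([Vt[0] * lo, Vt[0] * hi])
    edges = [(0, 1)]

    def optimize(nodes, edges, iters):
        prev_energy = np.inf
        assign = _assign(X, nodes)
        for _ in range(iters):
            nodes = _solve_positions(X, assign, nodes.shape[0], edges, lam, mu)
            edges = _mst_edges(nodes)
            assign = _assign(X, nodes)
            resid = ((X - nodes[assign]) ** 2).sum(axis=1)
            energy = resid.mean()
            if abs(prev_energy - energy) < tol * max(prev_energy, 1e-12):
                break
            prev_energy = energy
        return nodes, edges, assign

    nodes, edges, assign = optimize(nodes, edges, inner_iters)
    while nodes.shape[0] < max_nodes:
        resid = ((X - nodes[assign]) ** 2).sum(axis=1)
        worst = int(np.argmax(resid))
        new = 0.5 * (X[worst] + nodes[assign[worst]])
        nodes = np.vstack([nodes, new])
        edges = _mst_edges(nodes)
        nodes, edges, assign = optimize(nodes, edges, inner_iters)
    nodes, edges, assign = optimize(nodes, edges, final_iters)

    graph = PrincipalGraph(
        nodes=nodes * scale + points.mean(axis=0),
        edges=edges,
        meta={"lambda": lam, "mu": mu, "max_nodes": max_nodes},
    )
    min_cells = max(3, int(np.ceil(min_branch_frac * n)))
    graph = _prune_empty_spurs(graph, points, min_cells=min_cells)
    return graph


def diameter_root(graph: PrincipalGraph) -> int:
    """Endpoint of the tree diameter: the natural root of a linear or
    mildly branched trajectory when no biological anchor is supplied."""
    n = graph.n_nodes
    W = sp.lil_matrix((n, n))
    for a, b in graph.edges:
        w = float(np.linalg.norm(graph.nodes[a] - graph.nodes[b]))
        W[a, b] = W[b, a] = max(w, 1e-12)
    D = shortest_path(W.tocsr(), directed=False)
    i, _ = np.unravel_index(np.argmax(D), D.shape)
    return int(i)


def _maximal_paths(graph: PrincipalGraph) -> list[list[int]]:
    """Decompose the tree into maximal paths between nodes of degree != 2."""
    deg = graph.degrees()
    adj = graph.adjacency()
    endpoints = [v for v in range(graph.n_nodes) if deg[v] != 2]
    if not endpoints:  # cycle-free tree always has leaves; guard anyway
        endpoints = [0]
    paths = []
    visited_edges = set()
    for s in endpoints:
        for v in adj[s]:
            e = (min(s, v), max(s, v))
            if e in visited_edges:
                continue
            path = [s, v]
            visited_edges.add(e)
            while deg[path[-1]] == 2:
                nxt = [u for u in adj[path[-1]] if u != path[-2]][0]
                visited_edges.add((min(path[-1], nxt), max(path[-1], nxt)))
                path.append(nxt)
            paths.append(path)
    return paths


def _subgraph(graph: PrincipalGraph, drop_nodes: set[int]) -> PrincipalGraph:
    keep = [v for v in range(graph.n_nodes) if v not in drop_nodes]
    remap = {v: i for i, v in enumerate(keep)}
    edges = [
        (remap[a], remap[b])
        for a, b in graph.edges
        if a not in drop_nodes and b not in drop_nodes
    ]
    return PrincipalGraph(nodes=graph.nodes[keep], edges=edges, meta=dict(graph.meta))


def _path_length(graph: PrincipalGraph, path: list[int]) -> float:
    return float(
        sum(np.linalg.norm(graph.nodes[a] - graph.nodes[b]) for a, b in zip(path[:-1], path[1:]))
    )


def _prune_empty_spurs(
    graph: PrincipalGraph,
    points: np.ndarray,
    min_cells: int = 3,
    min_length_frac: float = 0.1,
) -> PrincipalGraph:
    """Drop junction-attached leaf paths that are geometrically short
    (< ``min_length_frac`` of the skeleton's total edge length) or thinly
    supported (< ``min_cells`` cells) - the density artifacts a skeleton
    grows near branch points, as opposed to genuine arms."""
    while True:
        assign = _assign(points, graph.nodes)
        deg = graph.degrees()
        total_len = sum(
            np.linalg.norm(graph.nodes[a] - graph.nodes[b]) for a, b in graph.edges
        )
        changed = False
        for path in _maximal_paths(graph):
            # leaf path: one end is a leaf, other end a junction
            a, b = path[0], path[-1]
            if deg[a] == 1 and deg[b] > 2:
                body = path[:-1]
            elif deg[b] == 1 and deg[a] > 2:
                body = path[1:]
            else:
                continue
            n_cells = int(np.isin(assign, body).sum())
            if n_cells < min_cells or _path_length(graph, path) < min_length_frac * total_len:
                graph = _subgraph(graph, set(body))
                changed = True
                break
        if not changed:
            return graph


def prune_same_cluster_paths(
    graph: PrincipalGraph,
    points: np.ndarray,
    cluster_labels: np.ndarray,
    max_cell_frac: float = 0.1,
) -> PrincipalGraph:
    """Remove noisy leaf paths that emerge and terminate in the same cluster.

    Each maximal path is labelled at both ends by the majority cluster of
    the cells projected onto its terminal nodes' halves; a leaf path whose
    two end labels agree is deleted, provided it is a minor path (claims
    at most ``max_cell_frac`` of the cells - the uneven-density artifacts
    this step targets, not genuine trajectory segments), every cluster
    stays represented and the graph stays connected.  At least one path
    is always retained.
    """
    cluster_labels = np.asarray(cluster_labels)
    while True:
        paths = _maximal_paths(graph)
        if len(paths) <= 1:
            return graph
        assign = _assign(points, graph.nodes)
        deg = graph.degrees()

        def end_label(path, end_node):
            # majority cluster among cells assigned to the end half of the path
            half = path[: max(1, len(path) // 2)] if path[0] == end_node else path[len(path) // 2 :]
            cells = np.isin(assign, half)
            if not cells.any():
                return None
            vals, cnt = np.unique(cluster_labels[cells], return_counts=True)
            return vals[np.argmax(cnt)]

        removed = False
        for path in paths:
            a, b = path[0], path[-1]
            leaf_first = deg[a] == 1 and deg[b] > 2
            leaf_last = deg[b] == 1 and deg[a] > 2
            if not (leaf_first or leaf_last):
                continue
            la, lb = end_label(path, a), end_label(path, b)
            if la is None or lb is None or la != lb:
                continue
            body = path[:-1] if leaf_first else path[1:]
            if np.isin(assign, body).mean() > max_cell_frac:
                continue  # genuine segment, not a density artifact
            candidate = _subgraph(graph, set(body))
            if not candidate.edges and candidate.n_nodes > 1:
                continue  # would disconnect
            # every cluster must remain the majority at some surviving node
            new_assign = _assign(points, candidate.nodes)
            represented = set()
            for v in range(candidate.n_nodes):
                cells = new_assign == v
                if cells.any():
                    vals, cnt = np.unique(cluster_labels[cells], return_counts=True)
                    represented.add(vals[np.argmax(cnt)])
            if set(np.unique(cluster_labels)) - represented:
                continue
            graph = candidate
            removed = True
            break
        if not removed:
            return graph


def project_and_order(
    graph: PrincipalGraph,
    points: np.ndarray,
    root: int = 0,
) -> PrincipalGraph:
    """Project cells orthogonally onto the nearest edge and compute the
    along-graph pseudo-order from ``root`` scaled to [0, 1], plus branch
    ids (maximal-path index of the supporting edge)."""
    if root < 0 or root >= graph.n_nodes:
        raise ValueError("root not in graph")
    if not graph.edges:
        raise ValueError("graph has no edges")
    points = np.asarray(points, dtype=float)
    E = len(graph.edges)
    n = points.shape[0]
    best_d2 = np.full(n, np.inf)
    best_e = np.zeros(n, dtype=int)
    best_t = np.zeros(n)
    for e, (a, b) in enumerate(graph.edges):
        pa, pb = graph.nodes[a], graph.nodes[b]
        ab = pb - pa
        L2 = float(ab @ ab)
        t = ((points - pa) @ ab / L2).clip(0, 1) if L2 > 0 else np.zeros(n)
        proj = pa[None, :] + t[:, None] * ab[None, :]
        d2 = ((points - proj) ** 2).sum(axis=1)
        upd = d2 < best_d2
        best_d2[upd] = d2[upd]
        best_e[upd] = e
        best_t[upd] = t[upd]

    # along-tree distance from root to every node
    W = sp.lil_matrix((graph.n_nodes, graph.n_nodes))
    for a, b in graph.edges:
        w = float(np.linalg.norm(graph.nodes[a] - graph.nodes[b]))
        W[a, b] = W[b, a] = max(w, 1e-12)
    droot = shortest_path(W.tocsr(), method="D", directed=False, indices=root)
    if not np.all(np.isfinite(droot)):
        raise ValueError("graph is disconnected")

    lengths = np.array([np.linalg.norm(graph.nodes[a] - graph.nodes[b]) for a, b in graph.edges])
    a_idx = np.array([a for a, _ in graph.edges])
    b_idx = np.array([b for _, b in graph.edges])
    da = droot[a_idx[best_e]] + best_t * lengths[best_e]
    db = droot[b_idx[best_e]] + (1 - best_t) * lengths[best_e]
    order = np.minimum(da, db)
    span = order.max()
    order = order / span if span > 0 else order

    paths = _maximal_paths(graph)
    edge_to_path = {}
    for pid, path in enumerate(paths):
        for a, b in zip(path[:-1], path[1:]):
            edge_to_path[(min(a, b), max(a, b))] = pid
    branch = np.array(
        [edge_to_path.get((min(a, b), max(a, b)), 0) for a, b in graph.edges]
    )[best_e]

    out = PrincipalGraph(nodes=graph.nodes, edges=graph.edges, meta=dict(graph.meta))
    out.cell_edge = best_e
    out.cell_t = best_t
    out.pseudo_order = order
    out.branch = branch
    return out


def depth_associated_genes(
    logX: np.ndarray,
    gene_names,
    pseudo_order: np.ndarray,
) -> pd.DataFrame:
    """Spearman association of every gene with the pseudo-order.

    Returns gene, rho, p, BH q sorted by rho; constant genes get rho 0,
    p 1.  The rho column doubles as a signed ranking for preranked GSEA.
    """
    from scipy.stats import t as t_dist

    po = rankdata(pseudo_order)
    n = po.size
    R = rankdata(logX, axis=0)
    po_c = po - po.mean()
    R_c = R - R.mean(axis=0)
    denom = np.sqrt((R_c**2).sum(axis=0) * (po_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (R_c * po_c[:, None]).sum(axis=0) / denom, 0.0)
    rho = np.clip(rho, -1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    pvals = np.where(np.abs(rho) < 1, 2 * t_dist.sf(np.abs(tstat), df=n - 2), 0.0)
    pvals = np.where(rho == 0, 1.0, pvals)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({"gene": np.asarray(gene_names), "rho": rho, "p": pvals, "q": qvals})
    return out.sort_values("rho", ascending=False).reset_index(drop=True)
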