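"""Synthetic single-cell data with planted ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
negative-binomial counts with log-normal library sizes, cluster-specific
marker programs, a low-quality cell mode (shrunken libraries, elevated
mitochondrial load), injected doublets, a continuous quiescence-depth axis
driving antagonistic gene modules, clone tables and two-species ortholog
tables with teleost-style one-to-many groups.

The negative binomial is parameterized by mean ``mu`` and dispersion
``theta`` with variance ``mu + mu**2 / theta`` and sampled as a
gamma-Poisson mixture.  All outputs are bit-reproducible from the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_counts",
    "inject_doublets",
    "generate_trajectory_counts",
    "generate_clone_table",
    "generate_ortholog_table",
]

MITO_PREFIX = "mt-"


@dataclass
class SimConfig:
    """Parameters of the count-matrix generator.

    Defaults describe the standard planted fixture used throughout the test
    suite: 1,500 cells in 6 clusters with 30 markers each at natural-log
    fold change 2, library sizes tuned so the detected-gene (nGene)
    distribution peaks near 900 genes, and a 2% mitochondrial gene block.
    """

    n_cells: int = 1500
    n_genes: int = 2000
    n_clusters: int = 6
    n_markers_per_cluster: int = 30
    marker_logfc: float = 2.0
    libsize_mean: float = 3000.0
    libsize_dispersion: float = 0.35  # sdlog of the log-normal library size
    nb_dispersion: float = 2.0  # NB theta
    mito_fraction_mean: float = 0.03
    lowq_fraction: float = 0.0
    lowq_libsize_scale: float = 0.08
    lowq_mito_mean: float = 0.25
    doublet_rate: float = 0.0
    trajectory: bool = False
    depth_module_size: int = 40
    branching: bool = False
    branch_point: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_cells",
            "n_genes",
            "n_clusters",
            "n_markers_per_cluster",
            "depth_module_size",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_genes <= 0 or self.n_clusters <= 0:
            raise ValueError("n_genes and n_clusters must be positive")
        for name in ("marker_logfc",):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("libsize_mean", "libsize_dispersion", "nb_dispersion"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive real, got {v!r}")
        for name in (
            "mito_fraction_mean",
            "lowq_fraction",
            "lowq_mito_mean",
            "doublet_rate",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.doublet_rate >= 1.0:
            raise ValueError("doublet_rate must be < 1")
        if self.n_markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("n_markers_per_cluster * n_clusters exceeds n_genes")
        if self.trajectory and self.depth_module_size == 0:
            raise ValueError("trajectory enabled but depth_module_size is 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated matrix."""

    cluster_label: np.ndarray  # int per cell, -1 for doublets
    is_lowq: np.ndarray  # bool per cell
    is_doublet: np.ndarray  # bool per cell
    marker_sets: dict = field(default_factory=dict)  # cluster -> list of gene names
    depth: np.ndarray | None = None  # float in [0,1] per cell, trajectory only
    depth_genes: pd.DataFrame | None = None  # columns: gene, sign
    branch: np.ndarray | None = None  # 0 trunk, 1/2 arms, trajectory+branching
    doublet_parents: np.ndarray | None = None  # (n_doublets, 2) parent indices


def _mito_gene_count(n_genes: int) -> int:
    return int(np.ceil(0.02 * n_genes)) if n_genes else 0


def _gene_names(n_genes: int) -> list[str]:
    n_mito = _mito_gene_count(n_genes)
    names = [f"{MITO_PREFIX}{i + 1}" for i in range(n_mito)]
    names += [f"gene{i + 1}" for i in range(n_genes - n_mito)]
    return names


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw of NB(mu, theta) with Var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam)


def _empty_adata(n_genes: int) -> ad.AnnData:
    adata = ad.AnnData(
        X=sp.csr_matrix((0, n_genes), dtype=np.int64),
        obs=pd.DataFrame(index=pd.Index([], name="cell_id")),
        var=pd.DataFrame(index=pd.Index(_gene_names(n_genes), name="gene_id")),
    )
    return adata


def generate_counts(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate an NB count matrix with planted clusters and QC structure.

    Returns an :class:`anndata.AnnData` with integer CSR counts and obs
    columns ``replicate``, plus the :class:`SyntheticTruth`.  Cluster
    markers are multiplied by ``exp(marker_logfc)`` in their own cluster;
    low-quality cells get libraries scaled by ``lowq_libsize_scale`` and a
    mitochondrial fraction centred on ``lowq_mito_mean``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes
    if n == 0:
        truth = SyntheticTruth(
            cluster_label=np.empty(0, dtype=int),
            is_lowq=np.zeros(0, dtype=bool),
            is_doublet=np.zeros(0, dtype=bool),
        )
        return _empty_adata(g), truth

    gene_names = _gene_names(g)
    n_mito = _mito_gene_count(g)
    mito_idx = np.arange(n_mito)
    body_idx = np.arange(n_mito, g)

    # baseline relative abundances: log-normal across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)

    # cluster markers drawn from non-mito genes, disjoint across clusters
    labels = rng.integers(0, config.n_clusters, size=n)
    marker_sets: dict[int, list[str]] = {}
    marker_idx = {}
    if config.n_markers_per_cluster > 0:
        perm = rng.permutation(body_idx)
        for c in range(config.n_clusters):
            sl = perm[c * config.n_markers_per_cluster : (c + 1) * config.n_markers_per_cluster]
            marker_idx[c] = np.sort(sl)
            marker_sets[c] = [gene_names[i] for i in marker_idx[c]]
    else:
        for c in range(config.n_clusters):
            marker_idx[c] = np.empty(0, dtype=int)
            marker_sets[c] = []

    is_lowq = rng.random(n) < config.lowq_fraction

    sdlog = config.libsize_dispersion
    libsize = rng.lognormal(mean=np.log(config.libsize_mean) - sdlog**2 / 2, sigma=sdlog, size=n)
    libsize = np.where(is_lowq, libsize * config.lowq_libsize_scale, libsize)

    # per-cell mito fraction ~ Beta with fixed concentration
    conc = 100.0
    m = np.where(is_lowq, config.lowq_mito_mean, config.mito_fraction_mean)
    frac_mito = rng.beta(np.maximum(m * conc, 1e-6), np.maximum((1 - m) * conc, 1e-6))

    counts = np.zeros((n, g), dtype=np.int64)
    fc = np.exp(config.marker_logfc)
    p_mito = base[mito_idx] / base[mito_idx].sum() if n_mito else np.empty(0)
    for c in range(config.n_clusters):
        cells = np.where(labels == c)[0]
        if cells.size == 0:
            continue
        w = base[body_idx].copy()
        if marker_idx[c].size:
            local = np.searchsorted(body_idx, marker_idx[c])
            w[local] *= fc
        w /= w.sum()
        mu_body = libsize[cells, None] * (1 - frac_mito[cells, None]) * w[None, :]
        counts[np.ix_(cells, body_idx)] = _nb_sample(rng, mu_body, config.nb_dispersion)
        if n_mito:
            mu_mito = libsize[cells, None] * frac_mito[cells, None] * p_mito[None, :]
            counts[np.ix_(cells, mito_idx)] = _nb_sample(rng, mu_mito, config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "replicate": np.where(rng.random(n) < 0.5, "rep1", "rep3"),
        },
        index=pd.Index([f"cell{i + 1}" for i in range(n)], name="cell_id"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    truth = SyntheticTruth(
        cluster_label=labels,
        is_lowq=is_lowq,
        is_doublet=np.zeros(n, dtype=bool),
        marker_sets=marker_sets,
    )
    if config.doublet_rate > 0:
        adata, truth = inject_doublets(adata, config.doublet_rate, seed=config.seed + 1, truth=truth)
    return adata, truth


def inject_doublets(
    adata: ad.AnnData,
    rate: float,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Append ``round(rate * n_cells)`` doublets, each the exact gene-wise
    sum of two distinct randomly chosen singlet cells."""
    if not (0 <= rate < 1):
        raise ValueError("doublet rate must lie in [0, 1)")
    n = adata.n_obs
    n_doub = int(round(rate * n))
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SyntheticTruth(
            cluster_label=np.zeros(n, dtype=int),
            is_lowq=np.zeros(n, dtype=bool),
            is_doublet=np.zeros(n, dtype=bool),
        )
    if n_doub == 0:
        return adata, truth
    parents = np.empty((n_doub, 2), dtype=int)
    for i in range(n_doub):
        parents[i] = rng.choice(n, size=2, replace=False)
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    doub = X[parents[:, 0]] + X[parents[:, 1]]
    new_X = sp.vstack([X, doub]).tocsr()
    obs = adata.obs.copy()
    dob = pd.DataFrame(index=pd.Index([f"doublet{i + 1}" for i in range(n_doub)], name=obs.index.name))
    for col in obs.columns:
        dob[col] = obs[col].iloc[parents[:, 0]].to_numpy()
    new_obs = pd.concat([obs, dob])
    out = ad.AnnData(X=new_X, obs=new_obs, var=adata.var.copy())
    new_truth = SyntheticTruth(
        cluster_label=np.concatenate([truth.cluster_label, np.full(n_doub, -1)]),
        is_lowq=np.concatenate([truth.is_lowq, np.zeros(n_doub, dtype=bool)]),
        is_doublet=np.concatenate([truth.is_doublet, np.ones(n_doub, dtype=bool)]),
        marker_sets=truth.marker_sets,
        depth=None if truth.depth is None else np.concatenate([truth.depth, np.full(n_doub, np.nan)]),
        depth_genes=truth.depth_genes,
        doublet_parents=parents,
    )
    return out, new_truth


def generate_trajectory_counts(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Counts along a continuous quiescence-depth axis.

    Each cell carries a latent depth ~ Uniform(0, 1).  A "deep" module of
    ``depth_module_size`` genes is multiplicatively up-regulated towards
    depth 1 (factor ``exp(marker_logfc * (depth - 1/2))``) and a mirrored
    "shallow" module towards depth 0.  With ``branching`` enabled, cells
    past ``branch_point`` split into two arms, each with its own module.
    Cluster labels (used by graph pruning downstream) are depth terciles,
    with the two arms labelled separately when branching.
    """
    config = replace(config, trajectory=True)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes
    if n == 0:
        truth = SyntheticTruth(
            cluster_label=np.empty(0, dtype=int),
            is_lowq=np.zeros(0, dtype=bool),
            is_doublet=np.zeros(0, dtype=bool),
            depth=np.empty(0),
        )
        return _empty_adata(g), truth

    gene_names = _gene_names(g)
    n_mito = _mito_gene_count(g)
    body_idx = np.arange(n_mito, g)
    m = config.depth_module_size
    n_modules = 2 + (2 if config.branching else 0)
    if n_modules * m > body_idx.size:
        raise ValueError("depth modules exceed available genes")
    perm = rng.permutation(body_idx)
    deep_idx = np.sort(perm[:m])
    shallow_idx = np.sort(perm[m : 2 * m])
    branch_a_idx = np.sort(perm[2 * m : 3 * m]) if config.branching else np.empty(0, dtype=int)
    branch_b_idx = np.sort(perm[3 * m : 4 * m]) if config.branching else np.empty(0, dtype=int)

    depth = rng.uniform(0.0, 1.0, size=n)
    branch = np.zeros(n, dtype=int)
    if config.branching:
        past = depth > config.branch_point
        branch[past] = rng.integers(1, 3, size=past.sum())

    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    sdlog = config.libsize_dispersion
    libsize = rng.lognormal(mean=np.log(config.libsize_mean) - sdlog**2 / 2, sigma=sdlog, size=n)
    conc = 100.0
    frac_mito = rng.beta(config.mito_fraction_mean * conc, (1 - config.mito_fraction_mean) * conc, size=n)

    # multiplicative depth effects on NB means, renormalized per cell
    w = np.tile(base[body_idx], (n, 1))
    lfc = config.marker_logfc
    loc = {v: i for i, v in enumerate(body_idx)}
    deep_l = np.array([loc[i] for i in deep_idx], dtype=int)
    shal_l = np.array([loc[i] for i in shallow_idx], dtype=int)
    w[:, deep_l] *= np.exp(lfc * (depth[:, None] - 0.5))
    w[:, shal_l] *= np.exp(lfc * (0.5 - depth[:, None]))
    if config.branching:
        a_l = np.array([loc[i] for i in branch_a_idx], dtype=int)
        b_l = np.array([loc[i] for i in branch_b_idx], dtype=int)
        prog = np.clip(depth - config.branch_point, 0, None) / (1 - config.branch_point)
        w[:, a_l] *= np.exp(lfc * prog[:, None] * (branch == 1)[:, None])
        w[:, b_l] *= np.exp(lfc * prog[:, None] * (branch == 2)[:, None])
    w /= w.sum(axis=1, keepdims=True)

    counts = np.zeros((n, g), dtype=np.int64)
    mu_body = libsize[:, None] * (1 - frac_mito[:, None]) * w
    counts[:, body_idx] = _nb_sample(rng, mu_body, config.nb_dispersion)
    if n_mito:
        p_mito = base[:n_mito] / base[:n_mito].sum()
        mu_mito = libsize[:, None] * frac_mito[:, None] * p_mito[None, :]
        counts[:, :n_mito] = _nb_sample(rng, mu_mito, config.nb_dispersion)

    # depth terciles as cluster labels; arms labelled separately
    terc = np.digitize(depth, [1 / 3, 2 / 3])
    labels = terc.copy()
    if config.branching:
        labels = np.where(branch == 2, 3, labels)

    obs = pd.DataFrame(
        {"replicate": "rep1"},
        index=pd.Index([f"cell{i + 1}" for i in range(n)], name="cell_id"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    depth_genes = pd.DataFrame(
        {
            "gene": [gene_names[i] for i in deep_idx] + [gene_names[i] for i in shallow_idx],
            "sign": [1] * len(deep_idx) + [-1] * len(shallow_idx),
        }
    )
    marker_sets = {"deep": [gene_names[i] for i in deep_idx], "shallow": [gene_names[i] for i in shallow_idx]}
    if config.branching:
        marker_sets["branch_a"] = [gene_names[i] for i in branch_a_idx]
        marker_sets["branch_b"] = [gene_names[i] for i in branch_b_idx]
    truth = SyntheticTruth(
        cluster_label=labels,
        is_lowq=np.zeros(n, dtype=bool),
        is_doublet=np.zeros(n, dtype=bool),
        marker_sets=marker_sets,
        depth=depth,
        depth_genes=depth_genes,
        branch=branch if config.branching else None,
    )
    return adata, truth


def generate_clone_table(
    n_hemispheres: int,
    clones_per_hemisphere: tuple[int, int] | int,
    p_rg_only: float | dict,
    chase_days: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli clone compositions by hemisphere and chase time.

    ``clones_per_hemisphere`` is either a fixed count or an inclusive
    (low, high) range sampled uniformly; ``p_rg_only`` is a scalar or a
    mapping chase_day -> probability that a clone contains only radial
    glia.
    """
    if len(chase_days) == 0:
        raise ValueError("chase_days must be nonempty")
    rng = np.random.default_rng(seed)
    if isinstance(clones_per_hemisphere, (int, np.integer)):
        lo = hi = int(clones_per_hemisphere)
    else:
        lo, hi = map(int, clones_per_hemisphere)
    rows = []
    clone_counter = 0
    for day in chase_days:
        p = p_rg_only[day] if isinstance(p_rg_only, dict) else float(p_rg_only)
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_rg_only must lie in [0, 1]")
        for h in range(n_hemispheres):
            n_clones = int(rng.integers(lo, hi + 1))
            for _ in range(n_clones):
                clone_counter += 1
                rg_only = rng.random() < p
                rows.append(
                    {
                        "clone_id": f"clone{clone_counter}",
                        "hemisphere_id": f"d{day}_h{h + 1}",
                        "chase_days": int(day),
                        "composition": "RG_only" if rg_only else "mixed",
                    }
                )
    return pd.DataFrame(rows)


def generate_ortholog_table(
    n_groups: int,
    frac_one2many: float = 0.0,
    frac_missing: float = 0.0,
    species: tuple[str, str] = ("zebrafish", "mouse"),
    seed: int = 0,
) -> pd.DataFrame:
    """Two-species ortholog table with teleost-style duplicate groups.

    Exactly ``round(frac_one2many * n_groups)`` groups carry two genes in
    the first (teleost) species; ``round(frac_missing * n_groups)`` further
    groups are absent from one species (alternating which).  Every gene
    maps to exactly one group.
    """
    for name, v in (("frac_one2many", frac_one2many), ("frac_missing", frac_missing)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if frac_one2many + frac_missing > 1.0:
        raise ValueError("frac_one2many + frac_missing must not exceed 1")
    rng = np.random.default_rng(seed)
    n_dup = int(round(frac_one2many * n_groups))
    n_miss = int(round(frac_missing * n_groups))
    order = rng.permutation(n_groups)
    dup_groups = set(order[:n_dup])
    miss_groups = order[n_dup : n_dup + n_miss]
    sp_a, sp_b = species
    rows = []
    for gi in range(n_groups):
        group = f"OG{gi + 1:05d}"
        in_a, in_b = True, True
        if gi in miss_groups[: len(miss_groups) // 2 + len(miss_groups) % 2]:
            in_a = False
        elif gi in miss_groups:
            in_b = False
        if in_a:
            rows.append({"species": sp_a, "gene_id": f"{sp_a[:2]}_g{gi + 1}a", "group_id": group, "provenance": "synthetic"})
            if gi in dup_groups:
                rows.append({"species": sp_a, "gene_id": f"{sp_a[:2]}_g{gi + 1}b", "group_id": group, "provenance": "synthetic"})
        if in_b:
            rows.append({"species": sp_b, "gene_id": f"{sp_b[:2]}_g{gi + 1}", "group_id": group, "provenance": "synthetic"})
    return pd.DataFrame(rows)
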