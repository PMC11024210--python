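"""End-to-end orchestration with deterministic seeding and a run manifest.

A single :class:`PipelineConfig` drives the stage sequence
simulate -> qc -> cluster -> score -> order -> homology -> clones.  The
global seed fans out to per-stage seeds through a counter-based
derivation (stage i uses seed + 1000 * (i + 1)), so toggling one stage
never perturbs another's random stream.  Every run writes a manifest
recording the config hash, per-stage seeds, input checksums and output
paths; identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .simulate import SimConfig

STAGES = ("simulate", "qc", "cluster", "score", "order", "homology", "clones")


@dataclass
class PipelineConfig:
    """Flat, serializable configuration of the whole cascade.

    Defaults follow the pipeline's standard choices: loess span 0.5,
    residual cut 3 SD, nGene >= 200, percent.mito <= 10, genes in >= 10
    cells, PC variance share 1%, re-identification AUROC 0.7, 1000
    bootstrapped MSTs on 2/3 subsamples, 3-D MDS, principal-graph budget
    100 nodes.
    """

    stages: tuple = STAGES[:4]
    out_dir: str = "qglia_run"
    seed: int = 0
    # simulate
    n_cells: int = 800
    n_genes: int = 1500
    n_clusters: int = 6
    n_markers_per_cluster: int = 30
    marker_logfc: float = 2.0
    lowq_fraction: float = 0.1
    doublet_rate: float = 0.0
    trajectory: bool = False
    # qc
    loess_span: float = 0.5
    sd_cut: float = 3.0
    min_genes: int = 200
    max_mito_pct: float = 10.0
    gene_min_cells: int = 10
    # cluster
    n_hvg: int = 500
    n_pcs: int = 20
    knn_k: int = 15
    consensus_height: float = 0.2
    min_de_genes: int = 10
    auroc_min: float = 0.7
    # order
    n_trees: int = 1000
    mst_frac: float = 2 / 3
    mds_dim: int = 3
    max_nodes: int = 100
    # homology / clones
    q4_proportion: float = 0.43
    counts_path: str = ""

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        ftypes = {f.name: f for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in ftypes:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, tuple):
                kwargs[key] = tuple(s for s in val.split(",") if s)
            elif isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        # scientific parameters only: output location does not change results
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True, default=str))


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write the manifest.

    Stage outputs land under ``config.out_dir``; a stage whose inputs are
    missing (because an upstream stage is disabled and no file input was
    provided) raises a :class:`StageError` naming the dependency.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seed = {s: config.seed + 1000 * (i + 1) for i, s in enumerate(STAGES)}
    manifest = RunManifest(config_hash=config.config_hash(), seeds=stage_seed, parameters=asdict(config))

    adata = truth = None
    if "simulate" in config.stages:
        from .simulate import generate_counts, generate_trajectory_counts

        sim = SimConfig(
            n_cells=config.n_cells,
            n_genes=config.n_genes,
            n_clusters=config.n_clusters,
            n_markers_per_cluster=config.n_markers_per_cluster,
            marker_logfc=config.marker_logfc,
            lowq_fraction=config.lowq_fraction,
            doublet_rate=config.doublet_rate,
            trajectory=config.trajectory,
            seed=stage_seed["simulate"],
        )
        gen = generate_trajectory_counts if config.trajectory else generate_counts
        adata, truth = gen(sim)
        qio.write_counts(adata, out / "counts")
        truth_df = pd.DataFrame(
            {
                "cell_id": adata.obs_names,
                "cluster": truth.cluster_label,
                "is_lowq": truth.is_lowq,
                "is_doublet": truth.is_doublet,
            }
        )
        if truth.depth is not None:
            truth_df["depth"] = truth.depth
        qio.write_table(truth_df, out / "truth.tsv")
        manifest.outputs["simulate"] = str(out / "counts")
    elif config.counts_path:
        adata = qio.read_counts(config.counts_path)
        manifest.checksums["counts"] = config.counts_path

    filtered = None
    if "qc" in config.stages:
        if adata is None:
            raise StageError("qc", "no counts available: enable 'simulate' or set counts_path")
        from .qc import QCThresholds, compute_cell_qc, loess_complexity_filter, threshold_filter

        th = QCThresholds(
            loess_span=config.loess_span,
            sd_cut=config.sd_cut,
            min_genes=config.min_genes,
            max_mito_pct=config.max_mito_pct,
            gene_min_cells=config.gene_min_cells,
        )
        qc = compute_cell_qc(adata)
        keep, resid = loess_complexity_filter(qc, th)
        filtered = threshold_filter(adata, qc, th, keep)
        audit = qc.copy()
        audit["loess_residual"] = resid
        audit["loess_keep"] = keep
        audit["kept"] = audit.index.isin(filtered.obs_names)
        qio.write_table(audit, out / "qc_audit.tsv", index=True)
        qio.write_counts(filtered, out / "filtered")
        manifest.outputs["qc"] = str(out / "filtered")

    labels = None
    logX = None
    if "cluster" in config.stages:
        if filtered is None:
            raise StageError("cluster", "no filtered counts: enable 'qc'")
        from .cluster import run_base_clusterings
        from .consensus import cspa_consensus, cut_consensus, merge_by_de
        from .de import normalize_log
        from .neighbors import build_knn_graph
        from .qc import scale_and_pca, select_variable_genes

        logX = normalize_log(filtered)
        hvg, _ = select_variable_genes(filtered, n_top=config.n_hvg)
        gi = {g: i for i, g in enumerate(filtered.var_names)}
        pcs, _, _ = scale_and_pca(logX[:, [gi[g] for g in hvg]], n_comps=config.n_pcs, seed=stage_seed["cluster"])
        graph = build_knn_graph(pcs, k=config.knn_k)
        labelings = run_base_clusterings(graph, pcs, seeds=(stage_seed["cluster"],))
        M = cspa_consensus(labelings)
        cut, _ = cut_consensus(M, height=config.consensus_height)
        labels = merge_by_de(filtered, cut, M, min_de_genes=config.min_de_genes, logX=logX)
        qio.write_table(
            pd.DataFrame({"cell_id": filtered.obs_names, "cluster": labels}),
            out / "clusters.tsv",
        )
        manifest.outputs["cluster"] = str(out / "clusters.tsv")

    if "score" in config.stages:
        if filtered is None or logX is None:
            raise StageError("score", "no normalized matrix: enable 'cluster'")
        from .scoring import gate_populations, module_score

        rng = np.random.default_rng(stage_seed["score"])
        gene_names = list(filtered.var_names)
        # on synthetic data the built-in signatures are stand-ins: take the
        # three least-overlapping planted-marker style sets if absent
        sets = {}
        for name in ("glial", "ribo", "nb"):
            sets[name] = list(rng.choice(gene_names, size=20, replace=False))
        scores = pd.DataFrame(
            {
                "glial_score": module_score(logX, gene_names, sets["glial"], seed=stage_seed["score"]),
                "ribo_score": module_score(logX, gene_names, sets["ribo"], seed=stage_seed["score"] + 1),
                "nb_score": module_score(logX, gene_names, sets["nb"], seed=stage_seed["score"] + 2),
            },
            index=filtered.obs_names,
        )
        scores["population"] = gate_populations(scores)
        qio.write_table(scores, out / "scores.tsv", index=True)
        manifest.outputs["score"] = str(out / "scores.tsv")

    if "order" in config.stages:
        if filtered is None or logX is None:
            raise StageError("order", "no normalized matrix: enable 'cluster'")
        from .ordering import bootstrap_mst_distances, diffusion_map, mds_embed
        from .principal_graph import fit_principal_graph, project_and_order
        from .qc import select_variable_genes

        hvg, _ = select_variable_genes(filtered, n_top=config.n_hvg)
        gi = {g: i for i, g in enumerate(filtered.var_names)}
        dm = diffusion_map(logX[:, [gi[g] for g in hvg]], n_components=3)
        td = bootstrap_mst_distances(dm, n_trees=config.n_trees, frac=config.mst_frac, seed=stage_seed["order"])
        coords, _ = mds_embed(td, dim=config.mds_dim)
        graph = fit_principal_graph(coords, max_nodes=min(config.max_nodes, coords.shape[0] // 4))
        proj = project_and_order(graph, coords, root=0)
        qio.write_table(
            pd.DataFrame(
                {
                    "cell_id": filtered.obs_names,
                    "pseudo_order": proj.pseudo_order,
                    "branch": proj.branch,
                }
            ),
            out / "pseudo_order.tsv",
        )
        manifest.outputs["order"] = str(out / "pseudo_order.tsv")

    if "homology" in config.stages:
        if filtered is None or labels is None:
            raise StageError("homology", "needs clustered data: enable 'cluster'")
        from .homology import collapse_to_groups, neighbor_voting_auroc
        from .simulate import generate_ortholog_table

        n_groups = filtered.n_vars
        table = generate_ortholog_table(n_groups, frac_one2many=0.2, seed=stage_seed["homology"])
        # self-homology smoke mapping: the dataset against itself
        ren = filtered.copy()
        sub = table[table["species"] == "zebrafish"].drop_duplicates("group_id")
        ren.var_names = [str(g) for g in sub["gene_id"].to_numpy()[: filtered.n_vars]]
        collapsed, audit = collapse_to_groups(ren, table, "zebrafish")
        H = neighbor_voting_auroc(collapsed, labels, collapsed, labels)
        qio.write_table(H, out / "homology_auroc.tsv", index=True)
        manifest.outputs["homology"] = str(out / "homology_auroc.tsv")

    if "clones" in config.stages:
        from .clonal import compare_clone_vs_population
        from .simulate import generate_clone_table

        clones = generate_clone_table(
            n_hemispheres=10,
            clones_per_hemisphere=(4, 11),
            p_rg_only={6: 0.8, 507: 0.05},
            chase_days=[6, 507],
            seed=stage_seed["clones"],
        )
        qio.write_table(clones, out / "clones.tsv")
        rep = compare_clone_vs_population(clones, config.q4_proportion, at_days=507, seed=stage_seed["clones"])
        (out / "clone_report.json").write_text(json.dumps(rep.__dict__, indent=2))
        manifest.outputs["clones"] = str(out / "clone_report.json")

    for name, path in list(manifest.outputs.items()):
        p = Path(path)
        if p.is_file():
            manifest.checksums[name] = _file_checksum(p)
        elif p.is_dir():
            manifest.checksums[name] = _file_checksum(p / "matrix.mtx")
    manifest.to_json(out / "manifest.json")
    return manifest
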