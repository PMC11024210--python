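#!/usr/bin/env python
"""Consensus clustering of the planted atlas.

Runs the base-clusterer ensemble on the filtered atlas, builds the CSPA
co-clustering matrix, cuts robust clusters, merges DE-indistinct
neighbours, derives marker gates and validates each cluster's
re-identification AUROC.  Writes the final labeling, the gates and the
validation table; prints K, ARI against the planted truth and the gate
summaries.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from qglia import io as qio
from qglia.cluster import run_base_clusterings
from qglia.consensus import (
    cspa_consensus,
    cut_consensus,
    find_marker_gate,
    merge_by_de,
    validate_cluster_auroc,
)
from qglia.de import normalize_log
from qglia.neighbors import build_knn_graph
from qglia.qc import scale_and_pca, select_variable_genes, threshold_filter

SEED = 0
ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    adata = qio.read_counts(ROOT / "data" / "atlas")
    truth = pd.read_csv(ROOT / "data" / "atlas_truth.tsv", sep="\t")
    filtered = threshold_filter(adata)
    keep = np.isin(adata.obs_names, filtered.obs_names)
    planted = truth["cluster"].to_numpy()[keep]

    logX = normalize_log(filtered)
    hvg, _ = select_variable_genes(filtered, n_top=500)
    gi = {g: i for i, g in enumerate(filtered.var_names)}
    pcs, _, _ = scale_and_pca(logX[:, [gi[g] for g in hvg]], n_comps=20, seed=SEED)
    graph = build_knn_graph(pcs, k=15)
    labelings = run_base_clusterings(graph, pcs, seeds=(SEED,))
    for lab in labelings:
        print(f"  {lab.method}: {lab.n_clusters} clusters, "
              f"ARI {adjusted_rand_score(planted, lab.labels):.3f}")
    M = cspa_consensus(labelings)
    cut, _ = cut_consensus(M, height=0.2)
    labels = merge_by_de(filtered, cut, M, min_de_genes=10, logX=logX)
    ari = adjusted_rand_score(planted, labels)
    print(f"consensus: K={labels.max() + 1} (planted 6), ARI {ari:.3f}")

    qio.write_table(
        pd.DataFrame({"cell_id": filtered.obs_names, "cluster": labels}),
        ROOT / "clusters.tsv",
    )
    gates = {int(c): find_marker_gate(filtered, labels, int(c), logX=logX) for c in np.unique(labels)}
    val = validate_cluster_auroc(filtered, labels, gates, logX=logX)
    qio.write_table(val, ROOT / "cluster_validation.tsv")
    gates_json = {
        str(c): {"terms": [[g, d, t] for g, d, t in gate.terms], "f1": gate.f1}
        for c, gate in gates.items()
    }
    (ROOT / "marker_gates.json").write_text(json.dumps(gates_json, indent=2))
    for c, gate in gates.items():
        row = val[val["cluster"] == c].iloc[0]
        print(f"  cluster {c}: gate {gate.terms[:2]}... F1 {gate.f1:.2f}, "
              f"AUROC {row['auroc']:.3f} ({'pass' if row['passed'] else 'fail'})")


if __name__ == "__main__":
    main()
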