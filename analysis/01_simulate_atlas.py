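#!/usr/bin/env python
"""Generate the synthetic datasets every later analysis step consumes.

Writes three fixtures under results/data/: the standard planted-cluster
atlas (1,500 cells, 6 clusters), the QC fixture with a low-quality cell
mode, and the quiescence-depth trajectory fixture, each with its planted
truth table.
"""

from pathlib import Path

import pandas as pd

from qglia import io as qio
from qglia.simulate import SimConfig, generate_counts, generate_trajectory_counts

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def truth_frame(adata, truth):
    df = pd.DataFrame({"cell_id": adata.obs_names, "cluster": truth.cluster_label,
                       "is_lowq": truth.is_lowq, "is_doublet": truth.is_doublet})
    if truth.depth is not None:
        df["depth"] = truth.depth
    return df


def main():
    atlas, truth = generate_counts(SimConfig(seed=SEED))
    qio.write_counts(atlas, OUT / "atlas")
    qio.write_table(truth_frame(atlas, truth), OUT / "atlas_truth.tsv")
    print(f"atlas: {atlas.n_obs} cells x {atlas.n_vars} genes, "
          f"{truth.cluster_label.max() + 1} planted clusters")

    qc_fix, qc_truth = generate_counts(SimConfig(n_cells=1000, lowq_fraction=0.1, seed=SEED + 1))
    qio.write_counts(qc_fix, OUT / "qc_fixture")
    qio.write_table(truth_frame(qc_fix, qc_truth), OUT / "qc_fixture_truth.tsv")
    print(f"qc fixture: {qc_fix.n_obs} cells, {qc_truth.is_lowq.sum()} planted low-quality")

    traj, traj_truth = generate_trajectory_counts(
        SimConfig(n_cells=800, n_genes=1000, trajectory=True, seed=SEED + 2)
    )
    qio.write_counts(traj, OUT / "trajectory")
    qio.write_table(truth_frame(traj, traj_truth), OUT / "trajectory_truth.tsv")
    qio.write_table(traj_truth.depth_genes, OUT / "trajectory_depth_genes.tsv")
    print(f"trajectory fixture: {traj.n_obs} cells with planted depth axis "
          f"and {len(traj_truth.depth_genes)} depth genes")


if __name__ == "__main__":
    main()
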