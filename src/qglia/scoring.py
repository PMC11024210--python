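"""Background-matched module scores, population gating, signed gene AUROC.

The module score follows the binned-control construction popularized by
Seurat/Tirosh: genes are binned by mean expression, each signature gene
draws control genes from its own bin, and a cell's score is the mean
signature expression minus the mean control expression.  The score is
therefore relative - a uniformly high housekeeping set scores ~0, and the
signature containing every gene scores exactly 0 (its controls are the
bins themselves).

Populations of the adult neurogenic cascade are gated from three such
scores: quiescent radial glia (qRG: high glial, low ribosomal, low
neuroblast), pre-activated RG (paRG: high glial, high ribosomal, low
neuroblast) and neuroblasts (NB: low glial, high ribosomal, high
neuroblast).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GLIAL_GENES",
    "NEUROBLAST_GENES",
    "ribosomal_genes",
    "module_score",
    "gate_populations",
    "gene_signed_auroc",
]

GLIAL_GENES = ["GFAP", "GLUL", "GJA1", "FABP7"]
NEUROBLAST_GENES = [
    "NEUROD1",
    "NEUROD2",
    "NEUROD4",
    "NEUROD6",
    "STMN1",
    "DPYSL3",
    "GAP43",
    "BHLHE22",
    "TUBB5",
]
RIBO_PATTERNS = ("RPS", "RPL", "rps", "rpl", "Rps", "Rpl")


def ribosomal_genes(gene_names) -> list[str]:
    """All ribosomal-protein genes by name convention (RPS*/RPL* and
    species-case variants)."""
    return [g for g in gene_names if str(g).startswith(RIBO_PATTERNS)]


def module_score(
    logX: np.ndarray,
    gene_names,
    gene_set,
    n_bins: int = 25,
    n_background: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell background-matched score of a gene set.

    Genes are cut into ``n_bins`` by average expression; each set gene
    samples ``n_background`` distinct control genes from its bin (the
    whole bin when smaller).  Score = mean(set) - mean(controls) per cell.
    """
    gene_names = np.asarray([str(g) for g in gene_names])
    present = [g for g in gene_set if g in set(gene_names)]
    missing = [g for g in gene_set if g not in set(gene_names)]
    if not present:
        raise ValueError(f"gene set has no genes in the matrix; missing: {missing}")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(gene_names)}
    mean_expr = logX.mean(axis=0)
    # equal-frequency bins on mean expression (rank-based, ties broken stably)
    ranks = rankdata(mean_expr, method="ordinal") - 1
    bins = (ranks * n_bins // len(gene_names)).astype(int)
    set_idx = np.array([idx[g] for g in present])
    set_score = logX[:, set_idx].mean(axis=1)
    control_means = np.zeros(logX.shape[0])
    for gi in set_idx:
        pool = np.where(bins == bins[gi])[0]
        if pool.size <= n_background:
            ctrl = pool
        else:
            ctrl = rng.choice(pool, size=n_background, replace=False)
        control_means += logX[:, ctrl].mean(axis=1)
    control_means /= set_idx.size
    return set_score - control_means


def gate_populations(
    scores: pd.DataFrame,
    quantile_hi: float = 0.7,
    quantile_lo: float = 0.3,
    exclude: np.ndarray | None = None,
) -> pd.Series:
    """Gate qRG / paRG / NB / other from glial, ribosomal and neuroblast
    scores using score-quantile thresholds.

    ``exclude`` marks cells left out of gating (e.g. proliferating cells
    identified by a cell-cycle signature); they are labelled "excluded".
    """
    for col in ("glial_score", "ribo_score", "nb_score"):
        if col not in scores:
            raise ValueError(f"missing score column {col}")
        if np.ptp(scores[col].to_numpy()) == 0:
            raise ValueError(f"degenerate score distribution in {col}")
    g = scores["glial_score"].to_numpy()
    r = scores["ribo_score"].to_numpy()
    b = scores["nb_score"].to_numpy()
    g_hi, g_lo = np.quantile(g, quantile_hi), np.quantile(g, quantile_lo)
    r_hi, r_lo = np.quantile(r, quantile_hi), np.quantile(r, quantile_lo)
    b_hi, b_lo = np.quantile(b, quantile_hi), np.quantile(b, quantile_lo)
    pop = np.full(len(scores), "other", dtype=object)
    pop[(g > g_hi) & (r < r_lo) & (b < b_lo)] = "qRG"
    pop[(g > g_hi) & (r > r_hi) & (b < b_lo)] = "paRG"
    pop[(g < g_lo) & (r > r_hi) & (b > b_hi)] = "NB"
    if exclude is not None:
        pop[np.asarray(exclude, dtype=bool)] = "excluded"
    return pd.Series(pop, index=scores.index, name="population")


def gene_signed_auroc(logX: np.ndarray, target_cells: np.ndarray) -> np.ndarray:
    """Signed AUROC of each gene as a one-gene classifier of the target.

    Rank-based (ties mid-ranked): AUC = P(expr_target > expr_rest) +
    0.5 P(tie); returned on the signed scale 2*AUC - 1 in [-1, 1].
    """
    target = np.asarray(target_cells, dtype=bool)
    n1 = int(target.sum())
    n2 = int((~target).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("target and complement must both be nonempty")
    ranks = rankdata(logX, axis=0)
    R1 = ranks[target].sum(axis=0)
    auc = (R1 - n1 * (n1 + 1) / 2) / (n1 * n2)
    return 2 * auc - 1
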