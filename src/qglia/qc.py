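"""Cell and gene quality control, variable-gene and PC selection.

The filtering cascade mirrors standard droplet scRNA-seq practice:

1. per-cell QC metrics (nUMI, nGene, percent.mito by "mt-" name prefix);
2. a loess fit of nGene ~ nUMI (span 0.5, gaussian family); cells whose
   residual exceeds ``sd_cut`` (default 3) standard deviations are flagged
   as complexity outliers (doublet-like or degraded libraries);
3. hard thresholds: nGene >= 200, percent.mito <= 10%, then genes kept
   only if expressed in >= 10 remaining cells (cells first, genes second);
4. variable genes by a variance-stabilizing transformation (loess of
   log10 variance vs log10 mean, standardized residual variance clipped at
   sqrt(n_cells));
5. PCs kept when they explain > 1% of the variance among the first
   ``n_max`` components and pass a JackStraw permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .loess import loess_fit

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "loess_complexity_filter",
    "threshold_filter",
    "select_variable_genes",
    "select_pcs",
    "scale_and_pca",
]

MITO_PREFIX = "mt-"


@dataclass
class QCThresholds:
    loess_span: float = 0.5
    sd_cut: float = 3.0
    min_genes: int = 200
    max_mito_pct: float = 10.0
    gene_min_cells: int = 10

    def validate(self) -> None:
        if self.loess_span <= 0 or self.sd_cut <= 0:
            raise ValueError("loess_span and sd_cut must be positive")
        if self.min_genes < 0 or self.gene_min_cells < 0 or self.max_mito_pct < 0:
            raise ValueError("thresholds must be non-negative")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def compute_cell_qc(adata: ad.AnnData, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell nUMI, nGene and percent.mito (0 for empty cells)."""
    if adata.n_vars == 0:
        raise ValueError("count matrix has no genes")
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    numi = np.asarray(X.sum(axis=1)).ravel()
    ngene = np.asarray((X > 0).sum(axis=1)).ravel()
    is_mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(adata.n_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(numi > 0, 100.0 * mito_counts / np.maximum(numi, 1), 0.0)
    return pd.DataFrame(
        {
            "nUMI": numi.astype(int),
            "nGene": ngene.astype(int),
            "percent_mito": pct,
        },
        index=adata.obs_names.rename("cell_id"),
    )


def loess_complexity_filter(
    qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flag library-complexity outliers on the nGene ~ nUMI relation.

    Returns ``(keep, residuals)``; ``keep`` is False for cells whose loess
    residual lies beyond ``sd_cut`` standard deviations (two-sided).
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if len(qc) < 10:
        raise ValueError("need at least 10 cells for the complexity filter")
    x = qc["nUMI"].to_numpy(dtype=float)
    y = qc["nGene"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("nUMI is constant; complexity filter undefined")
    fitted = loess_fit(x, y, span=thresholds.loess_span, degree=2)
    resid = y - fitted
    sd = resid.std(ddof=1)
    # exact-fit degeneracy: residuals are numerical noise, nothing to flag
    if sd <= 1e-8 * max(1.0, np.abs(y).mean()):
        return np.ones(len(qc), dtype=bool), resid
    keep = np.abs(resid) <= thresholds.sd_cut * sd
    return keep, resid


def threshold_filter(
    adata: ad.AnnData,
    qc: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
    loess_keep: np.ndarray | None = None,
) -> ad.AnnData:
    """Apply the hard QC thresholds: drop cells with nGene < min_genes or
    percent.mito > max_mito_pct (strict comparisons) or flagged by the
    loess filter; then drop genes expressed in fewer than gene_min_cells
    surviving cells."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if qc is None:
        qc = compute_cell_qc(adata)
    if len(qc) != adata.n_obs:
        raise ValueError("qc table does not match the matrix")
    keep_cells = (qc["nGene"].to_numpy() >= thresholds.min_genes) & (
        qc["percent_mito"].to_numpy() <= thresholds.max_mito_pct
    )
    if loess_keep is not None:
        keep_cells &= np.asarray(loess_keep, dtype=bool)
    if not keep_cells.any():
        raise ValueError("all cells removed by QC thresholds")
    out = adata[keep_cells].copy()
    X = out.X.tocsc() if sp.issparse(out.X) else sp.csc_matrix(out.X)
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= thresholds.gene_min_cells
    return out[:, keep_genes].copy()


def select_variable_genes(
    adata: ad.AnnData, n_top: int = 500, span: float = 0.3, clip: bool = True
) -> tuple[list[str], pd.DataFrame]:
    """Variance-stabilizing-transformation variable genes.

    Fits a loess of log10(variance) on log10(mean) over genes, standardizes
    counts with the fitted expected standard deviation, clips standardized
    values at sqrt(n_cells), and ranks genes by the variance of the clipped
    standardized counts.  Returns (top gene names, per-gene table).
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells")
    X = _dense(adata.X).astype(float)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    table = pd.DataFrame({"mean": mean, "variance": var}, index=adata.var_names.rename("gene_id"))
    ok = (mean > 0) & (var > 0)
    if ok.sum() == 0:
        table["std_variance"] = 0.0
        return [], table
    std_var = np.zeros(adata.n_vars)
    if ok.sum() >= 3 and np.ptp(np.log10(mean[ok])) > 0:
        fitted = loess_fit(np.log10(mean[ok]), np.log10(var[ok]), span=span, degree=2)
        exp_sd = np.sqrt(10**fitted)
        Z = (X[:, ok] - mean[ok]) / exp_sd
        if clip:
            Z = np.clip(Z, -np.sqrt(adata.n_obs), np.sqrt(adata.n_obs))
        std_var[ok] = Z.var(axis=0, ddof=1)
    else:
        std_var[ok] = var[ok] / np.maximum(mean[ok], 1e-12)
    table["std_variance"] = std_var
    n_top = min(n_top, int(ok.sum()))
    if n_top <= 0:
        return [], table
    order = np.argsort(-std_var, kind="stable")[:n_top]
    return [adata.var_names[i] for i in order], table


def scale_and_pca(
    logX: np.ndarray,
    n_comps: int,
    clip: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score genes (clipped), run PCA; returns (cell scores, gene
    loadings, explained variance)."""
    from sklearn.decomposition import PCA

    Z = logX - logX.mean(axis=0)
    sd = logX.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip(Z / sd, -clip, clip)
    n_comps = int(min(n_comps, min(Z.shape) - 1))
    if n_comps < 1:
        raise ValueError("matrix too small for PCA")
    pca = PCA(n_components=n_comps, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Z)
    return scores, pca.components_.T, pca.explained_variance_


def select_pcs(
    logX: np.ndarray,
    n_max: int = 100,
    var_threshold: float = 0.01,
    jackstraw_reps: int = 100,
    jackstraw_frac: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Count significant PCs: variance share among the first ``n_max``
    components above ``var_threshold`` AND a JackStraw permutation p-value
    below ``alpha``.

    JackStraw: in each replicate a small fraction of genes is permuted
    across cells, PCA re-run, and the permuted genes' loadings pooled into
    a null; a PC's p-value is a one-sided two-sample KS test that the
    observed |loadings| are stochastically larger than the null, BH
    corrected across components.  Returns (n_significant, per-PC table).
    """
    rng = np.random.default_rng(seed)
    n_cells, n_genes = logX.shape
    scores, loadings, expvar = scale_and_pca(logX, n_comps=n_max, seed=seed)
    n_comps = expvar.size
    share = expvar / expvar.sum()
    candidates = share > var_threshold
    null_loadings = [[] for _ in range(n_comps)]
    n_perm_genes = max(1, int(round(jackstraw_frac * n_genes)))
    for _ in range(jackstraw_reps):
        idx = rng.choice(n_genes, size=n_perm_genes, replace=False)
        Xp = logX.copy()
        for j in idx:
            Xp[:, j] = rng.permutation(Xp[:, j])
        _, load_p, _ = scale_and_pca(Xp, n_comps=n_comps, seed=seed)
        for c in range(n_comps):
            null_loadings[c].append(np.abs(load_p[idx, c]))
    pvals = np.ones(n_comps)
    for c in range(n_comps):
        null = np.concatenate(null_loadings[c])
        if null.size == 0:
            continue
        # observed |loadings| stochastically larger than the permutation null?
        pvals[c] = ks_2samp(np.abs(loadings[:, c]), null, alternative="less").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    significant = candidates & (qvals < alpha)
    table = pd.DataFrame(
        {
            "variance_share": share,
            "jackstraw_p": pvals,
            "jackstraw_q": qvals,
            "significant": significant,
        },
        index=pd.RangeIndex(n_comps, name="pc"),
    )
    return int(significant.sum()), table
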