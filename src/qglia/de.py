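"""The pipeline's single differential-expression test.

Wherever a stage needs DE genes (cluster merging, doublet-cluster
detection, marker listing) it uses the same nonparametric test: per-gene
Wilcoxon rank-sum on normalized log counts, Benjamini-Hochberg FDR, and a
minimum absolute log2 fold change.  Defaults: FDR 0.05, |log2FC| >= 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["normalize_log", "wilcoxon_de"]


def normalize_log(adata, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-``target_sum`` followed by log1p; returns a dense array."""
    X = adata.X if not hasattr(adata, "toarray") else adata
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * target_sum)


def _rank_sum_test(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum p-values per column of X for
    group ``mask`` vs the rest, with tie correction."""
    n = X.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    ranks = rankdata(X, axis=0)
    R1 = ranks[mask].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction per gene
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (U - mu) / sigma
    # continuity correction
    z = np.sign(z) * np.maximum(np.abs(z) - 0.5 / sigma, 0)
    return 2 * norm.sf(np.abs(z))


def wilcoxon_de(
    logX: np.ndarray,
    group_mask: np.ndarray,
    gene_names,
    fdr: float = 0.05,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Test each gene for differential expression between ``group_mask``
    cells and the rest.

    Returns a DataFrame with columns gene, log2fc, pval, qval, significant
    (BH q < fdr and |log2fc| >= min_abs_log2fc).  log2fc compares mean
    de-logged normalized expression between the groups.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() == 0 or (~group_mask).sum() == 0:
        raise ValueError("both groups must be nonempty")
    mean_in = np.expm1(logX[group_mask]).mean(axis=0)
    mean_out = np.expm1(logX[~group_mask]).mean(axis=0)
    log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
    pvals = _rank_sum_test(logX, group_mask)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    sig = (qvals < fdr) & (np.abs(log2fc) >= min_abs_log2fc)
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_names),
            "log2fc": log2fc,
            "pval": pvals,
            "qval": qvals,
            "significant": sig,
        }
    )
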