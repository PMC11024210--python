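"""Clonal-fate statistics.

Lineage-traced clones are classified as RG-only (containing only radial
glia, whether one or many cells) or mixed.  The statistics reproduce the
clone-versus-population comparison: a pooled RG-only proportion with a
hemisphere-level cluster bootstrap CI, an exact two-sided binomial test
of the clone proportion against an independently estimated population
proportion (e.g. the ~43% q4 share), and a Mann-Whitney U test with
Cliff's delta (plus percentile-bootstrap CI) for smFISH dot-count
comparisons between induced and control cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, mannwhitneyu

__all__ = [
    "rg_only_proportion",
    "binomial_two_sided",
    "mannwhitney_cliffs",
    "compare_clone_vs_population",
]


def rg_only_proportion(
    clones: pd.DataFrame,
    at_days: int | None = None,
    n_boot: int = 10000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Pooled RG-only clone proportion with a cluster-bootstrap CI.

    Bootstrap resamples hemispheres with replacement, then clones within
    each sampled hemisphere, respecting the nested design.
    """
    df = clones if at_days is None else clones[clones["chase_days"] == at_days]
    if df.empty:
        raise ValueError(f"no clones at chase_days={at_days}")
    rg = (df["composition"] == "RG_only").to_numpy()
    prop = float(rg.mean())
    rng = np.random.default_rng(seed)
    hemis = df["hemisphere_id"].unique()
    by_hemi = [rg[(df["hemisphere_id"] == h).to_numpy()] for h in hemis]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        picks = rng.integers(0, len(by_hemi), size=len(by_hemi))
        parts = []
        for p in picks:
            arr = by_hemi[p]
            parts.append(arr[rng.integers(0, arr.size, size=arr.size)])
        pooled = np.concatenate(parts)
        boots[b] = pooled.mean()
    alpha = 1 - ci
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return {
        "proportion": prop,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_clones": int(len(df)),
        "n_hemispheres": int(len(hemis)),
        "n_boot": n_boot,
    }


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by minimum-likelihood summation.

    Sums P(X = x | n, p0) over all outcomes x whose probability does not
    exceed P(k) (with the customary (1 + 1e-7) relative tolerance for
    floating-point ties), the convention of the classical exact test.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    x = np.arange(n + 1)
    pmf = binom.pmf(x, n, p0)
    p_k = pmf[k]
    p = float(pmf[pmf <= p_k * (1 + 1e-7)].sum())
    return min(p, 1.0)


def _cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    # pairwise comparison via broadcasting; fine at smFISH sample sizes
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def mannwhitney_cliffs(
    x,
    y,
    n_boot: int = 10000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Mann-Whitney U (two-sided) with Cliff's delta and a bootstrap CI.

    ``x`` is the induced group, ``y`` the control.  U uses the
    tie-corrected normal approximation except for small samples
    (n*m <= 10,000 without ties), where the exact distribution applies.
    delta = (#{x>y} - #{x<y}) / (n*m) and satisfies delta = 2U/(nm) - 1
    with ties counted half in U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 10000 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    delta = _cliffs_delta(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, size=x.size)]
        yb = y[rng.integers(0, y.size, size=y.size)]
        boots[b] = _cliffs_delta(xb, yb)
    alpha = 1 - ci
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return {
        "U": float(res.statistic),
        "pvalue": float(res.pvalue),
        "delta": delta,
        "delta_ci": (float(lo), float(hi)),
        "method": method,
    }


@dataclass
class CloneComparisonReport:
    proportion: float
    ci_low: float
    ci_high: float
    n_rg_only: int
    n_clones: int
    p0: float
    binomial_p: float


def compare_clone_vs_population(
    clones: pd.DataFrame,
    q4_proportion: float,
    at_days: int | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> CloneComparisonReport:
    """RG-only clone proportion versus an expected population share.

    Combines the bootstrapped proportion with the exact two-sided
    binomial test of #RG-only out of #clones against ``q4_proportion``.
    """
    if not (0 < q4_proportion < 1):
        raise ValueError("q4_proportion must lie in (0, 1)")
    df = clones if at_days is None else clones[clones["chase_days"] == at_days]
    if df.empty:
        raise ValueError("no clones to compare")
    boot = rg_only_proportion(df, None, n_boot=n_boot, seed=seed)
    k = int((df["composition"] == "RG_only").sum())
    n = int(len(df))
    p = binomial_two_sided(k, n, q4_proportion)
    return CloneComparisonReport(
        proportion=boot["proportion"],
        ci_low=boot["ci_low"],
        ci_high=boot["ci_high"],
        n_rg_only=k,
        n_clones=n,
        p0=q4_proportion,
        binomial_p=p,
    )
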