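"""Local polynomial (loess) regression with tricube weights.

Degree-2 local fits with a span given as the fraction of points entering
each local neighbourhood.  For large inputs the curve is evaluated on a
quantile grid of the predictor and linearly interpolated, which keeps the
fit O(grid * span * n) instead of O(n^2).
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_fit"]


def _local_fit(x0: float, x: np.ndarray, y: np.ndarray, k: int, degree: int) -> float:
    d = np.abs(x - x0)
    idx = np.argpartition(d, min(k - 1, d.size - 1))[:k]
    dmax = d[idx].max()
    if dmax == 0:
        return float(y[idx].mean())
    w = (1 - (d[idx] / dmax) ** 3) ** 3
    w = np.clip(w, 0, None)
    deg = min(degree, idx.size - 1)
    # weighted polynomial fit, centred for conditioning
    xs = x[idx] - x0
    V = np.vander(xs, deg + 1, increasing=True)
    W = w[:, None]
    beta, *_ = np.linalg.lstsq(V * W, y[idx] * w, rcond=None)
    return float(beta[0])


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
    max_grid: int = 300,
) -> np.ndarray:
    """Return fitted values of a loess regression of ``y`` on ``x``.

    Parameters
    ----------
    span
        Fraction of the data used in each local fit (0 < span <= 1).
    degree
        Degree of the local polynomial (2 matches the classical loess
        default).
    max_grid
        Above this many points the curve is evaluated on a quantile grid
        and interpolated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; loess fit is degenerate")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    if n <= max_grid:
        return np.array([_local_fit(xi, x, y, k, degree) for xi in x])
    grid = np.unique(np.quantile(x, np.linspace(0, 1, max_grid)))
    fitted_grid = np.array([_local_fit(xi, x, y, k, degree) for xi in grid])
    return np.interp(x, grid, fitted_grid)
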