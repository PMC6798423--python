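"""Storey q-values for FDR control across features.

The proportion of true nulls, pi0, is estimated from the upper tail of the
p-value distribution over a grid of cutoffs lambda and smoothed, after
which q-values follow the pi0-weighted step-up rule

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j.

With pi0 = 1 the rule reduces exactly to Benjamini-Hochberg adjusted
p-values.  Missing p-values (features that were never tested) are excluded
from m and receive missing q-values.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["DEFAULT_LAMBDA_GRID", "estimate_pi0", "qvalues", "storey_qvalues"]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

_MIN_PVALUES = 10


def estimate_pi0(pvalues, lambda_grid=None) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the
    grid, smoothed by a cubic least-squares fit (a low-df smoothing spline),
    and evaluated at the largest lambda; the result is clipped to (0, 1].
    Falls back to pi0 = 1 with a warning when fewer than 10 p-values are
    available.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < _MIN_PVALUES:
        warnings.warn("fewer than 10 p-values: falling back to pi0 = 1", stacklevel=2)
        return 1.0
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size < 4 or np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] > 0.95:
        raise ValueError("lambda grid must be increasing within [0, 0.95] with >= 4 points")
    raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    coef = np.polyfit(grid, raw, 3)
    pi0 = float(np.polyval(coef, grid[-1]))
    return float(np.clip(pi0, 1e-8, 1.0))


def qvalues(pvalues, pi0: float) -> np.ndarray:
    """Step-up q-values for a given pi0, in the input order.

    NaN entries pass through as NaN and do not count toward m.
    """
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pi0 * m * pv[order] / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    vals = np.empty(m)
    vals[order] = q
    out[mask] = vals
    return out


def storey_qvalues(pvalues, lambda_grid=None) -> np.ndarray:
    """Estimate pi0 from the p-values, then convert them to q-values."""
    return qvalues(pvalues, estimate_pi0(pvalues, lambda_grid))
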