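"""Benchmark metrics for differential-abundance method output.

Given per-feature p-values/q-values and the generating truth: the true
positive rate among the top-k ranked features, the ROC AUC of the p-value
ranking (Mann-Whitney formulation, ties counted half), realized-vs-reported
FDR at q-value thresholds, discovery counts, and the Shapiro-Wilk screen
used to stratify features into normal and non-normal subsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["tpr_at_topk", "auc", "fdr_calibration", "discoveries_at",
           "flag_nonnormal"]


def tpr_at_topk(pvalues, truth, k: int) -> float:
    """Fraction of all truly differential features found in the k smallest
    p-values.  Ties are broken by the stable feature order, so the result
    is deterministic for a fixed input ordering.
    """
    p = np.asarray(pvalues, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > p.size:
        raise ValueError("k exceeds the number of tested features")
    n_de = int(t.sum())
    if n_de == 0:
        raise ValueError("no differential features in truth")
    top = np.argsort(p, kind="stable")[:k]
    return float(t[top].sum() / n_de)


def auc(scores, truth) -> float:
    """Area under the ROC curve: P(score_DE > score_null) + P(tie)/2.

    Rank formulation over the scores (pass -p to rank by p-value); ties
    across classes contribute one half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def fdr_calibration(qvalues, truth, thresholds) -> pd.DataFrame:
    """Reported (the q-value cutoff) versus realized FDR at each threshold.

    With no discoveries at a threshold the true FDR is recorded as 0 with
    ``no_discoveries`` set, rather than NaN.
    """
    q = np.asarray(qvalues, dtype=float)
    t = np.asarray(truth, dtype=bool)
    rows = []
    for alpha in thresholds:
        if not 0 < alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        total, false = discoveries_at(q, t, alpha)
        rows.append({
            "threshold": alpha,
            "reported_fdr": alpha,
            "true_fdr": false / total if total else 0.0,
            "discoveries": total,
            "false_discoveries": false,
            "no_discoveries": total == 0,
        })
    return pd.DataFrame(rows)


def discoveries_at(qvalues, truth, alpha: float) -> tuple:
    """(total, false) discovery counts at q <= alpha; NaN q-values are
    never discoveries."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = np.asarray(qvalues, dtype=float)
    t = np.asarray(truth, dtype=bool)
    disc = np.isfinite(q) & (q <= alpha)
    return int(disc.sum()), int((disc & ~t).sum())


def flag_nonnormal(y0, y1, alpha: float = 0.01) -> bool:
    """Shapiro-Wilk screen: is either group's non-zero log abundance
    significantly non-normal?

    Groups with fewer than 3 non-zero values (or constant values) cannot be
    assessed and do not trigger the flag.
    """
    flagged = False
    for y in (y0, y1):
        y = np.asarray(y, dtype=float)
        nz = y[y > 0]
        if nz.size < 3 or np.ptp(nz) == 0:
            continue
        if stats.shapiro(np.log(nz)).pvalue < alpha:
            flagged = True
    return flagged
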