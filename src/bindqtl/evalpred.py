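"""Evaluation of variant-effect predictors with ROC/AUC and PPV curves.

Predictors (per-base conservation vs PWM allele log-odds delta) are ranked
against affected/unaffected labels from the association analysis.  The ROC
groups tied scores (deterministic trapezoidal curve); the AUC equals the
Mann-Whitney U statistic normalised by n_pos * n_neg, and both routes are
kept as mutually checking implementations.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve by descending score with tie grouping.

    Returns a DataFrame of (threshold, fpr, tpr) including the (0,0) and
    (1,1) anchors.  Raises ``ValueError`` when only one class is present.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single label class")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # group ties: advance over all records sharing a score
    uniq, first = np.unique(-s, return_index=True)
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    cut = np.append(first[1:] - 1, len(s) - 1)  # last index of each tie group
    rows = [(np.inf, 0.0, 0.0)]
    for i in cut:
        rows.append((float(s[i]), fp[i] / n_neg, tp[i] / n_pos))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def auc_trapezoid(points: pd.DataFrame) -> float:
    return float(np.trapezoid(points["tpr"].to_numpy(), points["fpr"].to_numpy()))


def auc_mannwhitney(scores, labels) -> float:
    """AUC as the normalised Mann-Whitney U (midranks handle ties)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single label class")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels):
    """(ROC points, AUC); the trapezoidal integral of the tie-grouped curve."""
    pts = roc_points(scores, labels)
    return pts, auc_trapezoid(pts)


def ppv_curve(scores, labels, cutoffs: Sequence[float]) -> pd.DataFrame:
    """Positive predictive value among SNPs scoring >= each cutoff.

    Cutoffs above the maximum score have no defined PPV and are suppressed.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    rows = []
    for c in cutoffs:
        sel = s >= c
        if sel.sum() == 0:
            continue
        rows.append((float(c), int(sel.sum()), float(y[sel].mean())))
    return pd.DataFrame(rows, columns=["cutoff", "n_called", "ppv"])


def compare_predictors(
    conservation: Sequence[float],
    allele_deltas: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Paired AUCs of the two predictors on an identical reference set,
    with a site-resampling bootstrap CI on the AUC difference."""
    cons = np.asarray(conservation, float)
    delta = np.asarray(allele_deltas, float)
    y = np.asarray(labels, bool)
    if not (len(cons) == len(delta) == len(y)):
        raise ValueError("predictors and labels must cover the same SNP set")
    if rng is None:
        rng = np.random.default_rng()
    auc_c = auc_mannwhitney(cons, y)
    auc_d = auc_mannwhitney(delta, y)
    diffs = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        if y[idx].all() or not y[idx].any():
            continue
        diffs.append(auc_mannwhitney(delta[idx], y[idx])
                     - auc_mannwhitney(cons[idx], y[idx]))
    lo, hi = (np.percentile(diffs, [2.5, 97.5]) if diffs else (np.nan, np.nan))
    return {
        "auc_conservation": auc_c,
        "auc_delta": auc_d,
        "auc_difference": auc_d - auc_c,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": n,
    }
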