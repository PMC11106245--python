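"""Shared scoring primitives: tie-aware AUROC, ROC bands, Pearson R².

The AUROC here is the Mann-Whitney pair statistic — the fraction of
(positive, negative) pairs in which the positive sample scores higher, ties
counted one half — computed through mid-ranks in O(n log n).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .exceptions import UndefinedStatisticError


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve for binary ``y_true`` (0/1) and real scores.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative, with ties counted 1/2.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUROC needs both classes present")
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve as (FPR, TPR) arrays, thresholds descending,
    anchored at (0,0) and (1,1)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]] if tps[-1] > 0 else np.r_[0.0, np.zeros(distinct.sum())]
    fpr = np.r_[0.0, fps / fps[-1]] if fps[-1] > 0 else np.r_[0.0, np.zeros(distinct.sum())]
    return fpr, tpr


@dataclasses.dataclass
class RocBand:
    """Vertically averaged ROC ensemble on a fixed FPR grid."""

    fpr: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    n_curves: int

    def auc_of_mean(self) -> float:
        """Trapezoid area under the mean ROC curve."""
        return float(np.trapezoid(self.tpr_mean, self.fpr))


def roc_band(curves: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101) -> RocBand:
    """Vertical averaging of ROC curves at ``n_grid`` evenly spaced FPR
    points: the band center is the mean TPR, the band half-width one
    standard deviation across curves."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.empty((len(curves), n_grid))
    for i, (fpr, tpr) in enumerate(curves):
        tprs[i] = np.interp(grid, fpr, tpr)
    return RocBand(
        fpr=grid,
        tpr_mean=tprs.mean(axis=0),
        tpr_sd=tprs.std(axis=0),
        n_curves=len(curves),
    )


def pearson_r2(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Square of Pearson's correlation between actual and predicted values."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.std() == 0 or p.std() == 0:
        raise UndefinedStatisticError("Pearson R^2 undefined for constant input")
    r = np.corrcoef(a, p)[0, 1]
    return float(r * r)
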