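"""Evaluation metrics for continual classification of time series.

Covers discrimination (AUC-ROC with a Hanley-McNeil confidence interval),
continual-learning transfer (backward/forward transfer over the task-by-task
score matrix), optimisation stability (gradient-sign fluctuation), multiple
comparison of methods (average ranks and the Bonferroni-Dunn critical
difference) and the cross-entropy objective.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AccuracyMatrix",
    "auc_roc",
    "auc_confidence_interval",
    "bwt",
    "fwt",
    "gradient_fluctuation",
    "bonferroni_dunn_cd",
    "average_ranks",
    "cross_entropy",
    "accuracy",
]


@dataclasses.dataclass
class AccuracyMatrix:
    """R[i, j] = score on distribution j after finishing task i, plus the
    random-initialisation reference score b_bar[j] per distribution."""

    R: np.ndarray
    b_bar: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        self.b_bar = np.asarray(self.b_bar, float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if self.b_bar.shape != (self.R.shape[0],):
            raise ValueError("b_bar length must match R")


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation:
    the fraction of (positive, negative) pairs where the positive is scored
    higher, ties counting one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Plain 0/1 accuracy of thresholded scores (alternative R entry)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    return float(np.mean((scores >= threshold).astype(int) == labels))


def auc_confidence_interval(auc: float, s1: int, s2: int,
                            alpha: float = 0.05):
    """Hanley-McNeil normal-approximation interval for an AUC estimated from
    s1 negatives-vs-s2 positives (group sizes of the two label classes)::

        q0 = A(1-A);  q1 = A/(2-A) - A^2;  q2 = 2A^2/(1+A) - A^2
        se = sqrt((q0 + (s1-1) q1 + (s2-1) q2) / (s1 s2))

    Returns (lo, hi) = auc -+ z_{1-alpha/2} * se.
    """
    if s1 < 2 or s2 < 2:
        raise ValueError("both group sizes must be >= 2")
    if auc <= 0.0 or auc >= 1.0:
        warnings.warn("degenerate AUC; returning a zero-width interval")
        return float(auc), float(auc)
    q0 = auc * (1.0 - auc)
    q1 = auc / (2.0 - auc) - auc ** 2
    q2 = 2.0 * auc ** 2 / (1.0 + auc) - auc ** 2
    se = np.sqrt((q0 + (s1 - 1) * q1 + (s2 - 1) * q2) / (s1 * s2))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(auc - se * z), float(auc + se * z)


def bwt(matrix) -> float:
    """Backward transfer: mean over earlier distributions i of
    R[last, i] - R[i, i].  Negative values quantify forgetting."""
    R = matrix.R if isinstance(matrix, AccuracyMatrix) else np.asarray(matrix, float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two distributions")
    return float(np.mean([R[n - 1, i] - R[i, i] for i in range(n - 1)]))


def fwt(matrix: AccuracyMatrix) -> float:
    """Forward transfer: mean over later distributions i of
    R[i-1, i] - b_bar[i] (benefit on a not-yet-learned distribution relative
    to the random-initialisation reference)."""
    R, b = matrix.R, matrix.b_bar
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two distributions")
    vals = [R[i - 1, i] - b[i] for i in range(1, n)]
    if np.any(~np.isfinite(vals)):
        raise ValueError("missing superdiagonal entries")
    return float(np.mean(vals))


def gradient_fluctuation(grad_series) -> float:
    """Frequency of gradient direction changes during training.

    For each parameter, the sign series d_i in {-1, +1} (zeros inherit the
    previous sign; a leading zero counts +1) gives
    R = (1/(n-1)) sum_i (d_i - d_{i-1})^2; the mean over parameters is
    returned.  R is 0 for a constant-sign series and 4 for a strictly
    alternating one.
    """
    g = np.asarray(grad_series, float)
    if g.ndim == 1:
        g = g[:, None]
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least two rounds")
    d = np.sign(g)
    d[0] = np.where(d[0] == 0, 1.0, d[0])
    for i in range(1, n):
        d[i] = np.where(d[i] == 0, d[i - 1], d[i])
    per_param = ((np.diff(d, axis=0) ** 2).sum(axis=0)) / (n - 1)
    return float(per_param.mean())


def bonferroni_dunn_cd(k: int, N: int, q: float) -> float:
    """Critical difference of the Bonferroni-Dunn post-hoc test:
    CD = q * sqrt(k(k+1) / (6N)) for k methods over N comparisons."""
    if k < 2 or N < 1 or q < 0:
        raise ValueError("need k >= 2, N >= 1, q >= 0")
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))


def average_ranks(table, cd: Optional[float] = None):
    """Average rank per method over a (comparisons x methods) score table,
    higher scores ranking better (rank 1 = best), ties by midrank.

    With ``cd`` given, also returns the boolean vector "significantly worse
    than the best-ranked method" under the strict rule
    rank_method - rank_best > cd.
    """
    tab = np.asarray(table, float)
    if tab.ndim != 2:
        raise ValueError("table must be 2-d")
    if np.any(~np.isfinite(tab)):
        raise ValueError("missing cells in the score table")
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in tab])
    r_bar = ranks.mean(axis=0)
    if cd is None:
        return r_bar
    best = r_bar.min()
    return r_bar, (r_bar - best) > cd


def cross_entropy(probabilities, labels) -> float:
    """Mean negative log-probability of the true class; rows must sum to 1
    within 1e-6.  True-class probabilities of 0 are clamped at 1e-12."""
    P = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = P[np.arange(P.shape[0]), y]
    if np.any(p_true <= 0):
        warnings.warn("zero probability at a true label; clamping at 1e-12")
    return float(-np.mean(np.log(np.clip(p_true, 1e-12, None))))
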