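"""Correlation, ROC and threshold analysis for solubility predictions.

The evaluation design mirrors the way the model is trained: the lowest and
highest tails of the measured quantity (solubility, or log-scale abundance)
form the two classes, the middle of the distribution is excluded, and a ROC
sweep over the predicted values yields the AUC and the accuracy attainable
at each candidate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import roc_curve as _sk_roc_curve


def pearson(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Pearson correlation coefficient between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if len(pred) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        raise ValueError("zero variance input")
    return float(_scipy_stats.pearsonr(pred, obs)[0])


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep over prediction values for a binary tail contrast."""

    thresholds: np.ndarray  # descending sweep over unique prediction values
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    accuracy_at: Mapping[float, float]  # threshold -> (TP+TN)/(P+N)


def _accuracy(pred: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    return float(np.mean((pred >= threshold) == labels))


def roc(pred: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis of predictions against binary labels.

    The sweep visits every unique prediction value; AUC is the trapezoid
    area, which equals the Mann-Whitney rank statistic with ties counted
    one half.  ``accuracy_at`` records, for each swept threshold, the
    fraction of inputs classified correctly by ``pred >= threshold``.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, pred, drop_intermediate=False)
    # drop sklearn's synthetic +inf starting threshold; sweep real values only
    thresholds = np.unique(pred)[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    accuracy_at = {float(t): _accuracy(pred, labels, float(t)) for t in thresholds}
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     accuracy_at=accuracy_at)


def tails_to_labels(
    values: Sequence[float], tail_fraction: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Label the low/high tails of a value distribution as classes 0/1.

    Returns ``(indices, labels)``: the indices (into the input) of the tail
    members in low-then-high order, and their 0/1 labels.  Tail size is
    ``ceil(tail_fraction * n)``; ties at a tail boundary are broken by
    stable input order; the middle of the distribution is excluded.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if np.ptp(values) == 0.0:
        raise ValueError("all values equal; tails are undefined")
    k = ceil(tail_fraction * n)
    if k < 2:
        raise ValueError(f"tail of {k} record(s) is too small; need >= 2 per tail")
    order = np.argsort(values, kind="stable")
    idx = np.concatenate([order[:k], order[n - k:]])
    labels = np.concatenate([np.zeros(k, dtype=int), np.ones(k, dtype=int)])
    return idx, labels


def best_threshold(result: ROCResult) -> float:
    """The swept threshold with maximal accuracy (ties: lowest threshold)."""
    best_t, best_a = None, -1.0
    for t in sorted(result.accuracy_at):  # ascending: first max is the lowest
        a = result.accuracy_at[t]
        if a > best_a:
            best_t, best_a = t, a
    return float(best_t)
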