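"""Evaluation metrics for ordinal staging: confusion matrices, balanced
accuracy, ROC/AUC, Spearman correlation, and the two-sample
Kolmogorov-Smirnov test.

Balanced accuracy (mean of sensitivity and specificity) is the headline
number because the cohorts are imbalanced.  The ROC sweep uses the
half-credit convention for tied scores, so its AUC equals the Mann-Whitney
concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion",
    "balanced_accuracy",
    "sensitivity_specificity",
    "roc_auc",
    "ks_two_sample",
    "spearman",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true classes, columns = predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self, title: str = "") -> str:
        names = self.class_names
        width = max(8, max(len(n) for n in names) + 2)
        lines = []
        if title:
            lines.append(title)
        lines.append(" " * width + "".join(f"{n:>{width}}" for n in names))
        for i, n in enumerate(names):
            row = "".join(f"{int(c):>{width}}" for c in self.counts[i])
            lines.append(f"{n:>{width}}" + row)
        return "\n".join(lines)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def confusion(
    truth: np.ndarray, predicted: np.ndarray, class_names: list
) -> ConfusionMatrix:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    index = {c: i for i, c in enumerate(class_names)}
    for arr, what in ((truth, "truth"), (predicted, "predicted")):
        unknown = set(arr.tolist()) - set(class_names)
        if unknown:
            raise ValueError(f"unknown {what} labels: {sorted(map(str, unknown))}")
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, [str(c) for c in class_names])


def sensitivity_specificity(
    truth: np.ndarray, calls: np.ndarray, positive
) -> tuple[float, float]:
    truth = np.asarray(truth)
    calls = np.asarray(calls)
    pos = truth == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in truth")
    sens = float(np.mean(calls[pos] == positive))
    spec = float(np.mean(calls[~pos] != positive))
    return sens, spec


def balanced_accuracy(truth: np.ndarray, calls: np.ndarray, positive=None) -> float:
    """(sensitivity + specificity) / 2 for a binary contrast.

    ``positive`` defaults to the larger of the two labels present in truth
    (for {CTL-like, AD-like} strings that is AD-like only by explicit
    argument; pass it when labels are not ordered as desired — the value is
    symmetric under swapping the positive class anyway).
    """
    truth = np.asarray(truth)
    labels = np.unique(truth)
    if len(labels) != 2:
        raise ValueError("balanced accuracy needs exactly two classes in truth")
    if positive is None:
        positive = labels[-1]
    sens, spec = sensitivity_specificity(truth, calls, positive)
    return 0.5 * (sens + spec)


def roc_auc(scores: np.ndarray, truth: np.ndarray, positive=None) -> RocCurve:
    """ROC curve over all distinct score thresholds plus AUC.

    AUC equals the Mann-Whitney concordance probability with half credit
    for ties: P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    labels = np.unique(truth)
    if len(labels) != 2:
        raise ValueError("ROC needs exactly two classes in truth")
    if positive is None:
        positive = labels[-1]
    pos = truth == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    order = np.argsort(-scores, kind="mergesort")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # collapse tied scores: keep the last index of each tie block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores) != 0), len(scores) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a - ECDF_b|, asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
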