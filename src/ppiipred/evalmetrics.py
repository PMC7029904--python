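"""Confusion-matrix metrics, ROC/AUC, and TP-versus-log10(FP) curves.

Note on naming: the "Spec" column of the reference performance tables is
numerically tp/(tp+fp), i.e. precision, not the textbook specificity
tn/(tn+fp).  It is exposed here as ``spec_as_precision``; textbook
specificity is provided alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sens: Optional[float]
    spec_as_precision: Optional[float]
    specificity: Optional[float]
    mcc: Optional[float]
    acc_percent: Optional[float]

    def rounded(self) -> "MetricSet":
        """Two-decimal rounding matching the printed report format."""
        r = lambda x: None if x is None else round(x, 2)
        return MetricSet(r(self.sens), r(self.spec_as_precision),
                         r(self.specificity), r(self.mcc), r(self.acc_percent))


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally TP/FP/TN/FN calling positive at score >= threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    calls = s >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Sens, precision (the tables' "Spec"), specificity, MCC, accuracy %.

    A metric with a zero denominator is reported as None, not 0.
    """
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = ((c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)) if denom else None
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total else None
    return MetricSet(sens=sens, spec_as_precision=prec, specificity=spec,
                     mcc=mcc, acc_percent=acc)


def positive_fraction_percent(n_positive: int, n_negative: int,
                              ndigits: int = 1) -> float:
    """Percentage of positive residues in a dataset, rounded."""
    if n_positive < 0 or n_negative < 0 or n_positive + n_negative == 0:
        raise ValueError("counts must be non-negative and not both zero")
    return round(100.0 * n_positive / (n_positive + n_negative), ndigits)


def roc_curve(scores, labels):
    """(fpr, tpr) points over unique-score thresholds plus trapezoidal AUC.

    Returns ``(points, auc)`` with points a list of (fpr, tpr) tuples.
    """
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise ValueError("roc_curve needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def auc_score(scores, labels) -> float:
    return roc_curve(scores, labels)[1]


#: Sentinel reported for log10(FP) when FP = 0 at a threshold.
LOG10_FP_SENTINEL = -np.inf


def tp_vs_log10fp(scores, labels):
    """Per-threshold (log10(fp), tp) pairs, thresholds descending.

    Thresholds sweep the unique score values; fp = 0 is reported with
    ``LOG10_FP_SENTINEL`` rather than dropped.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    # last index of each tie-group of equal scores
    distinct = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    points = []
    for idx in distinct:
        tp = int(tp_cum[idx])
        fp = int(fp_cum[idx])
        lfp = math.log10(fp) if fp > 0 else LOG10_FP_SENTINEL
        points.append((lfp, tp))
    return points


def write_roc_tsv(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
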