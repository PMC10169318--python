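"""Binary-classification evaluation suite.

Counts follow the standard four-way taxonomy — Positive means the
electron-dense granule is present:

* TP: true Positive predicted Positive;  FN: true Positive predicted Negative;
* FP: true Negative predicted Positive;  TN: true Negative predicted Negative.

Derived metrics:  recall = TP/(TP+FN),  precision = TP/(TP+FP),
F1 = 2*P*R/(P+R),  accuracy = (TP+TN)/total,  FPR = FP/(FP+TN),
TPR = TP/(TP+FN).  The ROC curve sweeps every distinct score threshold
(prediction Positive when score >= threshold, so tied scores share one
point), runs from (0,0) to (1,1), and AUROC is its trapezoidal area.

Zero-denominator metrics raise ``UndefinedMetricError`` rather than silently
returning 0, to flag degenerate evaluation sets.  Reported tables round to
2 decimal places; raw values are always available alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionMatrix", "ROCCurve", "confusion_matrix", "recall", "precision",
    "f1", "accuracy", "roc_curve", "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn}


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1) and the area under them."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auroc: float


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    t = np.asarray(y_true).astype(int).ravel()
    p = np.asarray(y_pred).astype(int).ravel()
    if t.shape != p.shape or t.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, nonempty")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): how many true Positives the model finds."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("recall undefined: no Positive samples")
    return cm.tp / (cm.tp + cm.fn)


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP): how many predicted Positives are correct."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("precision undefined: no Positive predictions")
    return cm.tp / (cm.tp + cm.fp)


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    return 2.0 * p * r / (p + r)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def roc_curve(y_true, scores) -> ROCCurve:
    """Threshold sweep per the FPR/TPR definitions, trapezoidal AUROC."""
    t = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if t.shape != s.shape or t.size == 0:
        raise ValidationError("y_true and scores must be equal-length, nonempty")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores contain non-finite values")
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: need both classes in y_true")
    pts = [(0.0, 0.0)]
    for thr in np.unique(s)[::-1]:          # descending distinct thresholds
        pred = s >= thr
        tp = int(np.sum(pred & (t == 1)))
        fp = int(np.sum(pred & (t == 0)))
        pts.append((fp / n_neg, tp / n_pos))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=tuple(fpr.tolist()), tpr=tuple(tpr.tolist()),
                    auroc=auroc)


def metrics_report(cm: ConfusionMatrix, ndigits: int = 2) -> dict:
    """Raw and table-rounded metric values for one model."""
    p = precision(cm)
    r = recall(cm)
    return {
        "confusion_matrix": cm.as_dict(),
        "raw": {"precision": p, "recall": r, "f1": f1(p, r),
                "accuracy": accuracy(cm)},
        "rounded": {"precision": round(p, ndigits), "recall": round(r, ndigits),
                    "f1": round(f1(p, r), ndigits),
                    "accuracy": round(accuracy(cm), ndigits)},
    }
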