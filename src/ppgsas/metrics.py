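"""Confusion-matrix metrics for the binary SAS / healthy decision.

Positive class is SAS (label 1).  The four indicators:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PRE = TP / (TP + FP)
    SE  = TP / (TP + FN)        (sensitivity, recall of SAS)
    SP  = TN / (TN + FP)        (specificity, recall of healthy)

A zero denominator yields ``None`` (rendered "NA"), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float | None
    pre: float | None
    se: float | None
    sp: float | None
    condition: str = ""
    n_segments: int = 0

    def as_row(self) -> dict:
        fmt = lambda v: "NA" if v is None else f"{v:.4f}"
        return {"condition": self.condition, "n": self.n_segments,
                "ACC": fmt(self.acc), "PRE": fmt(self.pre),
                "SE": fmt(self.se), "SP": fmt(self.sp)}


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with positive = 1 (SAS)."""
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if y.shape != yhat.shape:
        raise ValueError("label arrays must have equal lengths")
    if not (np.isin(y, (0, 1)).all() and np.isin(yhat, (0, 1)).all()):
        raise ValueError("labels must be 0 (healthy) or 1 (SAS)")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix, condition: str = "") -> MetricsReport:
    """ACC / PRE / SE / SP from a confusion matrix; NA on zero denominators."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return MetricsReport(
        acc=_ratio(cm.tp + cm.tn, cm.total),
        pre=_ratio(cm.tp, cm.tp + cm.fp),
        se=_ratio(cm.tp, cm.tp + cm.fn),
        sp=_ratio(cm.tn, cm.tn + cm.fp),
        condition=condition,
        n_segments=cm.total,
    )
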