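"""Confusion counts and the four performance metrics.

Positive class = TNBC. With TP/TN/FP/FN the usual 2x2 tallies:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Zero-denominator convention: precision, recall and F1 are defined as 0 when
their denominators vanish (a degenerate model predicting a single class
scores 0, not NaN). On this imbalanced problem F1 is the headline metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "confusion_counts", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    for name, v in (("true", t), ("predicted", p)):
        if not set(np.unique(v).tolist()) <= {0, 1}:
            raise ValueError(f"{name} labels must be binary 0/1")
    t = t.astype(bool)
    p = p.astype(bool)
    return ConfusionCounts(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero samples")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)
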