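"""Binary-classification performance metrics for binder/non-binder calls.

The five metrics reported throughout the toolkit, computed from the
confusion counts of predicted versus assayed activity:

    accuracy            = (TP + TN) / (TP + TN + FP + FN)
    sensitivity         = TP / (TP + FN)
    specificity         = TN / (TN + FP)
    MCC                 = (TP*TN - FP*FN) /
                          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    balanced accuracy   = (TP(TN+FP) + TN(TP+FN)) / (2 (TP+FN)(TN+FP))
                        = (sensitivity + specificity) / 2

TP counts binders predicted as binders, TN non-binders predicted as
non-binders, FN binders predicted as non-binders, FP non-binders
predicted as binders.

Degenerate denominators: MCC is 0 by convention when any factor under the
square root vanishes; sensitivity / specificity / balanced accuracy are
undefined (None) when the relevant class is absent rather than silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc", "balanced_accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_actual_binders(self) -> int:
        return self.tp + self.fn

    @property
    def n_actual_nonbinders(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    mcc: float
    balanced_accuracy: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
        }

    def rounded(self, ndigits: int = 3) -> dict:
        """Report-style rounding (3 decimals by default); internal values
        stay at full precision."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def confusion(actual: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN from aligned actual and predicted 0/1 calls."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError(
            f"actual and predicted must be 1-D and equal length "
            f"({a.shape} vs {p.shape})"
        )
    for name, arr in (("actual", a), ("predicted", p)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} contains values outside {{0,1}}: {sorted(bad)}")
    tp = int(np.sum((a == 1) & (p == 1)))
    tn = int(np.sum((a == 0) & (p == 0)))
    fp = int(np.sum((a == 0) & (p == 1)))
    fn = int(np.sum((a == 1) & (p == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """All five metrics from a confusion table."""
    if c.total < 1:
        raise ValueError("cannot compute metrics on zero predictions")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn

    accuracy = (tp + tn) / c.total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)

    if (tp + fn) > 0 and (tn + fp) > 0:
        balanced = (tp * (tn + fp) + tn * (tp + fn)) / (2 * (tp + fn) * (tn + fp))
    else:
        balanced = None
    return MetricReport(accuracy, sensitivity, specificity, mcc, balanced)
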