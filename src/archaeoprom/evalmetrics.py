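"""Confusion-matrix bookkeeping and binary classification metrics.

Accuracy = (TP+TN)/(TP+TN+FP+FN), Precision = TP/(TP+FP),
Recall = TP/(TP+FN), Specificity = TN/(TN+FP).  A metric whose
denominator is zero is undefined and returned as NaN with a warning —
never silently as 0.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

#: Sentinel for a metric whose denominator is zero.
UNDEFINED = math.nan


@dataclass
class ConfusionMatrix:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


def confusion(predicted, actual, *, positive=1) -> ConfusionMatrix:
    """Build the error matrix from predicted and actual label vectors."""
    predicted, actual = list(predicted), list(actual)
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(actual)} actual labels"
        )
    cm = ConfusionMatrix()
    for p, a in zip(predicted, actual):
        if a == positive:
            if p == positive:
                cm.TP += 1
            else:
                cm.FN += 1
        else:
            if p == positive:
                cm.FP += 1
            else:
                cm.TN += 1
    return cm


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return UNDEFINED
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TP + cm.TN, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TP, cm.TP + cm.FP, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TP, cm.TP + cm.FN, "recall")


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.TN, cm.TN + cm.FP, "specificity")


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of recall and specificity; equals accuracy on balanced sets."""
    r, s = recall(cm), specificity(cm)
    return (r + s) / 2


def metric_report(cm: ConfusionMatrix) -> dict[str, float]:
    """All four metrics as proportions in [0, 1] (NaN when undefined)."""
    return {
        "accuracy": accuracy(cm),
        "precision": precision(cm),
        "recall": recall(cm),
        "specificity": specificity(cm),
    }


def format_percent(value: float) -> str:
    """Presentation-layer percent formatting, two decimals (e.g. '92.48')."""
    if math.isnan(value):
        return "NA"
    return f"{100 * value:.2f}"
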