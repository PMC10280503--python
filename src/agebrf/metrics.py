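"""Confusion-matrix metrics and segmentation overlap scores.

Two metric modes are supported.  ``standard`` computes the textbook
definitions (sensitivity = tp/(tp+fn), specificity = tn/(tn+fp)).
``paper_fidelity`` reproduces, for auditability, a published variant in
which both sensitivity and specificity are normalized by (tp+tn) instead;
this is *not* the standard definition and is reported only with an explicit
mode tag.  Accuracy, precision and F1 are identical in both modes.
Malignant is the positive class for label metrics; lesion is the positive
class for pixel metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Mode = Literal["standard", "paper_fidelity"]
MODES = ("standard", "paper_fidelity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mode: str

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mode": self.mode,
        }


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown metric mode {mode!r}")


def confusion_from_labels(predicted: Sequence, truth: Sequence,
                          positive="malignant") -> ConfusionCounts:
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth label sequences differ in length")
    p = pred == positive
    t = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)),
    )


def confusion_from_masks(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)), tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)), fn=int(np.sum(~pred & true)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts, mode: Mode = "standard") -> float:
    _check_mode(mode)
    denom = c.tp + c.fn if mode == "standard" else c.tp + c.tn
    if denom == 0:
        raise ValueError(f"sensitivity denominator is zero in {mode} mode")
    return c.tp / denom


def specificity(c: ConfusionCounts, mode: Mode = "standard") -> float:
    _check_mode(mode)
    denom = c.tn + c.fp if mode == "standard" else c.tp + c.tn
    if denom == 0:
        raise ValueError(f"specificity denominator is zero in {mode} mode")
    return c.tn / denom


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise ValueError("precision denominator is zero")
    return c.tp / (c.tp + c.fp)


def f1_score(precision_value: float, sensitivity_value: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if precision_value + sensitivity_value <= 0:
        raise ValueError("precision + sensitivity must be > 0")
    return 2.0 * precision_value * sensitivity_value / (
        precision_value + sensitivity_value
    )


def report(c: ConfusionCounts, mode: Mode = "standard") -> MetricReport:
    _check_mode(mode)
    p = precision(c)
    s = sensitivity(c, mode)
    return MetricReport(
        accuracy=accuracy(c),
        sensitivity=s,
        specificity=specificity(c, mode),
        precision=p,
        f1=f1_score(p, s),
        mode=mode,
    )


def balanced_accuracy(predicted: Sequence, truth: Sequence,
                      positive="malignant") -> float:
    """Mean of the two standard-mode class recalls."""
    c = confusion_from_labels(predicted, truth, positive=positive)
    return 0.5 * (sensitivity(c, "standard") + specificity(c, "standard"))


def dice(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap; defined as 1 when both masks are empty."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    total = int(pred.sum()) + int(true.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.sum(pred & true)) / total


def iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; defined as 1 when both masks are empty."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    union = int(np.sum(pred | true))
    if union == 0:
        return 1.0
    return int(np.sum(pred & true)) / union
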