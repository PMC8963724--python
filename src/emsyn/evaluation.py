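"""Contact-wise accuracy metrics with ambiguous exclusion.

Detection accuracy is measured per contact against expert labels. Contacts
voted AMBIGUOUS are excluded entirely: whatever the detector predicts for
them counts as neither true positive, false positive, nor false negative.
Precision = TP/(TP+FP), recall = TP/(TP+FN), and the F-beta score

    F_beta = (1 + beta^2) * precision * recall / (beta^2 * precision + recall)

weights recall more heavily for beta > 1. Precision-recall curves over a
controllable pipeline parameter drive threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .core import GroundTruth

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "UndefinedMetricError",
    "confusion_counts",
    "precision_recall",
    "f_beta",
    "pr_curve",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero (no silent zeros)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRCurve:
    """Precision/recall along a parameter grid, sorted by parameter value."""

    parameter: str
    points: list[tuple[float, float, float]]  # (param, precision, recall)


def confusion_counts(
    predicted: Iterable[int], truth: Mapping[int, GroundTruth]
) -> ConfusionCounts:
    """Count TP/FP/FN of a predicted contact-ID set against expert labels.

    Every predicted ID must carry a truth label. AMBIGUOUS contacts
    contribute to no count regardless of the prediction.
    """
    pred = set(predicted)
    unlabeled = pred - set(truth)
    if unlabeled:
        raise KeyError(f"predicted contacts without a truth label: {sorted(unlabeled)[:5]}")
    synaptic = {cid for cid, lbl in truth.items() if lbl == GroundTruth.SYNAPTIC}
    non_synaptic = {cid for cid, lbl in truth.items() if lbl == GroundTruth.NON_SYNAPTIC}
    return ConfusionCounts(
        tp=len(pred & synaptic),
        fp=len(pred & non_synaptic),
        fn=len(synaptic - pred),
    )


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """Precision and recall; zero denominators raise, never silently zero.

    tp = 0 with nonzero denominators is a defined (0, 0) result.
    """
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive ground truth")
    return (
        counts.tp / (counts.tp + counts.fp),
        counts.tp / (counts.tp + counts.fn),
    )


def f_beta(counts: ConfusionCounts, beta: float = 1.0) -> float:
    """F-beta score; the precision = recall = 0 corner is 0 by continuity."""
    p, r = precision_recall(counts)
    if p == 0.0 and r == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * p * r / (b2 * p + r)


def pr_curve(
    detector: Callable[[float], Iterable[int]],
    grid: Iterable[float],
    truth: Mapping[int, GroundTruth],
    beta: float = 1.0,
    stricter: str = "higher",
) -> tuple[PRCurve, float]:
    """Precision-recall curve over a parameter grid and the best parameter.

    ``detector(value)`` re-runs the (deterministic) pipeline at one parameter
    value and returns the predicted contact IDs. The best parameter is the
    argmax of the F-beta score; exact ties go to the stricter parameter
    (``stricter`` says whether higher or lower values are stricter).
    Grid order does not matter — the curve is sorted by parameter value.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    if stricter not in ("higher", "lower"):
        raise ValueError("stricter must be 'higher' or 'lower'")
    points = []
    best_score = -1.0
    best_param = grid[0]
    for value in grid:
        counts = confusion_counts(detector(value), truth)
        p, r = precision_recall(counts)
        points.append((value, p, r))
        score = f_beta(counts, beta)
        tie_wins = score == best_score and (
            value > best_param if stricter == "higher" else value < best_param
        )
        if score > best_score or tie_wins:
            best_score, best_param = score, value
    return PRCurve(parameter="", points=points), best_param
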