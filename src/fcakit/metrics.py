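"""Confusion-matrix evaluation (accuracy, sensitivity, specificity, F1).

All rates are reported as percentages, matching how benchmark tables in
histopathology classification are printed.  "Positive" means the
designated positive class — malignant (label ``"1"``) by default.  A rate
whose denominator is zero is reported as ``None`` (printed as
``undefined``), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "evaluate",
    "evaluate_counts",
    "evaluate_multiclass",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    y_true: Sequence[Hashable], y_pred: Sequence[Hashable], positive: Hashable
) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def evaluate_counts(counts: ConfusionCounts) -> dict:
    """Metrics from raw confusion counts, as percentages."""
    return {
        "accuracy": _pct(counts.tp + counts.tn, counts.total),
        "sensitivity": _pct(counts.tp, counts.tp + counts.fn),
        "specificity": _pct(counts.tn, counts.tn + counts.fp),
        "f1": _pct(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        "counts": counts,
    }


def evaluate(
    y_true: Sequence[Hashable],
    y_pred: Sequence[Hashable],
    positive: Hashable = "1",
) -> dict:
    """Binary evaluation with ``positive`` as the positive class.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), F1 = 2·TP/(2·TP+FP+FN); every label other
    than ``positive`` counts as negative.
    """
    return evaluate_counts(confusion_counts(y_true, y_pred, positive))


def evaluate_multiclass(
    y_true: Sequence[Hashable], y_pred: Sequence[Hashable]
) -> dict:
    """Overall accuracy plus one-vs-rest metrics per class."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    labels = sorted(set(y_true) | set(y_pred), key=str)
    correct = sum(t == p for t, p in zip(y_true, y_pred))
    return {
        "accuracy": _pct(correct, len(y_true)),
        "per_class": {lbl: evaluate(y_true, y_pred, positive=lbl) for lbl in labels},
    }


def _fmt(v: float | None) -> str:
    return "undefined" if v is None else f"{v:.2f}"


def format_report(result: dict, title: str = "") -> str:
    """Plain-text table in the conventional benchmark column order."""
    header = f"{'':<16}Accuracy %  Sensitivity %  Specificity %  F1 Score %"
    row = (
        f"{title:<16}{_fmt(result['accuracy']):>10}  "
        f"{_fmt(result['sensitivity']):>13}  "
        f"{_fmt(result['specificity']):>13}  "
        f"{_fmt(result['f1']):>10}"
    )
    return header + "\n" + row + "\n"
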