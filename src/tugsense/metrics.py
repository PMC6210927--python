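"""Classification metrics: per-class confusion counts and derived scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "f1_from_precision_recall",
    "per_class_counts",
]


def _ratio(num: float, den: float) -> float:
    """0/0 ratios are defined as 0 so degenerate classes stay reportable."""
    return num / den if den > 0 else 0.0


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _ratio(2.0 * precision * recall, precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    """One class's confusion counts with precision/recall/F1/accuracy."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    """Derive precision, recall, F1 and accuracy from confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = f1_from_precision_recall(precision, recall)
    accuracy = _ratio(tp + tn, tp + tn + fp + fn)
    return MetricsReport(tp, fp, fn, tn, precision, recall, f1, accuracy)


def per_class_counts(y_true, y_pred, classes=None) -> dict[str, dict[str, int]]:
    """One-vs-rest confusion counts per class label."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    out = {}
    for c in classes:
        t = y_true == c
        p = y_pred == c
        out[c] = {
            "tp": int(np.sum(t & p)),
            "fp": int(np.sum(~t & p)),
            "fn": int(np.sum(t & ~p)),
            "tn": int(np.sum(~t & ~p)),
        }
    return out
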