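"""Confusion matrices and classification metrics for two-class MI decoding.

Class order is fixed to (left, right): rows of the confusion matrix are the
true class, columns the predicted class.  Metrics take *left* as the positive
class:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    accuracy  = (TP + TN) / total     F = 2 P R / (P + R)
    kappa     = (p_o - p_e) / (1 - p_e)   (Cohen, marginal-product p_e)

Raw fractions are stored; percentage display values are rounded half-up to
two decimals and never overwrite the raw numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ShapeError
from .synth import LABEL_NAMES


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), used only for display values."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows = true (left, right), columns = predicted."""

    counts: np.ndarray
    class_order: Sequence[str] = LABEL_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise DimensionError("confusion matrix must be 2x2")
        if np.any(self.counts < 0):
            raise DimensionError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Cross-tabulate integer labels in {0 (left), 1 (right)}."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise DimensionError(
            f"label length mismatch: {t.shape} vs {p.shape}")
    valid = {0, 1}
    if not set(np.unique(t)).issubset(valid) or not set(np.unique(p)).issubset(valid):
        raise DimensionError("labels must be 0 (left) or 1 (right)")
    counts = np.zeros((2, 2), dtype=int)
    for i in range(2):
        for j in range(2):
            counts[i, j] = int(np.sum((t == i) & (p == j)))
    return ConfusionMatrix(counts=counts)


@dataclass
class ClassificationMetrics:
    """Raw fractions in [0, 1]; ``as_percent_row`` gives the display values."""

    precision: float
    recall: float
    accuracy: float
    f_score: float
    kappa: float

    def as_percent_row(self) -> Dict[str, float]:
        return {
            "precision": round_half_up(100 * self.precision),
            "recall": round_half_up(100 * self.recall),
            "accuracy": round_half_up(100 * self.accuracy),
            "f_score": round_half_up(100 * self.f_score),
            "kappa": round_half_up(100 * self.kappa),
        }


def metrics_from_cm(cm: ConfusionMatrix, positive: str = "left"
                    ) -> ClassificationMetrics:
    """Precision/recall/accuracy/F/kappa with the given positive class."""
    if cm.total == 0:
        raise DimensionError("empty confusion matrix")
    c = cm.counts
    if positive == "left":
        tp, fn, fp, tn = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
    elif positive == "right":
        tp, fn, fp, tn = c[1, 1], c[1, 0], c[0, 1], c[0, 0]
    else:
        raise DimensionError(f"unknown positive class {positive!r}")

    total = cm.total
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / total
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    p_o = acc
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / total ** 2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    return ClassificationMetrics(precision=precision, recall=recall,
                                 accuracy=acc, f_score=f, kappa=kappa)


def average_metrics(rows: List[ClassificationMetrics]) -> ClassificationMetrics:
    """Arithmetic mean of per-iteration metrics (the 'Average' row)."""
    if not rows:
        raise DimensionError("no metric rows to average")
    return ClassificationMetrics(
        precision=float(np.mean([r.precision for r in rows])),
        recall=float(np.mean([r.recall for r in rows])),
        accuracy=float(np.mean([r.accuracy for r in rows])),
        f_score=float(np.mean([r.f_score for r in rows])),
        kappa=float(np.mean([r.kappa for r in rows])),
    )


def subject_report(accuracies) -> pd.DataFrame:
    """Per-run x per-subject accuracy table with row/column/grand means.

    ``accuracies``: rectangular runs x subjects array of percentages in
    [0, 100].  Output mirrors the table layout: one row per run plus an
    ``Avg.`` row of column means; last column ``Avg.`` holds row means; the
    bottom-right cell is the grand mean.
    """
    arr = np.asarray(accuracies, dtype=float)
    if arr.ndim != 2:
        raise ShapeError("accuracy table must be rectangular (runs x subjects)")
    if np.any(arr < 0) or np.any(arr > 100):
        raise ShapeError("accuracies must lie in [0, 100]")
    n_runs, n_subj = arr.shape
    idx = [f"R-{i + 1}" for i in range(n_runs)] + ["Avg."]
    cols = [f"S-{j + 1}" for j in range(n_subj)] + ["Avg."]
    out = np.zeros((n_runs + 1, n_subj + 1))
    out[:n_runs, :n_subj] = arr
    out[:n_runs, -1] = arr.mean(axis=1)
    out[-1, :n_subj] = arr.mean(axis=0)
    out[-1, -1] = arr.mean()
    df = pd.DataFrame(out, index=idx, columns=cols)
    return df.map(lambda v: round_half_up(v))


__all__ = ["ConfusionMatrix", "ClassificationMetrics", "confusion",
           "metrics_from_cm", "average_metrics", "subject_report",
           "round_half_up"]
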