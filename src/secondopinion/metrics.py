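"""Confusion-matrix bookkeeping and binary scoring functions.

The positive class is pulp exposure (label 1). All scores are computed from
explicit TP/FP/FN/TN tallies so that degenerate trials (e.g. a protocol that
never predicts the positive class) remain scoreable: a precision or recall
whose denominator is zero is defined as 0, and a class F1 is 0 when
precision + recall is 0. This is the standard convention used by most ML
toolkits and keeps every Monte-Carlo trial on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision_recall",
    "macro_f1",
    "balanced_accuracy",
    "macro_f1_from_counts",
    "macro_f1_batch",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies for a binary prediction task.

    ``tp + fp + fn + tn`` always equals the number of scored cases.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(np.int64)


def confusion(predictions, truth) -> ConfusionCounts:
    """Tally TP/FP/FN/TN of binary ``predictions`` against binary ``truth``."""
    preds = _as_binary(predictions, "predictions")
    y = _as_binary(truth, "truth")
    if preds.shape != y.shape:
        raise ValueError(
            f"length mismatch: {preds.size} predictions vs {y.size} truth labels"
        )
    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0 on empty denominators."""
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return prec, rec


def _f1(prec: float, rec: float) -> float:
    return 2.0 * prec * rec / (prec + rec) if prec + rec else 0.0


def macro_f1_from_counts(counts: ConfusionCounts) -> float:
    """Macro-average F1 from tallies: the unweighted mean of the F1 of the
    exposure class and the F1 of the no-exposure class (scored by swapping
    the roles of the labels, so TN plays TP etc.)."""
    p1, r1 = precision_recall(counts)
    neg = ConfusionCounts(tp=counts.tn, fp=counts.fn, fn=counts.fp, tn=counts.tp)
    p0, r0 = precision_recall(neg)
    return 0.5 * (_f1(p1, r1) + _f1(p0, r0))


def macro_f1(predictions, truth) -> float:
    """Macro-average F1 over the two outcome classes, both weighted equally."""
    return macro_f1_from_counts(confusion(predictions, truth))


def balanced_accuracy(predictions, truth) -> float:
    """Mean of sensitivity and specificity.

    A class absent from ``truth`` contributes 0 to the mean (its conditional
    rate has an empty denominator), mirroring the zero-division rule above.
    """
    c = confusion(predictions, truth)
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    return 0.5 * (sens + spec)


def macro_f1_batch(predictions: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Macro-F1 of many prediction vectors at once.

    ``predictions`` has shape (n_trials, n_cases); ``truth`` has shape
    (n_cases,). Returns one score per row. Used by the Monte-Carlo engine,
    where per-trial Python-level scoring would dominate the run time.
    """
    preds = np.asarray(predictions, dtype=np.int64)
    y = np.asarray(truth, dtype=np.int64)[np.newaxis, :]
    tp = np.sum((preds == 1) & (y == 1), axis=1, dtype=np.float64)
    fp = np.sum((preds == 1) & (y == 0), axis=1, dtype=np.float64)
    fn = np.sum((preds == 0) & (y == 1), axis=1, dtype=np.float64)
    tn = np.sum((preds == 0) & (y == 0), axis=1, dtype=np.float64)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r1 = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1_pos = np.where(p1 + r1 > 0, 2 * p1 * r1 / (p1 + r1), 0.0)
        p0 = np.where(tn + fn > 0, tn / (tn + fn), 0.0)
        r0 = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        f1_neg = np.where(p0 + r0 > 0, 2 * p0 * r0 / (p0 + r0), 0.0)
    return 0.5 * (f1_pos + f1_neg)
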