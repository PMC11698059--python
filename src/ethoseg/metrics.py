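"""Decoding, confusion matrices, classification metrics, and time budgets.

Per-timestep class probabilities are decoded by argmax (ties broken toward
the lowest class index, counted).  From the confusion matrix we derive
global accuracy, per-class precision/recall/F1 and the macro F1 that serves
as the headline score; the macro average is unweighted over classes that
have at least one true or predicted instance, which is the robust choice
under heavy class imbalance.  A time budget is the proportion of labeled
time spent in each behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)


class EmptyEvaluationError(ValueError):
    """Metrics requested from an empty confusion matrix."""


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: sigma(z)_i = exp(z_i) / sum_j exp(z_j)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class PredictionTrack:
    """Reassembled per-timestep class probabilities for one recording."""

    probs: np.ndarray  # (N, C), rows sum to 1
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be (N, C)")

    @property
    def labels(self) -> np.ndarray:
        """Argmax decoding; ties go to the lowest class index."""
        return self.probs.argmax(axis=1)

    @property
    def n_ties(self) -> int:
        top = self.probs.max(axis=1, keepdims=True)
        return int(np.sum((self.probs == top).sum(axis=1) > 1))


@dataclass
class ConfusionMatrix:
    """counts[true, predicted] over a fixed class set."""

    counts: np.ndarray  # (C, C) int64
    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative (C, C) matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> dict[int, tuple[int, int, int, int]]:
        """Per-class (TP, TN, FP, FN) by one-vs-rest reduction."""
        out = {}
        total = self.total
        for i, cls in enumerate(self.classes):
            tp = int(self.counts[i, i])
            fp = int(self.counts[:, i].sum() - tp)
            fn = int(self.counts[i, :].sum() - tp)
            out[cls] = (tp, total - tp - fp - fn, fp, fn)
        return out


@dataclass
class MetricsReport:
    """Percentages derived from one confusion matrix."""

    accuracy: float  # correct / total, %
    ovr_accuracy: float  # one-vs-rest aggregated (TP+TN)/(TP+TN+FP+FN), %
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    macro_f1: float
    weighted_f1: float
    support: dict[int, int] = field(default_factory=dict)


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray,
              class_set: tuple[int, ...] | list[int]) -> ConfusionMatrix:
    """Count (true, predicted) pairs over ``class_set``."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted labels must have equal length")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_set))
    return ConfusionMatrix(counts=counts, classes=tuple(int(c) for c in class_set))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Global accuracy, per-class precision/recall/F1 and macro/weighted F1.

    Zero-denominator precision or recall is defined as 0 (logged); classes
    with neither true nor predicted instances are excluded from the macro
    average.
    """
    if cm.total == 0:
        raise EmptyEvaluationError("empty confusion matrix")
    ovr = cm.one_vs_rest()
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    f1: dict[int, float] = {}
    support: dict[int, int] = {}
    present: list[int] = []
    for cls, (tp, tn, fp, fn) in ovr.items():
        support[cls] = tp + fn
        if tp + fp == 0 and tp + fn > 0:
            logger.debug("class %s never predicted; precision set to 0", cls)
        precision[cls] = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        recall[cls] = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        pr = precision[cls] + recall[cls]
        f1[cls] = 2.0 * precision[cls] * recall[cls] / pr if pr else 0.0
        if tp + fn > 0 or tp + fp > 0:
            present.append(cls)

    correct = float(np.trace(cm.counts))
    tp_s = sum(ovr[c][0] for c in ovr)
    tn_s = sum(ovr[c][1] for c in ovr)
    fp_s = sum(ovr[c][2] for c in ovr)
    fn_s = sum(ovr[c][3] for c in ovr)
    total_support = sum(support[c] for c in present) or 1
    return MetricsReport(
        accuracy=100.0 * correct / cm.total,
        ovr_accuracy=100.0 * (tp_s + tn_s) / (tp_s + tn_s + fp_s + fn_s),
        precision=precision, recall=recall, f1=f1,
        macro_f1=float(np.mean([f1[c] for c in present])) if present else 0.0,
        weighted_f1=float(sum(f1[c] * support[c] for c in present)) / total_support,
        support=support,
    )


def macro_f1_score(true_labels: np.ndarray, predicted_labels: np.ndarray,
                   class_set: tuple[int, ...] | list[int]) -> float:
    """Convenience: macro F1 (%) straight from label arrays."""
    return metrics_from_confusion(
        confusion(true_labels, predicted_labels, class_set)).macro_f1


def time_budget(decoded_labels: np.ndarray,
                class_set: tuple[int, ...] | list[int] | None = None
                ) -> dict[int, float]:
    """Proportion of labeled time in each behavior class (sums to 1)."""
    decoded_labels = np.asarray(decoded_labels)
    if decoded_labels.size == 0:
        raise ValueError("need at least one label")
    if class_set is None:
        class_set = sorted(np.unique(decoded_labels).tolist())
    n = len(decoded_labels)
    return {int(c): float(np.sum(decoded_labels == c)) / n for c in class_set}
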