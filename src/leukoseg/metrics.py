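"""Confusion-matrix evaluation suite for multi-class segmentation.

Every metric derives from the K x K pixel-count confusion matrix
(rows = ground truth, columns = prediction) through the one-vs-rest
reductions TP, FP, FN, TN:

    P   = TP / (TP + FP)            (precision)
    R   = TP / (TP + FN)            (recall)
    F1  = 2PR / (P + R)             (harmonic mean)
    IoU = TP / (FP + TP + FN)       (Jaccard)
    Acc = trace / total             (pixel accuracy)
    mIoU = mean of per-class IoU

Core functions return fractions in [0, 1]; :class:`MetricsReport` carries
the percentage view for human-readable output.  Ratios that are 0/0 (a
class absent from both masks) are reported as the NaN sentinel and such
classes are excluded from the mIoU average rather than counted as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "class_counts",
    "class_metrics",
    "accuracy",
    "miou",
    "f1_from_pr",
    "report",
]


class ClassMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    iou: float


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> np.ndarray:
    """counts[i, j] = number of pixels with truth ``i`` predicted ``j``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if m.min() < 0 or m.max() >= num_classes:
            raise ValueError(f"{name} labels must lie in [0, {num_classes})")
    idx = truth.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64)
    return np.bincount(idx, minlength=num_classes ** 2).reshape(num_classes, num_classes)


def class_counts(cm: np.ndarray, k: int) -> tuple:
    """One-vs-rest (TP, FP, FN, TN) for class ``k``."""
    cm = np.asarray(cm)
    tp = int(cm[k, k])
    fp = int(cm[:, k].sum() - tp)
    fn = int(cm[k, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return tp, fp, fn, tn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: np.ndarray, k: int) -> ClassMetrics:
    """Per-class precision, recall, F1 and IoU as fractions (NaN if 0/0)."""
    tp, fp, fn, _ = class_counts(cm, k)
    p = _ratio(tp, tp + fp)
    r = _ratio(tp, tp + fn)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)  # == 2PR/(P+R) on hard counts
    iou = _ratio(tp, fp + tp + fn)
    return ClassMetrics(p, r, f1, iou)


def accuracy(cm: np.ndarray) -> float:
    """Overall pixel accuracy, trace/total, as a fraction."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm) / total)


def miou(cm: np.ndarray, class_set=None) -> float:
    """Mean per-class IoU over ``class_set`` (default: all classes).

    Classes absent from both masks (0/0 IoU) are excluded from the mean.
    """
    cm = np.asarray(cm)
    classes = range(cm.shape[0]) if class_set is None else list(class_set)
    if len(list(classes)) == 0:
        raise ValueError("class set must not be empty")
    ious = [class_metrics(cm, k).iou for k in classes]
    valid = [v for v in ious if not math.isnan(v)]
    if not valid:
        raise ValueError("no class present in either mask")
    return float(np.mean(valid))


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); scale-agnostic (fractions or percent)."""
    if p + r == 0:
        return float("nan")
    return 2.0 * p * r / (p + r)


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics, expressed as percentages."""

    per_class: dict = field(default_factory=dict)
    accuracy: float = 0.0
    miou: float = 0.0

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "accuracy": self.accuracy,
                "miou": self.miou}

    def table(self) -> str:
        lines = [f"{'class':>12} {'P%':>8} {'R%':>8} {'F1%':>8} {'IoU%':>8}"]
        for name, m in self.per_class.items():
            lines.append(f"{name:>12} " + " ".join(
                f"{m[key]:8.2f}" if not math.isnan(m[key]) else f"{'--':>8}"
                for key in ("precision", "recall", "f1", "iou")))
        lines.append(f"accuracy: {self.accuracy:.2f}%   mIoU: {self.miou:.2f}%")
        return "\n".join(lines)


def report(cm: np.ndarray, class_names=None, class_set=None) -> MetricsReport:
    """Full percentage report from a confusion matrix."""
    cm = np.asarray(cm)
    k = cm.shape[0]
    if class_names is None:
        class_names = [f"class_{i}" for i in range(k)]
    per_class = {}
    for i in range(k):
        m = class_metrics(cm, i)
        per_class[class_names[i]] = {
            "precision": m.precision * 100.0,
            "recall": m.recall * 100.0,
            "f1": m.f1 * 100.0,
            "iou": m.iou * 100.0,
        }
    return MetricsReport(per_class=per_class,
                         accuracy=accuracy(cm) * 100.0,
                         miou=miou(cm, class_set) * 100.0)
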