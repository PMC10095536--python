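"""Focal + Dice loss for multi-class per-pixel segmentation.

Blood smears are extremely class-imbalanced: background (plus red-cell
distractors) dominates, and some leukocyte types are rare.  Two terms
address this:

* focal loss ``-(1 - p_t)^gamma * log(p_t)`` — cross-entropy rescaled so
  confidently-classified pixels contribute little, concentrating gradient
  on hard pixels (gamma = 2 by default; gamma = 0 recovers cross-entropy);
* Dice loss ``1 - mean_k (2*TP_k) / (FP_k + 2*TP_k + FN_k)`` with soft
  (probability-weighted) counts, which scores region overlap per class and
  is insensitive to how much background surrounds a small cell.

The combined objective is their sum.  Each loss has a plain-numpy form
(channels-last ``(H, W, K)`` or ``(N, H, W, K)`` probability maps) and a
differentiable form on :class:`leukoseg.nn.Tensor` (``(N, K, H, W)``) used
by the training loop; a test pins the two paths to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "LossConfig",
    "focal_loss",
    "dice_loss",
    "combined_loss",
    "dice_from_counts",
    "focal_loss_t",
    "dice_loss_t",
    "combined_loss_t",
]

_PT_LO = 1e-7
_PT_HI = 1.0 - 1e-7


@dataclass
class LossConfig:
    """gamma: focal exponent; dice_smooth: soft-Dice smoothing constant;
    dice_class_set: classes averaged in the Dice term (None = all);
    combine_weights: (dice, focal) weights of the sum."""

    gamma: float = 2.0
    dice_smooth: float = 1e-6
    dice_class_set: tuple | None = None
    combine_weights: tuple = (1.0, 1.0)

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")
        if self.dice_class_set is not None and len(self.dice_class_set) == 0:
            raise ValueError("dice_class_set must not be empty")


def _validate(probs: np.ndarray, truth: np.ndarray):
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    if probs.shape[:-1] != truth.shape:
        raise ValueError(
            f"probability map {probs.shape} does not match labels {truth.shape}")
    k = probs.shape[-1]
    if truth.min() < 0 or truth.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    return probs, truth.astype(np.int64), k


def focal_loss(probs: np.ndarray, truth: np.ndarray, gamma: float = 2.0) -> float:
    """Mean over pixels of ``-(1 - p_t)^gamma * log(p_t)``."""
    probs, truth, _ = _validate(probs, truth)
    pt = np.take_along_axis(probs, truth[..., None], axis=-1)[..., 0]
    pt = np.clip(pt, _PT_LO, _PT_HI)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def dice_loss(probs: np.ndarray, truth: np.ndarray,
              cfg: LossConfig | None = None) -> float:
    """``1 - mean_k Dice_k`` with soft per-class counts."""
    cfg = cfg or LossConfig()
    probs, truth, k = _validate(probs, truth)
    classes = range(k) if cfg.dice_class_set is None else cfg.dice_class_set
    s = cfg.dice_smooth
    dices = []
    for c in classes:
        p = probs[..., c]
        t = (truth == c).astype(np.float64)
        tp = float((p * t).sum())
        fp = float((p * (1.0 - t)).sum())
        fn = float(((1.0 - p) * t).sum())
        dices.append((2.0 * tp + s) / (fp + 2.0 * tp + fn + s))
    return 1.0 - float(np.mean(dices))


def combined_loss(probs: np.ndarray, truth: np.ndarray,
                  cfg: LossConfig | None = None) -> float:
    """Weighted sum of Dice and focal terms (default: plain sum)."""
    cfg = cfg or LossConfig()
    wd, wf = cfg.combine_weights
    return wd * dice_loss(probs, truth, cfg) + wf * focal_loss(probs, truth, cfg.gamma)


def dice_from_counts(tp: float, fp: float, fn: float, smooth: float = 0.0) -> float:
    """Dice coefficient ``2TP / (FP + 2TP + FN)`` from hard counts."""
    return (2.0 * tp + smooth) / (fp + 2.0 * tp + fn + smooth)


# -- differentiable forms (NCHW tensors) ----------------------------------

def focal_loss_t(probs: nn.Tensor, labels: np.ndarray, gamma: float = 2.0) -> nn.Tensor:
    pt = nn.take_class(probs, labels).clip(_PT_LO, _PT_HI)
    return (((1.0 - pt) ** gamma) * -pt.log()).mean()


def dice_loss_t(probs: nn.Tensor, labels: np.ndarray,
                cfg: LossConfig | None = None) -> nn.Tensor:
    cfg = cfg or LossConfig()
    k = probs.shape[1]
    classes = range(k) if cfg.dice_class_set is None else cfg.dice_class_set
    s = cfg.dice_smooth
    total = None
    for c in classes:
        p = probs[:, c]
        t = (labels == c).astype(np.float64)
        tp = (p * t).sum()
        fp = (p * (1.0 - t)).sum()
        fn = ((1.0 - p) * t).sum()
        dice = (tp * 2.0 + s) / (fp + tp * 2.0 + fn + s)
        total = dice if total is None else total + dice
    return 1.0 - total * (1.0 / len(list(classes)))


def combined_loss_t(probs: nn.Tensor, labels: np.ndarray,
                    cfg: LossConfig | None = None) -> nn.Tensor:
    cfg = cfg or LossConfig()
    wd, wf = cfg.combine_weights
    return (dice_loss_t(probs, labels, cfg) * wd
            + focal_loss_t(probs, labels, cfg.gamma) * wf)
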