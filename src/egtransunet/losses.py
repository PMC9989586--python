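"""Training objective (BCE + Dice) and confusion-count evaluation metrics.

The training loss is ``L = alpha * L_BCE + beta * L_Dice`` with
``alpha = beta = 0.5`` by default and smoothing ``epsilon = 1e-6`` in the
Dice term.  Two Dice-loss variants are available:

* ``conventional`` (default): ``1 - (2*sum(y*p) + eps) / (sum(y) + sum(p) + eps)``,
  which is zero for a perfect prediction;
* ``printed``: ``1 - (sum(y*p) + eps) / (sum(y + p) + eps)``, the variant
  without the factor 2 (it tends to 0.5 for a perfect prediction on a
  large mask) — kept selectable for fidelity with its published form.

BCE is reduced as a mean over pixels by default so its magnitude does not
grow with image size relative to the Dice term; the sum reduction is
available via ``bce_reduction="sum"``.

Evaluation metrics are computed from pixel confusion counts:
``dice = 2TP/(2TP+FP+FN)``, ``iou = TP/(TP+FP+FN)`` (Jaccard),
``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``.  Degenerate cases
follow the empty-mask convention: if TP = FP = FN = 0 every metric is 1;
if TP = 0 with FP + FN > 0 every metric is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Union

import numpy as np

from .nn import Tensor, as_tensor

CLIP = 1e-7

ArrayLike = Union[np.ndarray, Tensor, float, list]


@dataclass
class LossConfig:
    alpha: float = 0.5
    beta: float = 0.5
    epsilon: float = 1e-6
    dice_form: str = "conventional"  # or "printed"
    bce_reduction: str = "mean"      # or "sum"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.dice_form not in ("conventional", "printed"):
            raise ValueError(f"unknown dice_form {self.dice_form!r}")
        if self.bce_reduction not in ("mean", "sum"):
            raise ValueError(f"unknown bce_reduction {self.bce_reduction!r}")


def _pair(y: ArrayLike, p: ArrayLike):
    """Coerce (truth, prediction) to Tensors with matching shapes."""
    was_tensor = isinstance(p, Tensor)
    y, p = as_tensor(y), as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs prediction {p.shape}")
    return y, p, was_tensor


def _ret(value: Tensor, as_tensor_out: bool):
    return value if as_tensor_out else float(value.data)


def bce_loss(y: ArrayLike, p: ArrayLike, reduction: str = "mean"):
    """Binary cross-entropy, probabilities clipped away from {0, 1}."""
    y, p, t = _pair(y, p)
    p = p.clip(CLIP, 1.0 - CLIP)
    per_pixel = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    out = per_pixel.mean() if reduction == "mean" else per_pixel.sum()
    return _ret(out, t)


def dice_loss(y: ArrayLike, p: ArrayLike, config: LossConfig = None):
    """Soft Dice loss with epsilon smoothing (conventional or printed form)."""
    config = config or LossConfig()
    y, p, t = _pair(y, p)
    eps = config.epsilon
    inter = (y * p).sum()
    if config.dice_form == "conventional":
        out = 1.0 - (2.0 * inter + eps) / (y.sum() + p.sum() + eps)
    else:
        out = 1.0 - (inter + eps) / ((y + p).sum() + eps)
    return _ret(out, t)


def total_loss(y: ArrayLike, p: ArrayLike, config: LossConfig = None):
    """``alpha * BCE + beta * Dice``; both terms share the config."""
    config = config or LossConfig()
    y, p, t = _pair(y, p)
    out = config.alpha * bce_loss(y, p, reduction=config.bce_reduction) + (
        config.beta * dice_loss(y, p, config)
    )
    out = as_tensor(out)
    return _ret(out, t)


# --------------------------------------------------------------------------
# Confusion counts and metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(pred: ArrayLike, truth: ArrayLike, threshold: float = 0.5) -> ConfusionCounts:
    """Pixel confusion counts after thresholding ``pred >= threshold``."""
    pred = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
    truth = truth.data if isinstance(truth, Tensor) else np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    hard = pred >= threshold
    t = truth >= 0.5
    return ConfusionCounts(
        tp=int(np.sum(hard & t)),
        tn=int(np.sum(~hard & ~t)),
        fp=int(np.sum(hard & ~t)),
        fn=int(np.sum(~hard & t)),
    )


def metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Dice / IoU / precision / recall with the empty-mask convention."""
    if c.tp == 0:
        value = 1.0 if (c.fp + c.fn) == 0 else 0.0
        return {"dice": value, "iou": value, "precision": value, "recall": value}
    return {
        "dice": 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn),
        "iou": c.tp / (c.tp + c.fp + c.fn),
        "precision": c.tp / (c.tp + c.fp),
        "recall": c.tp / (c.tp + c.fn),
    }
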