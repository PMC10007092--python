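"""Dice loss family, regularized total loss and the segmentation metric suite.

The training objective is a soft multi-class Dice loss over per-pixel class
probabilities

    K = 1 - sum_l  w_l * 2 * sum_g n(l,g) i(l,g)
                   / (sum_g n(l,g)^2 + sum_g i(l,g)^2 + eps)

with class weights w_l summing to one and a small epsilon in the denominator
guarding empty classes. A lesion-weighted binary variant triples the
ground-truth term in the denominator (and rescales the numerator so a perfect
prediction still scores zero), penalizing under-segmentation of the tumor
more heavily than over-segmentation. Both are differentiable in the
probabilities and accept either NumPy arrays or autodiff tensors.

Evaluation metrics follow the standard confusion-matrix definitions
(accuracy, precision, recall = sensitivity, specificity), plus MSE and PSNR
for the reconstruction branch. A ``paper_exact`` switch reproduces an
alternative printed convention in which sensitivity uses the TP + FP
denominator and specificity is TN / (TP + FP); it exists for comparison only
and is not the default. Metrics with a zero denominator are reported as NaN,
never silently as zero, so averages cannot be inflated by degenerate cases.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice_loss",
    "weighted_dice_loss",
    "total_loss",
    "dice_coefficient",
    "confusion",
    "classification_metrics",
    "mse",
    "psnr",
]

DICE_EPS = 1e-6


def _check_weights(weights, num_classes: int) -> np.ndarray:
    if weights is None:
        return np.full(num_classes, 1.0 / num_classes)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (num_classes,):
        raise ValueError(f"expected {num_classes} class weights")
    if np.any(weights < 0):
        raise ValueError("class weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"class weights must sum to 1, got {weights.sum()}")
    return weights


def dice_loss(probs, onehot, weights=None, eps: float = DICE_EPS):
    """Weighted soft Dice loss in [0, 1]; 0 at perfect overlap, 1 at disjoint.

    ``probs``: (H, W, L) class probabilities (array or autodiff Tensor).
    ``onehot``: (H, W, L) 0/1 ground truth. Returns a float, or a Tensor when
    ``probs`` is a Tensor (for use inside a training graph).
    """
    onehot = np.asarray(onehot, dtype=np.float64)
    is_tensor = isinstance(probs, Tensor)
    p_arr = probs.data if is_tensor else np.asarray(probs, dtype=np.float64)
    if p_arr.shape != onehot.shape or p_arr.ndim != 3:
        raise ValueError("probs and onehot must both be (H, W, L)")
    w = _check_weights(weights, p_arr.shape[2])
    if is_tensor:
        num = (probs * onehot).sum(axis=(0, 1)) * 2.0
        den = (probs * probs).sum(axis=(0, 1)) + (onehot ** 2).sum(axis=(0, 1)) + eps
        return 1.0 - ((num / den) * w).sum()
    num = 2.0 * (p_arr * onehot).sum(axis=(0, 1))
    den = (p_arr ** 2).sum(axis=(0, 1)) + (onehot ** 2).sum(axis=(0, 1)) + eps
    return float(1.0 - (w * num / den).sum())


def weighted_dice_loss(probs, truth, eps: float = DICE_EPS):
    """Binary Dice loss with the ground-truth term weighted 3x in the denominator.

    ``probs``: (H, W) foreground probabilities; ``truth``: (H, W) binary mask.
    The numerator is rescaled (2 -> 4) so a perfect hard prediction scores 0;
    disjoint masks score 1. Under-covering the lesion costs strictly more
    than under the plain Dice loss.
    """
    truth = np.asarray(truth, dtype=np.float64)
    vals = np.unique(truth)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("truth mask must be binary (0/1)")
    is_tensor = isinstance(probs, Tensor)
    p_arr = probs.data if is_tensor else np.asarray(probs, dtype=np.float64)
    if p_arr.shape != truth.shape or p_arr.ndim != 2:
        raise ValueError("probs and truth must both be 2D and congruent")
    if is_tensor:
        num = (probs * truth).sum() * 4.0
        den = (probs * probs).sum() + 3.0 * truth.sum() + eps
        return 1.0 - num / den
    num = 4.0 * (p_arr * truth).sum()
    den = (p_arr ** 2).sum() + 3.0 * (truth ** 2).sum() + eps
    return float(1.0 - num / den)


def total_loss(dice, params=(), lam: float = 1e-4):
    """Dice term plus an L2 penalty on the given weight arrays.

    With ``lam == 0`` the Dice term is returned unchanged (bitwise). Biases
    should not be included in ``params``.
    """
    if lam < 0:
        raise ValueError("regularization coefficient must be non-negative")
    if lam == 0:
        return dice
    if isinstance(dice, Tensor) or any(isinstance(p, Tensor) for p in params):
        reg = 0.0
        for p in params:
            pt = p if isinstance(p, Tensor) else Tensor(p)
            reg = reg + (pt * pt).sum()
        return dice + lam * reg
    reg = sum(float((np.asarray(p) ** 2).sum()) for p in params)
    return float(dice + lam * reg)


def dice_coefficient(pred_labels: np.ndarray, true_labels: np.ndarray,
                     cls: int = 1) -> float:
    """Hard Dice overlap 2|A∩B| / (|A| + |B|) for one class; 1.0 if both empty."""
    a = np.asarray(pred_labels) == cls
    b = np.asarray(true_labels) == cls
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel tallies for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray,
              positive_class: int = 1) -> ConfusionCounts:
    """Pixelwise one-vs-rest confusion tallies; tp+fp+tn+fn equals pixel count."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"label maps differ in shape: {pred.shape} vs {true.shape}")
    p = pred == positive_class
    t = true == positive_class
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


@dataclass
class MetricsReport:
    """Evaluation metrics; NaN marks a metric whose denominator was zero."""

    accuracy: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    mse: float | None = None
    psnr: float | None = None
    dice_per_class: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float)

    def tsv_row(self, prefix: tuple[str, ...] = ()) -> str:
        vals = [self.accuracy, self.precision, self.recall,
                self.sensitivity, self.specificity, self.mse, self.psnr]
        cells = list(prefix) + [
            "" if v is None else f"{v:.6g}" for v in vals
        ] + [f"{d:.6g}" for d in self.dice_per_class]
        return "\t".join(cells)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(counts: ConfusionCounts,
                           paper_exact: bool = False) -> MetricsReport:
    """Accuracy, precision, recall/sensitivity and specificity from tallies.

    Default definitions: recall = sensitivity = TP/(TP+FN) and
    specificity = TN/(TN+FP). With ``paper_exact`` the alternative printed
    convention sensitivity = TP/(TP+FP), specificity = TN/(TP+FP) is used.
    """
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if paper_exact:
        sens = _ratio(tp, tp + fp)
        spec = _ratio(tn, tp + fp)
    else:
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
    return MetricsReport(
        accuracy=_ratio(tp + tn, counts.total),
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        sensitivity=sens,
        specificity=spec,
    )


def mse(pred: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared difference over all pixels."""
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    return float(((pred - actual) ** 2).mean())


def psnr(pred: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    err = mse(pred, ref)
    if err == 0:
        return math.inf
    return float(10.0 * math.log10(peak ** 2 / err))
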