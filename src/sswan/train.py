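"""Training loop: joint Dice + self-supervised reconstruction objective.

One epoch is one pass over the sample list in fixed order, with an Adam step
per sample. The per-sample objective is

    L = dice_weight * K_dice(probs, labels)
      + recon_weight * MSE(reconstruction, normalized image)
      + lam * sum ||W||^2        (weights only, no biases)

The reconstruction term is the self-supervised part — its target is derived
from the input image itself — and it is also the only path through which the
final coefficient-fusion convolution receives gradient, so it is on by
default. Setting ``recon_weight=0`` recovers a pure supervised Dice
objective; setting ``dice_weight=0`` gives a reconstruction-only pretext
phase. Everything is deterministic given the model seed (the loop itself
draws no randomness).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .losses import dice_coefficient, dice_loss
from .network import SSWAN

__all__ = ["TrainConfig", "train", "evaluate_dice", "evaluate_reconstruction"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, constant learning rate)."""

    epochs: int = 200
    lr: float = 1e-3
    dice_weight: float = 1.0
    recon_weight: float = 1.0
    reg_lambda: float = 0.0
    class_weights: tuple | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be non-negative")
        if self.dice_weight == 0 and self.recon_weight == 0:
            raise ValueError("at least one of dice_weight/recon_weight must be nonzero")


def _onehot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    eye = np.eye(num_classes)
    return eye[np.asarray(labels, dtype=int)]


def _pad_labels(labels: np.ndarray) -> np.ndarray:
    pr = labels.shape[0] % 2
    pc = labels.shape[1] % 2
    if pr or pc:
        labels = np.pad(labels, ((0, pr), (0, pc)), mode="symmetric")
    return labels


def train(model: SSWAN, samples, config: TrainConfig | None = None,
          log=None) -> list[dict]:
    """Optimize ``model`` on (image, labels) pairs; returns per-epoch history.

    ``samples`` is a sequence of objects with ``image`` and ``labels``
    attributes (phantom samples) or plain (image, labels) tuples. History
    entries carry the epoch index, mean loss and mean foreground Dice of the
    predictions seen during the pass.
    """
    config = config or TrainConfig()
    pairs = [(s.image, s.labels) if hasattr(s, "image") else tuple(s)
             for s in samples]
    L = model.config.num_classes
    onehots = [_onehot(_pad_labels(lab), L) for _, lab in pairs]
    opt = Adam(model.params, lr=config.lr)
    weights = (None if config.class_weights is None
               else np.asarray(config.class_weights, dtype=np.float64))
    history: list[dict] = []
    for epoch in range(config.epochs):
        losses, dices = [], []
        for (img, lab), oh in zip(pairs, onehots):
            out = model.forward(img)
            loss = 0.0
            if config.dice_weight:
                dterm = dice_loss(out["probs_padded"], oh, weights=weights)
                loss = loss + config.dice_weight * dterm
            if config.recon_weight:
                diff = out["recon"] - out["norm"]
                loss = loss + config.recon_weight * (diff * diff).mean()
            if config.reg_lambda:
                reg = 0.0
                for wt in model.weight_tensors():
                    reg = reg + (wt * wt).sum()
                loss = loss + config.reg_lambda * reg
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            pred = out["probs_padded"].data.argmax(axis=2)
            dices.append(dice_coefficient(pred, _pad_labels(lab), cls=1))
        entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                 "mean_foreground_dice": float(np.mean(dices))}
        history.append(entry)
        if log is not None:
            log(entry)
    return history


def evaluate_dice(model: SSWAN, samples, cls: int = 1) -> float:
    """Mean hard Dice of ``cls`` over the samples (fresh forward passes)."""
    pairs = [(s.image, s.labels) if hasattr(s, "image") else tuple(s)
             for s in samples]
    return float(np.mean([
        dice_coefficient(model.segment(img).label_map, lab, cls=cls)
        for img, lab in pairs
    ]))


def evaluate_reconstruction(model: SSWAN, samples) -> dict:
    """Mean reconstruction MSE/PSNR against the normalized inputs."""
    from .losses import mse as _mse, psnr as _psnr

    mses, psnrs = [], []
    for s in samples:
        img = s.image if hasattr(s, "image") else s[0]
        out = model.forward(img)
        ref, rec = out["norm"], out["recon"].data
        peak = float(ref.max() - ref.min()) or 1.0
        mses.append(_mse(rec, ref))
        psnrs.append(_psnr(rec, ref, peak=peak))
    return {"mse": float(np.mean(mses)), "psnr": float(np.mean(psnrs))}
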