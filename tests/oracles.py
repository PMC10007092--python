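"""Independent brute-force oracles used to validate the vectorized code paths.

Everything here is written with explicit Python loops and elementary
arithmetic, deliberately avoiding pywt and the package's autodiff engine, so
agreement between an oracle and the implementation is evidence for both.
"""
from __future__ import annotations

import math

import numpy as np

INV_SQRT2 = 1.0 / math.sqrt(2.0)

# Orthonormal Haar analysis filters (lowpass, highpass).
HAAR_LO = (INV_SQRT2, INV_SQRT2)
HAAR_HI = (-INV_SQRT2, INV_SQRT2)


def haar_analysis_axis(x: np.ndarray, filt, axis: int) -> np.ndarray:
    """Periodized filter + downsample-by-2 along one axis, by explicit loops.

    Convention matched to periodized convolution: output k combines samples
    (2k, 2k+1) with filter taps applied in reverse (convolution) order.
    """
    x = np.asarray(x, dtype=np.float64)
    if axis == 1:
        return haar_analysis_axis(x.T, filt, 0).T
    n = x.shape[0]
    out = np.zeros((n // 2,) + x.shape[1:])
    for k in range(n // 2):
        for t, coeff in enumerate(filt):
            out[k] += coeff * x[(2 * k + 1 - t) % n]
    return out


def haar_dwt2_oracle(image: np.ndarray) -> dict[str, np.ndarray]:
    """Four coefficient channels named by (row filter, column filter)."""
    lo_r = haar_analysis_axis(image, HAAR_LO, axis=0)
    hi_r = haar_analysis_axis(image, HAAR_HI, axis=0)
    return {
        "ll": haar_analysis_axis(lo_r, HAAR_LO, axis=1),
        "lh": haar_analysis_axis(lo_r, HAAR_HI, axis=1),
        "hl": haar_analysis_axis(hi_r, HAAR_LO, axis=1),
        "hh": haar_analysis_axis(hi_r, HAAR_HI, axis=1),
    }


def conv2d_same_oracle(x: np.ndarray, weight: np.ndarray,
                       bias: np.ndarray | float = 0.0) -> np.ndarray:
    """Same-padded stride-1 correlation by quadruple loop.

    x: (H, W, Cin); weight: (kh, kw, Cin, Cout); zero padding.
    """
    h, w, cin = x.shape
    kh, kw, _, cout = weight.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((h, w, cout))
    for i in range(h):
        for j in range(w):
            for a in range(kh):
                for b in range(kw):
                    ii, jj = i + a - ph, j + b - pw
                    if 0 <= ii < h and 0 <= jj < w:
                        out[i, j] += x[ii, jj] @ weight[a, b]
    return out + np.asarray(bias)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _leaky(z, alpha):
    return np.where(z >= 0, z, alpha * z)


def channel_descriptor_oracle(feat: np.ndarray, w1, b1, w2, b2,
                              alpha: float) -> np.ndarray:
    """Per-channel gate by explicit pooling and per-element MLP arithmetic."""
    h, w, c = feat.shape
    pmax = np.array([feat[:, :, k].max() for k in range(c)])
    pavg = np.array([feat[:, :, k].mean() for k in range(c)])

    def mlp(p):
        hidden = _leaky(np.array(
            [sum(p[i] * w1[i, j] for i in range(c)) + b1[j]
             for j in range(w1.shape[1])]), alpha)
        return np.array(
            [sum(hidden[j] * w2[j, k] for j in range(w2.shape[0])) + b2[k]
             for k in range(c)])

    return _sigmoid(mlp(pmax) + mlp(pavg))


def spatial_descriptor_oracle(feat: np.ndarray, kernel: np.ndarray,
                              bias: float) -> np.ndarray:
    """Per-position gate: channel pooling, 7x7 same conv, sigmoid — all loops."""
    h, w, c = feat.shape
    stacked = np.zeros((h, w, 2))
    for i in range(h):
        for j in range(w):
            stacked[i, j, 0] = feat[i, j].max()
            stacked[i, j, 1] = feat[i, j].mean()
    conv = conv2d_same_oracle(stacked, kernel, bias)
    return _sigmoid(conv[..., 0])


def dice_loss_oracle(probs: np.ndarray, onehot: np.ndarray,
                     weights, eps: float = 1e-6) -> float:
    """Explicit-sum weighted soft Dice loss."""
    h, w, L = probs.shape
    loss = 1.0
    for l in range(L):
        num = den_p = den_t = 0.0
        for i in range(h):
            for j in range(w):
                num += probs[i, j, l] * onehot[i, j, l]
                den_p += probs[i, j, l] ** 2
                den_t += onehot[i, j, l] ** 2
        loss -= weights[l] * 2.0 * num / (den_p + den_t + eps)
    return loss


def confusion_oracle(pred: np.ndarray, truth: np.ndarray,
                     positive: int) -> tuple[int, int, int, int]:
    """Per-pixel counting loop -> (tp, fp, tn, fn)."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p = pred[i, j] == positive
            t = truth[i, j] == positive
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
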