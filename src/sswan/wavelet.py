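"""Single-level 2D discrete wavelet analysis/synthesis and the bicubic baseline.

One analysis level splits an image into four half-resolution coefficient
channels — LL (approximation), LH (vertical-edge detail), HL (horizontal-edge
detail) and HH (diagonal detail). The channel naming convention here is that
the first letter is the filter applied along rows (axis 0) and the second the
filter along columns (axis 1). With an orthonormal filter pair (the default
Haar) the transform conserves energy and is exactly invertible, which is what
lets the network learn in the coefficient domain and map back losslessly.

Odd-sized images are symmetrically padded to even size before analysis; the
pad is recorded on the stack so synthesis restores the original shape.

The bicubic resampler is the classic Keys cubic-convolution kernel (a = -1/2)
with half-pixel center alignment, the convention used by standard image
toolboxes. It is local (4 taps per axis), reproduces constants everywhere and
linear ramps away from the border exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "CoefficientStack",
    "dwt2",
    "idwt2",
    "bicubic_baseline",
    "degraded_baseline",
    "residual_target",
    "pad_to_even",
]


@dataclass
class CoefficientStack:
    """Four half-resolution wavelet coefficient channels of one image.

    ``pad`` records how many rows/columns of symmetric padding were appended
    before analysis so that synthesis can crop back to the source shape.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    wavelet: str = "haar"
    pad: tuple[int, int] = (0, 0)

    def __post_init__(self):
        for name in ("ll", "lh", "hl", "hh"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"{name} must be a 2D array")
            setattr(self, name, arr)
        shapes = {self.ll.shape, self.lh.shape, self.hl.shape, self.hh.shape}
        if len(shapes) != 1:
            raise ValueError(f"coefficient channels disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ll.shape

    def as_array(self) -> np.ndarray:
        """Channel-last (H, W, 4) array in the documented (LL, LH, HL, HH) order."""
        return np.stack([self.ll, self.lh, self.hl, self.hh], axis=-1)

    @classmethod
    def from_array(cls, arr: np.ndarray, wavelet: str = "haar",
                   pad: tuple[int, int] = (0, 0)) -> "CoefficientStack":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[-1] != 4:
            raise ValueError("expected an (H, W, 4) array")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3],
                   wavelet=wavelet, pad=pad)

    def energy(self) -> float:
        return float(sum((c ** 2).sum() for c in (self.ll, self.lh, self.hl, self.hh)))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image plane")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError(f"image too small for analysis: {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def pad_to_even(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetrically pad the trailing edge so both dimensions are even."""
    pr = image.shape[0] % 2
    pc = image.shape[1] % 2
    if pr or pc:
        image = np.pad(image, ((0, pr), (0, pc)), mode="symmetric")
    return image, (pr, pc)


def dwt2(image: np.ndarray, wavelet: str = "haar") -> CoefficientStack:
    """One analysis level; returns the four half-resolution channels.

    Uses periodized convolution so the coefficient arrays are exactly half
    the (padded) image size and orthonormal filters conserve energy.
    """
    image = _check_image(image)
    image, pad = pad_to_even(image)
    ca, (ch, cv, cd) = pywt.dwt2(image, wavelet, mode="periodization")
    # pywt cH is the row-axis highpass; our LH is the column-axis highpass.
    return CoefficientStack(ll=ca, lh=cv, hl=ch, hh=cd, wavelet=wavelet, pad=pad)


def idwt2(coeffs: CoefficientStack) -> np.ndarray:
    """Inverse of :func:`dwt2`; restores the original (pre-pad) shape."""
    rec = pywt.idwt2((coeffs.ll, (coeffs.hl, coeffs.lh, coeffs.hh)),
                     coeffs.wavelet, mode="periodization")
    pr, pc = coeffs.pad
    if pr:
        rec = rec[:-pr, :]
    if pc:
        rec = rec[:, :-pc]
    return rec


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic-convolution kernel on |t| <= 2."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _resample_axis_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """4-tap indices (n_out, 4) and weights for one axis, half-pixel centers."""
    scale = n_out / n_in
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    base = np.floor(src).astype(int)
    offs = np.arange(-1, 3)
    idx = base[:, None] + offs[None, :]
    wts = _keys_kernel(src[:, None] - idx)
    wts /= wts.sum(axis=1, keepdims=True)  # partition of unity (exact constants)
    idx = np.clip(idx, 0, n_in - 1)        # replicate borders
    return idx, wts


def bicubic_baseline(image: np.ndarray, scale: float) -> np.ndarray:
    """Bicubic (Keys kernel) resampling by a positive scale factor."""
    image = _check_image(image)
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if scale == 1:
        return image.copy()
    r_out = max(int(round(image.shape[0] * scale)), 1)
    c_out = max(int(round(image.shape[1] * scale)), 1)
    ri, rw = _resample_axis_weights(image.shape[0], r_out)
    ci, cw = _resample_axis_weights(image.shape[1], c_out)
    tmp = np.einsum("rkc,rk->rc", image[ri, :], rw)          # rows
    return np.einsum("rck,ck->rc", tmp[:, ci], cw)           # cols


def degraded_baseline(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Bicubic downsample-then-upsample baseline at the original resolution.

    This is the low-frequency reference the network's global residual branch
    is added back onto; the residual it must learn is the detail this
    round-trip destroys.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return _check_image(image).copy()
    image = _check_image(image)
    low = bicubic_baseline(image, 1.0 / factor)
    up = bicubic_baseline(low, factor)
    if up.shape != image.shape:  # non-divisible sizes round; resample to match
        ri, rw = _resample_axis_weights(up.shape[0], image.shape[0])
        ci, cw = _resample_axis_weights(up.shape[1], image.shape[1])
        tmp = np.einsum("rkc,rk->rc", up[ri, :], rw)
        up = np.einsum("rck,ck->rc", tmp[:, ci], cw)
    return up


def residual_target(full: np.ndarray, baseline: np.ndarray,
                    wavelet: str = "haar") -> CoefficientStack:
    """Wavelet coefficients of the residual image (training target).

    The network is trained so its predicted stack matches the analysis of the
    difference between the true image and its bicubic baseline.
    """
    full = _check_image(full)
    baseline = _check_image(baseline)
    if full.shape != baseline.shape:
        raise ValueError(
            f"full {full.shape} and baseline {baseline.shape} shapes differ")
    return dwt2(full - baseline, wavelet=wavelet)
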