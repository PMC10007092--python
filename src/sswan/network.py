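"""The wavelet-domain attention network (SSW-AN) and its forward pipeline.

Pipeline for one 2D slice of shape (r, c):

1. per-image z-score normalization, symmetric pad to even size;
2. bicubic degrade-upsample baseline (the low-frequency reference);
3. one-level DWT of the baseline -> four (r/2, c/2) coefficient channels;
4. shallow extraction: 5x5 conv to width w + leaky ReLU;
5. T stacked attention blocks (SSABs), each with a local skip;
6. channel concatenation of all T block outputs (width w*T) — a dense
   shortcut that keeps gradient flowing to the early blocks;
7. fusion: 3x3 conv back to width w + leaky ReLU, then 3x3 conv to the four
   predicted residual coefficient channels;
8. global residual reconstruction: inverse DWT of the prediction plus the
   bicubic baseline;
9. segmentation head: 1x1 conv on the fused width-w features to L class
   scores, bilinear 2x upsampling to input resolution, per-pixel softmax.

The reconstruction branch is the self-supervised part — its target, the
wavelet coefficients of (image - baseline), comes for free from the input.
The head turns the same features into class probabilities and is trained
with the Dice loss.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import wavelet as wv
from .attention import ssab_block_t
from .autodiff import Tensor, concat, conv2d, upsample2x
from .wavelet import CoefficientStack

__all__ = ["NetworkConfig", "SegmentationOutput", "SSWAN",
           "reconstruct", "count_parameters"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``num_blocks`` (T) and ``width`` (w) default to the full-scale settings
    (8 blocks, 64 channels); tests and desk-scale runs use much smaller
    values. ``reduction`` is the channel-attention bottleneck ratio h, so the
    hidden MLP width is w/h. ``leaky_slope`` is the negative slope of every
    leaky ReLU — the coefficient channels are signed, so a one-sided ReLU
    would discard half the signal. ``downsample_factor`` controls how much
    detail the bicubic baseline destroys (and hence how much the residual
    branch must restore).
    """

    num_blocks: int = 8
    width: int = 64
    reduction: int = 4
    leaky_slope: float = 0.2
    num_classes: int = 2
    wavelet: str = "haar"
    downsample_factor: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.num_blocks < 1:
            raise ValueError("num_blocks must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.width < 1 or self.width % self.reduction != 0:
            raise ValueError("width must be positive and divisible by reduction")


@dataclass
class SegmentationOutput:
    """Per-slice network output."""

    reconstructed: np.ndarray          # (r, c) image estimate
    class_probs: np.ndarray            # (r, c, L), rows sum to 1 per pixel
    label_map: np.ndarray              # (r, c) int argmax labels

    def __post_init__(self):
        s = np.abs(self.class_probs.sum(axis=2) - 1.0).max()
        if s > 1e-6:
            raise ValueError("class probabilities must sum to 1 per pixel")


def reconstruct(ic: CoefficientStack, baseline: np.ndarray) -> np.ndarray:
    """Global residual reconstruction: inverse DWT of ``ic`` plus the baseline."""
    rec = wv.idwt2(ic)
    baseline = np.asarray(baseline, dtype=np.float64)
    if rec.shape != baseline.shape:
        raise ValueError(
            f"coefficient stack implies {rec.shape}, baseline is {baseline.shape}")
    return rec + baseline


def _zscore(image: np.ndarray) -> np.ndarray:
    mu = image.mean()
    sd = image.std()
    return (image - mu) / (sd if sd > 1e-12 else 1.0)


class _IDWTOp:
    """Differentiable inverse DWT: orthonormal, so the adjoint is the forward DWT."""

    @staticmethod
    def apply(coeff_map: Tensor, wavelet: str) -> Tensor:
        import pywt

        def synth(arr):
            return pywt.idwt2((arr[..., 0], (arr[..., 2], arr[..., 1], arr[..., 3])),
                              wavelet, mode="periodization")

        y = synth(coeff_map.data)
        out = Tensor._child(y, (coeff_map,), None)

        def bw(g):
            import pywt as _p
            ca, (ch, cv, cd) = _p.dwt2(g, wavelet, mode="periodization")
            coeff_map._accum(np.stack([ca, cv, ch, cd], axis=-1))

        out._bw = bw
        return out


class SSWAN:
    """The assembled network; parameters are named autodiff tensors.

    Initialization is Kaiming-uniform from a seeded generator; two models
    built from the same config are bitwise identical.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, t, h = config.width, config.num_blocks, config.reduction
        p: dict[str, np.ndarray] = {}
        p["shallow/w"] = _kaiming(rng, (5, 5, 4, w))
        p["shallow/b"] = np.zeros(w)
        for i in range(t):
            p[f"block{i}/conv_w"] = _kaiming(rng, (3, 3, w, w))
            p[f"block{i}/conv_b"] = np.zeros(w)
            p[f"block{i}/ca_w1"] = _kaiming(rng, (w, w // h), fan_in=w)
            p[f"block{i}/ca_b1"] = np.zeros(w // h)
            p[f"block{i}/ca_w2"] = _kaiming(rng, (w // h, w), fan_in=w // h)
            p[f"block{i}/ca_b2"] = np.zeros(w)
            p[f"block{i}/sa_k"] = _kaiming(rng, (7, 7, 2, 1))
            p[f"block{i}/sa_b"] = np.zeros(())
        p["fuse1/w"] = _kaiming(rng, (3, 3, w * t, w))
        p["fuse1/b"] = np.zeros(w)
        p["fuse2/w"] = _kaiming(rng, (3, 3, w, 4))
        p["fuse2/b"] = np.zeros(4)
        p["head/w"] = _kaiming(rng, (1, 1, w, config.num_classes))
        p["head/b"] = np.zeros(config.num_classes)
        self.params: dict[str, Tensor] = {
            k: Tensor(v, requires_grad=True) for k, v in p.items()
        }

    # -- sub-operations (NumPy-facing, mirrored inside the training graph) ----

    def shallow_extract(self, coeffs: CoefficientStack) -> np.ndarray:
        """5x5 conv + leaky ReLU on the 4-channel stack -> (r/2, c/2, w)."""
        return self._shallow_t(Tensor(coeffs.as_array())).data

    def _shallow_t(self, stack4: Tensor) -> Tensor:
        out = conv2d(stack4, self.params["shallow/w"], self.params["shallow/b"])
        return out.leaky_relu(self.config.leaky_slope)

    def forward_trunk(self, i0: np.ndarray) -> CoefficientStack:
        """Blocks + concat + fusion -> predicted residual coefficients."""
        i0 = np.asarray(i0, dtype=np.float64)
        if i0.ndim != 3 or i0.shape[2] != self.config.width:
            raise ValueError(f"expected width-{self.config.width} features")
        ic, _ = self._trunk_t(Tensor(i0))
        return CoefficientStack.from_array(ic.data, wavelet=self.config.wavelet)

    def _trunk_t(self, i0: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (predicted coefficient map (r/2, c/2, 4), fused features)."""
        alpha = self.config.leaky_slope
        feat = i0
        states = []
        for i in range(self.config.num_blocks):
            ca = {k: self.params[f"block{i}/ca_{k}"] for k in ("w1", "b1", "w2", "b2")}
            sa = {"kernel": self.params[f"block{i}/sa_k"],
                  "bias": self.params[f"block{i}/sa_b"]}
            feat = ssab_block_t(feat, self.params[f"block{i}/conv_w"],
                                self.params[f"block{i}/conv_b"], ca, sa, alpha)
            states.append(feat)
        cat = states[0] if len(states) == 1 else concat(states, axis=2)
        fused = conv2d(cat, self.params["fuse1/w"],
                       self.params["fuse1/b"]).leaky_relu(alpha)
        ic = conv2d(fused, self.params["fuse2/w"], self.params["fuse2/b"])
        return ic, fused

    # -- full forward ---------------------------------------------------------

    def forward(self, image: np.ndarray) -> dict:
        """Build the full differentiable graph for one slice.

        Returns a dict with tensors ``recon`` (padded size), ``probs``
        (cropped to input size) and arrays ``norm`` (normalized padded
        image), ``baseline``, plus the pad bookkeeping.
        """
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("expected a 2D image plane")
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        r, c = image.shape
        norm = _zscore(image)
        padded, pad = wv.pad_to_even(norm)
        baseline = wv.degraded_baseline(padded, self.config.downsample_factor)
        coeffs = wv.dwt2(baseline, wavelet=self.config.wavelet)
        i0 = self._shallow_t(Tensor(coeffs.as_array()))
        ic, fused = self._trunk_t(i0)
        recon = _IDWTOp.apply(ic, self.config.wavelet) + baseline
        logits = conv2d(fused, self.params["head/w"], self.params["head/b"])
        up = upsample2x(logits)
        probs = up.softmax(axis=2)
        return {"recon": recon, "probs_padded": probs, "ic": ic,
                "norm": padded, "baseline": baseline, "pad": pad,
                "shape": (r, c)}

    def segment(self, image: np.ndarray) -> SegmentationOutput:
        """Run the pipeline and return probabilities, labels and reconstruction."""
        out = self.forward(image)
        r, c = out["shape"]
        probs = out["probs_padded"].data[:r, :c, :]
        probs = probs / probs.sum(axis=2, keepdims=True)
        recon = out["recon"].data[:r, :c]
        return SegmentationOutput(
            reconstructed=recon,
            class_probs=probs,
            label_map=probs.argmax(axis=2).astype(np.int64),
        )

    # -- bookkeeping ----------------------------------------------------------

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def weight_tensors(self) -> list[Tensor]:
        """Convolution/MLP weights (no biases) — the L2-regularized set."""
        return [p for k, p in self.params.items()
                if k.endswith(("/w", "conv_w", "ca_w1", "ca_w2", "sa_k"))]

    def save(self, path) -> None:
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SSWAN":
        with np.load(path) as npz:
            cfg = NetworkConfig(**json.loads(bytes(npz["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = npz[k].astype(np.float64)
        return model


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int | None = None) -> np.ndarray:
    if fan_in is None:
        fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else max(shape[0], 1)
    if len(shape) == 0:
        return np.zeros(())
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def count_parameters(config: NetworkConfig) -> int:
    """Exact learnable-scalar count; strictly increasing in both T and w."""
    return SSWAN(config).count_parameters()
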