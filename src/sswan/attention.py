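"""Channel and spatial attention, and their composition into one SSAB.

The self-supervised attention block (SSAB) is the network's repeating unit:
a 3x3 same-padded convolution, a channel-attention gate, a spatial-attention
gate and a local additive skip. Channel attention squeezes the feature map
with global max- and average-pooling, pushes both pooled vectors through one
shared bottleneck MLP (hidden width w/h for reduction ratio h), sums them and
applies a sigmoid — a per-channel multiplicative gate in (0, 1). Spatial
attention pools along the channel axis instead, fuses the two resulting maps
with a 7x7 convolution and a sigmoid, and gates every channel by the same
2D map.

Public functions take plain NumPy (H, W, C) feature maps and parameter
dataclasses; the ``*_t`` functions operate on autodiff tensors and are what
the network's training graph is built from.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "channel_descriptor",
    "channel_attention",
    "spatial_descriptor",
    "spatial_attention",
    "ssab_block",
]


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class ChannelAttentionParams:
    """Shared two-layer MLP of the channel gate; biases initialize to zero."""

    w1: np.ndarray  # (w, w // h)
    b1: np.ndarray  # (w // h,)
    w2: np.ndarray  # (w // h, w)
    b2: np.ndarray  # (w,)

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        w, hidden = self.w1.shape
        if self.w2.shape != (hidden, w):
            raise ValueError("w2 must map the hidden width back to w")
        if self.b1.shape != (hidden,) or self.b2.shape != (w,):
            raise ValueError("bias shapes inconsistent with the MLP widths")

    @property
    def width(self) -> int:
        return self.w1.shape[0]

    @classmethod
    def initialize(cls, width: int, reduction: int,
                   rng: np.random.Generator) -> "ChannelAttentionParams":
        if width % reduction != 0:
            raise ValueError(f"width {width} not divisible by reduction {reduction}")
        hidden = width // reduction
        return cls(
            w1=kaiming_uniform(rng, (width, hidden), fan_in=width),
            b1=np.zeros(hidden),
            w2=kaiming_uniform(rng, (hidden, width), fan_in=hidden),
            b2=np.zeros(width),
        )


@dataclass
class SpatialAttentionParams:
    """7x7 fusion convolution of the spatial gate."""

    kernel: np.ndarray  # (7, 7, 2, 1)
    bias: float = 0.0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.shape != (7, 7, 2, 1):
            raise ValueError(
                f"spatial kernel must be (7, 7, 2, 1), got {self.kernel.shape}")
        self.bias = float(self.bias)

    @classmethod
    def initialize(cls, rng: np.random.Generator) -> "SpatialAttentionParams":
        return cls(kernel=kaiming_uniform(rng, (7, 7, 2, 1), fan_in=7 * 7 * 2),
                   bias=0.0)


# -- tensor-graph implementations -------------------------------------------


def _shared_mlp_t(pooled: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor,
                  alpha: float) -> Tensor:
    return (pooled @ w1 + b1).leaky_relu(alpha) @ w2 + b2


def channel_descriptor_t(feat: Tensor, w1: Tensor, b1: Tensor, w2: Tensor,
                         b2: Tensor, alpha: float = 0.2) -> Tensor:
    pmax = feat.spatial_max()
    pavg = feat.spatial_mean()
    m = _shared_mlp_t(pmax, w1, b1, w2, b2, alpha) + \
        _shared_mlp_t(pavg, w1, b1, w2, b2, alpha)
    return m.sigmoid()


def channel_attention_t(feat: Tensor, w1, b1, w2, b2, alpha: float = 0.2) -> Tensor:
    return feat * channel_descriptor_t(feat, w1, b1, w2, b2, alpha)


def spatial_descriptor_t(feat: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    stacked = concat([feat.channel_max(), feat.channel_mean()], axis=2)
    return conv2d(stacked, kernel, bias).sigmoid()


def spatial_attention_t(feat: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    return feat * spatial_descriptor_t(feat, kernel, bias)


def ssab_block_t(feat: Tensor, conv_w: Tensor, conv_b: Tensor,
                 ca: dict[str, Tensor], sa: dict[str, Tensor],
                 alpha: float = 0.2) -> Tensor:
    y = conv2d(feat, conv_w, conv_b)
    y = channel_attention_t(y, ca["w1"], ca["b1"], ca["w2"], ca["b2"], alpha)
    y = spatial_attention_t(y, sa["kernel"], sa["bias"])
    return y + feat


# -- NumPy-facing API --------------------------------------------------------


def _check_feat(feat: np.ndarray) -> np.ndarray:
    feat = np.asarray(feat, dtype=np.float64)
    if feat.ndim != 3 or feat.shape[2] < 1:
        raise ValueError("feature map must be (height, width, channels)")
    if not np.all(np.isfinite(feat)):
        raise ValueError("feature map contains non-finite values")
    return feat


def _ca_tensors(params: ChannelAttentionParams) -> tuple[Tensor, ...]:
    return (Tensor(params.w1), Tensor(params.b1),
            Tensor(params.w2), Tensor(params.b2))


def channel_descriptor(feat: np.ndarray, params: ChannelAttentionParams,
                       alpha: float = 0.2) -> np.ndarray:
    """Per-channel gate in (0,1)^w from globally pooled statistics."""
    feat = _check_feat(feat)
    if feat.shape[2] != params.width:
        raise ValueError(
            f"feature width {feat.shape[2]} != parameter width {params.width}")
    return channel_descriptor_t(Tensor(feat), *_ca_tensors(params), alpha).data


def channel_attention(feat: np.ndarray, params: ChannelAttentionParams,
                      alpha: float = 0.2) -> np.ndarray:
    """Each channel scaled by its descriptor entry; shape preserved."""
    return _check_feat(feat) * channel_descriptor(feat, params, alpha)


def spatial_descriptor(feat: np.ndarray,
                       params: SpatialAttentionParams) -> np.ndarray:
    """Per-position gate in (0,1) from channel-pooled maps, as (H, W)."""
    feat = _check_feat(feat)
    out = spatial_descriptor_t(Tensor(feat), Tensor(params.kernel),
                               Tensor(params.bias)).data
    return out[..., 0]


def spatial_attention(feat: np.ndarray,
                      params: SpatialAttentionParams) -> np.ndarray:
    """Every channel multiplied by the same 2D descriptor; shape preserved."""
    feat = _check_feat(feat)
    return feat * spatial_descriptor(feat, params)[..., None]


def ssab_block(feat: np.ndarray, conv_kernel: np.ndarray, conv_bias: np.ndarray,
               ch_params: ChannelAttentionParams,
               sp_params: SpatialAttentionParams,
               alpha: float = 0.2) -> np.ndarray:
    """One attention block: conv -> channel gate -> spatial gate -> + input."""
    feat = _check_feat(feat)
    conv_kernel = np.asarray(conv_kernel, dtype=np.float64)
    w = feat.shape[2]
    if conv_kernel.shape[2] != w or conv_kernel.shape[3] != w:
        raise ValueError("block convolution must preserve the feature width")
    if ch_params.width != w:
        raise ValueError("channel attention width mismatch")
    ca = dict(zip(("w1", "b1", "w2", "b2"), _ca_tensors(ch_params)))
    sa = {"kernel": Tensor(sp_params.kernel), "bias": Tensor(sp_params.bias)}
    return ssab_block_t(Tensor(feat), Tensor(conv_kernel), Tensor(conv_bias),
                        ca, sa, alpha).data


def identity_conv_kernel(width: int, size: int = 3) -> np.ndarray:
    """Kernel whose convolution is the identity map (center tap per channel)."""
    k = np.zeros((size, size, width, width))
    c = size // 2
    for i in range(width):
        k[c, c, i, i] = 1.0
    return k
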