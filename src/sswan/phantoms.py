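"""Synthetic 2D tumor phantoms with nested sub-regions.

Each phantom emulates the structure of an annotated brain-tumor MRI slice:
up to three concentric elliptical sub-regions — whole tumor (WT) containing
tumor core (TC) containing enhancing tumor (ET) — drawn on a smoothly
textured background with additive Gaussian noise. The nested regions share a
center and orientation with strictly shrinking semi-axes, so the label
nesting ET ⊆ TC ⊆ WT holds by construction for every seed.

The background texture is a sum of three low-frequency cosine gratings with
seeded random orientations and phases; it gives the wavelet frontend
nontrivial approximation and detail content without obscuring the regions.
Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]

_DEFAULT_MEANS = (0.2, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise settings for one phantom.

    ``num_classes`` counts the background, so L=2 draws only the WT ellipse
    and L=4 the full WT/TC/ET nesting. ``region_means`` are the per-class
    intensities (background first); defaults step from 0.2 up to 1.0.
    ``noise_sigma`` is the standard deviation of the i.i.d. Gaussian pixel
    noise and ``texture_scale`` the amplitude of the background gratings.
    """

    size: tuple[int, int] = (64, 64)
    num_classes: int = 2
    region_means: tuple | None = None
    noise_sigma: float = 0.05
    texture_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        r, c = self.size
        if r < 16 or c < 16 or r % 2 or c % 2:
            raise ValueError("size must be even and at least 16x16")
        if not 2 <= self.num_classes <= 4:
            raise ValueError("num_classes must be between 2 and 4")
        if self.region_means is not None and len(self.region_means) != self.num_classes:
            raise ValueError("need one region mean per class")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def means(self) -> np.ndarray:
        if self.region_means is not None:
            return np.asarray(self.region_means, dtype=np.float64)
        return np.asarray(_DEFAULT_MEANS[: self.num_classes], dtype=np.float64)


@dataclass
class PhantomSample:
    """Image, label map and the generation metadata that produced them."""

    image: np.ndarray            # (r, c) float intensities
    labels: np.ndarray           # (r, c) int in {0..L-1}
    meta: dict = field(default_factory=dict)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _ellipse_fits(shape, center, axes) -> bool:
    # conservative: bounding circle of the rotated ellipse inside the frame
    r = max(axes)
    return (center[0] - r >= 1 and center[0] + r <= shape[0] - 2
            and center[1] - r >= 1 and center[1] + r <= shape[1] - 2)


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Draw one phantom; deterministic for a given config (seed included)."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.size)
    short = min(shape)

    # Outer (whole tumor) ellipse; resample until it fits in the frame.
    for _ in range(200):
        center = (rng.uniform(0.30, 0.70) * shape[0],
                  rng.uniform(0.30, 0.70) * shape[1])
        axes = (rng.uniform(0.12, 0.28) * short, rng.uniform(0.12, 0.28) * short)
        theta = rng.uniform(0.0, np.pi)
        if _ellipse_fits(shape, center, axes):
            break
    else:  # pragma: no cover - the sampling box makes failure implausible
        raise RuntimeError("could not place the outer ellipse")

    ellipses = [{"center": center, "axes": axes, "theta": theta}]
    for _ in range(config.num_classes - 2):     # TC, then ET, concentric
        shrink = rng.uniform(0.5, 0.72)
        axes = (axes[0] * shrink, axes[1] * shrink)
        ellipses.append({"center": center, "axes": axes, "theta": theta})

    labels = np.zeros(shape, dtype=np.int64)
    for cls, e in enumerate(ellipses, start=1):
        labels[_ellipse_mask(shape, e["center"], e["axes"], e["theta"])] = cls

    image = config.means[labels]

    if config.texture_scale:
        rr, cc = np.mgrid[0: shape[0], 0: shape[1]].astype(np.float64)
        texture = np.zeros(shape)
        for _ in range(3):
            freq = rng.uniform(0.5, 2.0)
            ang = rng.uniform(0.0, np.pi)
            phase = rng.uniform(0.0, 2 * np.pi)
            kx = 2 * np.pi * freq * np.cos(ang) / shape[0]
            ky = 2 * np.pi * freq * np.sin(ang) / shape[1]
            texture += np.cos(kx * rr + ky * cc + phase)
        image = image + config.texture_scale / 3.0 * texture

    if config.noise_sigma:
        image = image + rng.normal(0.0, config.noise_sigma, size=shape)

    meta = asdict(config)
    meta["ellipses"] = [
        {"center": list(e["center"]), "axes": list(e["axes"]),
         "theta": float(e["theta"])} for e in ellipses
    ]
    return PhantomSample(image=image, labels=labels, meta=meta)


def generate_dataset(n: int, config: PhantomConfig,
                     base_seed: int | None = None) -> list[PhantomSample]:
    """n phantoms seeded ``base_seed .. base_seed+n-1`` (distinct geometries)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    from dataclasses import replace

    return [generate_phantom(replace(config, seed=base_seed + i))
            for i in range(n)]
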