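"""Readers and writers for volumes, slices, masks and phantom samples.

NIfTI-1/2 volumes go through nibabel with the affine passed through
untouched (no resampling — that belongs upstream). PNGs are treated as
single-slice volumes. Label masks round-trip losslessly as uint8; image
intensities round-trip within float32. Axis convention throughout is
0-based (row, col, slice).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantoms import PhantomSample

__all__ = ["VolumeHandle", "read_volume", "write_volume", "slice_iter",
           "write_mask", "read_mask", "save_sample", "load_sample",
           "write_manifest", "read_manifest"]


@dataclass
class VolumeHandle:
    """A 3D intensity array plus the spatial metadata needed to write it back."""

    data: np.ndarray                      # (rows, cols, slices)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (rows, cols, slices)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path) -> VolumeHandle:
    """Read a NIfTI volume or a PNG (as a single-slice volume)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        if _is_nifti(path):
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float64)
            if data.ndim == 2:
                data = data[..., None]
            if data.ndim != 3:
                raise ValueError(f"expected a 2D/3D volume, got ndim={data.ndim}")
            zooms = img.header.get_zooms()[:3]
            spacing = tuple(float(z) for z in zooms) if len(zooms) == 3 else (
                float(zooms[0]), float(zooms[1]), 1.0)
            return VolumeHandle(data=data, spacing=spacing, affine=img.affine)
        if path.suffix.lower() == ".png":
            arr = np.asarray(iio.imread(path)).astype(np.float64)
            if arr.ndim == 3:          # collapse RGB(A) to luminance
                arr = arr[..., :3].mean(axis=2)
            return VolumeHandle(data=arr[..., None])
    except (ValueError, OSError, nib.filebasedimages.ImageFileError) as exc:
        raise ValueError(f"could not read {path}: {exc}") from exc
    raise ValueError(f"unsupported image format: {path} "
                     "(expected .nii, .nii.gz or .png)")


def write_volume(data: np.ndarray, path, spacing=(1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> None:
    """Write a 3D array as NIfTI (float32), preserving spacing/affine."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("volume data must be 3D")
    if affine is None:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def slice_iter(volume: VolumeHandle, axis: int = 2):
    """Yield every 2D plane of the volume along ``axis`` (0, 1 or 2)."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    for i in range(volume.data.shape[axis]):
        yield np.take(volume.data, i, axis=axis)


def write_mask(labels: np.ndarray, path,
               reference: VolumeHandle | None = None) -> None:
    """Write an integer label map as uint8 NIfTI or PNG (lossless)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("label values must fit in uint8")
    labels = labels.astype(np.uint8)
    try:
        if _is_nifti(path):
            data = labels if labels.ndim == 3 else labels[..., None]
            affine = reference.affine if reference is not None and \
                reference.affine is not None else np.eye(4)
            nib.save(nib.Nifti1Image(data, affine), str(path))
        elif path.suffix.lower() == ".png":
            if labels.ndim != 2:
                raise ValueError("PNG masks must be 2D")
            iio.imwrite(path, labels)
        else:
            raise ValueError(f"unsupported mask format: {path.suffix}")
    except OSError as exc:
        raise ValueError(f"could not write mask to {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a label map written by :func:`write_mask` (exact values)."""
    path = Path(path)
    if _is_nifti(path):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        arr = np.squeeze(arr, axis=-1) if arr.ndim == 3 and arr.shape[-1] == 1 else arr
    elif path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")
    return arr.astype(np.int64)


# -- phantom sample serialization (PNG pair + JSON meta) ---------------------


def save_sample(sample: PhantomSample, out_dir, stem: str) -> dict:
    """Write image (8-bit rescaled PNG), labels (PNG) and metadata (JSON).

    The intensity range is recorded in the JSON so the image can be restored
    to its float range (up to 8-bit quantization).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmin, vmax = float(sample.image.min()), float(sample.image.max())
    scale = (vmax - vmin) or 1.0
    img8 = np.round((sample.image - vmin) / scale * 255).astype(np.uint8)
    iio.imwrite(out_dir / f"{stem}_image.png", img8)
    write_mask(sample.labels, out_dir / f"{stem}_labels.png")
    meta = dict(sample.meta, intensity_min=vmin, intensity_max=vmax)
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))
    return {"stem": stem, "image": f"{stem}_image.png",
            "labels": f"{stem}_labels.png", "meta": f"{stem}_meta.json"}


def load_sample(data_dir, stem: str) -> PhantomSample:
    data_dir = Path(data_dir)
    meta = json.loads((data_dir / f"{stem}_meta.json").read_text())
    img8 = np.asarray(iio.imread(data_dir / f"{stem}_image.png"), dtype=np.float64)
    vmin, vmax = meta["intensity_min"], meta["intensity_max"]
    image = img8 / 255.0 * ((vmax - vmin) or 1.0) + vmin
    labels = read_mask(data_dir / f"{stem}_labels.png")
    return PhantomSample(image=image, labels=labels, meta=meta)


def write_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["stem", "image", "labels", "meta"])
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
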