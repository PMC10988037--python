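"""CT preprocessing for vessel segmentation.

The chain applied before the network sees a volume:

1. clip intensities to the liver window (0–400 HU),
2. resample to an isotropic 1 mm grid (cubic spline for intensities,
   nearest-neighbour for labels so masks stay binary),
3. z-score normalise to zero mean / unit variance (per volume).

Normalisation runs after resampling so the statistics describe the grid the
network is actually trained on.  A liver region of interest is built by
dilating a liver label outward by a physical margin (20 mm default) per
axis with a box structuring element, then cropping image and label to the
ROI's bounding box.  The only augmentations are axis flips, applied jointly
to image and label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import CTVolume, MaskVolume

__all__ = [
    "PreprocessConfig",
    "clip_hu",
    "normalize_zscore",
    "resample_isotropic",
    "build_liver_roi",
    "crop_to_roi",
    "reinsert",
    "augment_flip",
    "preprocess_volume",
]

DEFAULT_HU_WINDOW = (0.0, 400.0)
DEFAULT_TARGET_SPACING = (1.0, 1.0, 1.0)
DEFAULT_MASK_MARGIN_MM = 20.0


@dataclass(frozen=True)
class PreprocessConfig:
    hu_window: tuple = DEFAULT_HU_WINDOW
    target_spacing: tuple = DEFAULT_TARGET_SPACING
    mask_margin_mm: float = DEFAULT_MASK_MARGIN_MM
    augmentation_axes: tuple = (0, 1, 2)

    def __post_init__(self) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"hu_window low must be < high, got {self.hu_window}")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be strictly positive")
        if self.mask_margin_mm < 0:
            raise ValueError("mask_margin_mm must be >= 0")


def clip_hu(volume: CTVolume, window: tuple = DEFAULT_HU_WINDOW) -> CTVolume:
    """Clamp every voxel into [low, high] HU; idempotent, grid unchanged."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window low must be < high, got {window}")
    return CTVolume(np.clip(volume.voxels, lo, hi), volume.spacing)


def normalize_zscore(volume: CTVolume) -> CTVolume:
    """Standardise to zero mean and unit variance over all voxels."""
    v = np.asarray(volume.voxels, dtype=np.float64)
    if v.size < 2:
        raise ValueError("z-score normalisation needs more than one voxel")
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant volume: zero variance")
    return CTVolume(((v - v.mean()) / sd).astype(np.float32), volume.spacing)


def resample_isotropic(volume, target_spacing: tuple = DEFAULT_TARGET_SPACING):
    """Resample to ``target_spacing``; output shape = round(shape·spacing/target).

    Intensity volumes are interpolated with an order-3 spline, masks with
    nearest neighbour so the output stays binary.  Returns the same kind of
    volume that was passed in.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be > 0, got {target}")
    zoom = [s / t for s, t in zip(volume.spacing, target)]
    is_mask = isinstance(volume, MaskVolume)
    order = 0 if is_mask else 3
    data = volume.voxels.astype(np.uint8 if is_mask else np.float32)
    out = ndimage.zoom(data, zoom, order=order, mode="grid-constant", grid_mode=True)
    if is_mask:
        return MaskVolume(out.astype(np.uint8), target)
    return CTVolume(out, target)


def build_liver_roi(liver_label: MaskVolume, margin_mm: float = DEFAULT_MASK_MARGIN_MM) -> MaskVolume:
    """Dilate a liver label outward by ``margin_mm`` along each axis.

    The margin is converted to voxels per axis via the grid spacing and the
    dilation uses a box structuring element, i.e. the label grows by the
    same physical distance in each dimension.  A ball element is available
    via :func:`build_liver_roi_ball` but the box is the default.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    lab = liver_label.voxels.astype(bool)
    if not lab.any():
        raise ValueError("liver label is empty")
    radii = [int(round(margin_mm / s)) for s in liver_label.spacing]
    if all(r == 0 for r in radii):
        return liver_label.copy()
    # box dilation = separable running maximum per axis
    out = ndimage.maximum_filter(
        lab.astype(np.uint8), size=[2 * r + 1 for r in radii],
        mode="constant", cval=0,
    )
    return MaskVolume(out.astype(np.uint8), liver_label.spacing)


def build_liver_roi_ball(liver_label: MaskVolume, margin_mm: float = DEFAULT_MASK_MARGIN_MM) -> MaskVolume:
    """Ellipsoidal (physical-ball) variant of :func:`build_liver_roi`."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    lab = liver_label.voxels.astype(bool)
    if not lab.any():
        raise ValueError("liver label is empty")
    if margin_mm == 0:
        return liver_label.copy()
    radii = [max(int(round(margin_mm / s)), 0) for s in liver_label.spacing]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(radii, liver_label.spacing)],
        indexing="ij",
    )
    ball = sum(g**2 for g in grids) <= margin_mm**2
    out = ndimage.binary_dilation(lab, structure=ball)
    return MaskVolume(out.astype(np.uint8), liver_label.spacing)


def crop_to_roi(volume, roi: MaskVolume):
    """Crop to the tight bounding box of ``roi``; returns (cropped, offset)."""
    r = roi.voxels.astype(bool)
    if not r.any():
        raise ValueError("ROI is empty")
    if r.shape != volume.shape:
        raise ValueError(f"grid mismatch: volume {volume.shape} vs roi {r.shape}")
    nz = np.nonzero(r)
    lo = tuple(int(idx.min()) for idx in nz)
    hi = tuple(int(idx.max()) + 1 for idx in nz)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    cropped = type(volume)(volume.voxels[sl].copy(), volume.spacing)
    return cropped, lo


def reinsert(cropped, offset: tuple, full_shape: tuple, fill=0):
    """Place a cropped volume back at ``offset`` inside a ``full_shape`` grid."""
    out = np.full(full_shape, fill, dtype=cropped.voxels.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, cropped.shape))
    out[sl] = cropped.voxels
    return type(cropped)(out, cropped.spacing)


def augment_flip(image: CTVolume, label: MaskVolume, axes=(0, 1, 2), rng=None):
    """Randomly flip image and label jointly along each eligible axis."""
    if image.shape != label.shape:
        raise ValueError("image and label must share a grid")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    img, lab = image.voxels, label.voxels
    for ax in axes:
        if rng.random() < 0.5:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)
    return CTVolume(img.copy(), image.spacing), MaskVolume(lab.copy(), label.spacing)


def preprocess_volume(image: CTVolume, label: MaskVolume | None = None,
                      config: PreprocessConfig = PreprocessConfig()):
    """Full chain clip → resample → normalise; label resampled alongside."""
    img = clip_hu(image, config.hu_window)
    img = resample_isotropic(img, config.target_spacing)
    img = normalize_zscore(img)
    if label is None:
        return img, None
    lab = resample_isotropic(label, config.target_spacing)
    if lab.shape != img.shape:
        raise RuntimeError("image/label grids diverged during resampling")
    return img, lab
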