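"""Voxel-grid containers shared by every stage of the pipeline.

A volume is a plain numpy array on a regular 3-D grid plus per-axis voxel
spacing in millimetres.  Images carry CT intensities in Hounsfield units
(HU); masks are strictly binary; probability volumes hold the two-class
softmax output (foreground ``p0``, background ``p1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "MaskVolume",
    "ProbabilityVolume",
    "read_nifti_image",
    "read_nifti_mask",
    "write_nifti",
]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D scalar intensity field (HU) with per-axis spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing)


@dataclass
class MaskVolume:
    """A binary label field (1 = vessel foreground) on the same grid as its image."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask voxels must be 0 or 1")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.voxels.mean())

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.voxels.copy(), self.spacing)


@dataclass
class ProbabilityVolume:
    """Two-class per-voxel probabilities: p0 (foreground) + p1 (background) = 1."""

    p0: np.ndarray
    p1: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=np.float32)
        self.p1 = np.asarray(self.p1, dtype=np.float32)
        if self.p0.shape != self.p1.shape:
            raise ValueError("p0 and p1 must share a grid")
        self.spacing = _check_spacing(self.spacing)
        s = self.p0 + self.p1
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("p0 + p1 must equal 1 per voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.p0.shape

    def argmax_mask(self) -> MaskVolume:
        return MaskVolume((self.p0 > self.p1).astype(np.uint8), self.spacing)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(volume: CTVolume | MaskVolume, path: str) -> None:
    """Write a volume as NIfTI with spacing stored in the header zooms."""
    data = volume.voxels
    img = nib.Nifti1Image(data, _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def _load(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    # dataobj preserves the on-disk dtype; get_fdata would silently cast to float64
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_nifti_image(path: str) -> CTVolume:
    data, spacing = _load(path)
    return CTVolume(data, spacing)


def read_nifti_mask(path: str) -> MaskVolume:
    data, spacing = _load(path)
    return MaskVolume(data.astype(np.uint8), spacing)
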