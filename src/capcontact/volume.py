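"""Voxel-grid containers for segmentation masks and intensity volumes.

All world coordinates are in millimetres. Voxel indices are 0-based and the
world position of voxel ``(i, j, k)`` is ``origin + index * spacing`` (voxel
*centers*, RAS axis order). Anisotropic spacing is carried everywhere; masks
are never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["SegmentationVolume", "IntensityVolume", "load_segmentation",
           "load_intensity", "save_volume"]


def _validate_spacing(spacing: np.ndarray) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise ValueError(f"spacing must be a 3-vector, got shape {spacing.shape}")
    if not np.all(spacing > 0):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class SegmentationVolume:
    """A 3D binary mask on an anisotropic voxel grid.

    Parameters
    ----------
    voxels : ndarray of bool, shape (nx, ny, nz)
        The mask. Axis order follows RAS: the last axis is
        superior-inferior, so an axial slice is ``voxels[:, :, k]``.
    spacing_mm : array-like of 3 floats
        Edge length of a voxel along each axis, in mm.
    origin_mm : array-like of 3 floats
        World position of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.voxels.dtype != bool:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all():
                bad = vals[~np.isin(vals, (0, 1))]
                raise ValueError(f"mask values must be in {{0,1}}; found {bad[:5]}")
            self.voxels = self.voxels.astype(bool)
        self.spacing_mm = _validate_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates (n, 3) of the centers of all foreground voxels."""
        idx = np.argwhere(self.voxels)
        return self.origin_mm + idx * self.spacing_mm

    def same_grid(self, other: "SegmentationVolume | IntensityVolume") -> bool:
        return (self.shape == other.data_array().shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def data_array(self) -> np.ndarray:
        return self.voxels


@dataclass
class IntensityVolume:
    """A scalar intensity volume (e.g. an ADC map, 1e-6 mm^2/s) on a voxel grid."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("intensity volume must be 3D")
        self.spacing_mm = _validate_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def data_array(self) -> np.ndarray:
        return self.values


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(vol: SegmentationVolume | IntensityVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (RAS, spacing in the affine)."""
    data = vol.data_array()
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # reorient to RAS
    data = np.asarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return data, spacing, origin


def load_segmentation(path: str | Path) -> SegmentationVolume:
    """Load and validate a binary segmentation mask from a NIfTI file.

    Raises ``ValueError`` for non-binary values or non-positive spacing.
    """
    data, spacing, origin = _load_nifti(path)
    return SegmentationVolume(data, spacing, origin)


def load_intensity(path: str | Path) -> IntensityVolume:
    data, spacing, origin = _load_nifti(path)
    return IntensityVolume(data, spacing, origin)


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Validate that two volumes live on an identical grid (never resample)."""
    if a.data_array().shape != b.data_array().shape:
        raise ValueError(
            f"{what} have mismatched grid shapes "
            f"{a.data_array().shape} vs {b.data_array().shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise ValueError(f"{what} have mismatched spacing "
                         f"{a.spacing_mm} vs {b.spacing_mm}")
    if not np.allclose(a.origin_mm, b.origin_mm):
        raise ValueError(f"{what} have mismatched origins")
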