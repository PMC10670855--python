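"""Shared phantom builders and fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from capcontact.volume import SegmentationVolume


def make_cuboid(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> SegmentationVolume:
    """Axis-aligned solid cuboid occupying voxel slices lo[i]:hi[i]."""
    m = np.zeros(shape, bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return SegmentationVolume(m, spacing)


def make_sphere(shape, center_vox, radius_mm, spacing=(1.0, 1.0, 1.0)
                ) -> SegmentationVolume:
    """Solid sphere of ``radius_mm`` centered on a voxel center."""
    spacing = np.asarray(spacing, float)
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    c = np.asarray(center_vox, float) * spacing
    r2 = sum((g - mu) ** 2 for g, mu in zip(coords, c))
    return SegmentationVolume(r2 <= radius_mm ** 2, spacing)


def make_cylinder(shape, center_xy_vox, radius_mm, spacing=(1.0, 1.0, 1.0)
                  ) -> SegmentationVolume:
    """Solid cylinder extruded along the axial (last) axis."""
    spacing = np.asarray(spacing, float)
    x = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    cx, cy = np.asarray(center_xy_vox, float) * spacing[:2]
    disc = ((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) <= radius_mm ** 2
    m = np.repeat(disc[:, :, None], shape[2], axis=2)
    return SegmentationVolume(m, spacing)


def random_phantom_pair(rng: np.random.Generator, max_grid: int = 32):
    """Random ellipsoidal prostate + spherical lesion at random capsule depth.

    Grids stay at or below ``max_grid`` per axis so the O(N^2) oracle is fast.
    The lesion is pushed laterally (in-plane) so contact, when present, sits
    on the in-plane capsule contour.
    """
    shape = tuple(int(rng.integers(24, max_grid + 1)) for _ in range(3))
    spacing = rng.choice([0.8, 1.0, 1.5, 2.0], size=3)
    radii_vox = np.array([rng.uniform(0.28, 0.40) * n for n in shape])
    radii_mm = radii_vox * spacing
    center = (np.asarray(shape) - 1) / 2 * spacing
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    rho2 = sum(((g - mu) / r) ** 2 for g, mu, r in
               zip(coords, center, radii_mm))
    prostate = SegmentationVolume(rho2 <= 1.0, spacing)

    lesion_r = rng.uniform(0.25, 0.5) * radii_mm.min()
    depth = rng.uniform(0.0, 0.35) * radii_mm.min()
    phi = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    # place along the in-plane direction at the requested depth below capsule
    r_capsule = 1.0 / np.sqrt(sum((direction[i] / radii_mm[i]) ** 2
                                  for i in range(3)))
    c = center + direction * max(r_capsule - depth - lesion_r, 0.0)
    r2 = sum((g - mu) ** 2 for g, mu in zip(coords, c))
    lesion_mask = (r2 <= lesion_r ** 2) & prostate.voxels
    if not lesion_mask.any():
        idx = np.unravel_index(np.argmin(r2 + np.where(prostate.voxels, 0, 1e9)),
                               shape)
        lesion_mask = np.zeros(shape, bool)
        lesion_mask[idx] = True
    lesion = SegmentationVolume(lesion_mask, spacing)
    return prostate, lesion


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
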