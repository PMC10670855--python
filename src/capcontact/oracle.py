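"""Brute-force reference implementations of the contact geometry.

Every quantity here is computed by explicit O(N^2) pairwise Euclidean
distances (``scipy.spatial.distance.cdist``) with no spatial indexing, so
the code is short enough to verify by inspection. The fast implementations
in :mod:`capcontact.geometry` are tested against these on randomized
phantoms; the synthetic-cohort generator also uses them to produce ground
truth so that truth never flows through the code under test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .volume import SegmentationVolume

__all__ = [
    "oracle_surface_elements", "oracle_distance_map", "oracle_tcsa",
    "oracle_tcv", "oracle_tcl", "oracle_lesion_truth",
]


def _shift(mask: np.ndarray, axis: int, sign: int) -> np.ndarray:
    """Neighbour occupancy along an axis; outside the grid counts as background."""
    padded = np.pad(mask, 1)
    rolled = np.roll(padded, -sign, axis=axis)
    sl = tuple(slice(1, -1) for _ in range(3))
    return rolled[sl]


def oracle_surface_elements(vol: SegmentationVolume):
    """Exposed voxel faces: (positions (n,3) mm, areas (n,), normal axes (n,),
    slice indices (n,))."""
    mask = vol.voxels
    spacing, origin = vol.spacing_mm, vol.origin_mm
    pos, area, ax, sl = [], [], [], []
    for axis in range(3):
        other = [a for a in range(3) if a != axis]
        a_face = spacing[other[0]] * spacing[other[1]]
        for sign in (-1, 1):
            exposed = mask & ~_shift(mask, axis, sign)
            for idx in np.argwhere(exposed):
                p = origin + idx * spacing
                p[axis] += sign * 0.5 * spacing[axis]
                pos.append(p)
                area.append(a_face)
                ax.append(axis)
                sl.append(idx[2])
    return (np.asarray(pos, float), np.asarray(area, float),
            np.asarray(ax, int), np.asarray(sl, int))


def _surface_voxel_centers(vol: SegmentationVolume) -> np.ndarray:
    mask = vol.voxels
    interior = np.ones_like(mask)
    for axis in range(3):
        for sign in (-1, 1):
            interior &= _shift(mask, axis, sign)
    surf = mask & ~interior
    return vol.origin_mm + np.argwhere(surf) * vol.spacing_mm


def oracle_distance_map(shape, spacing_mm, element_positions,
                        origin_mm=None) -> np.ndarray:
    spacing = np.asarray(spacing_mm, float)
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, float)
    idx = np.indices(shape).reshape(3, -1).T
    centers = origin + idx * spacing
    # chunked to bound the pairwise matrix size
    out = np.empty(len(centers))
    for i in range(0, len(centers), 4096):
        out[i:i + 4096] = cdist(centers[i:i + 4096], element_positions).min(axis=1)
    return out.reshape(shape)


def oracle_tcsa(lesion: SegmentationVolume, prostate: SegmentationVolume,
                d_mm: float) -> float:
    pos, area, _, _ = oracle_surface_elements(prostate)
    surf = _surface_voxel_centers(lesion)
    dmin = cdist(pos, surf).min(axis=1)
    return float(area[dmin <= d_mm].sum())


def oracle_tcv(lesion: SegmentationVolume, prostate: SegmentationVolume,
               d_mm: float) -> float:
    pos, _, _, _ = oracle_surface_elements(prostate)
    centers = lesion.voxel_centers_mm()
    dmin = cdist(centers, pos).min(axis=1)
    return float((dmin <= d_mm).sum() * lesion.voxel_volume_mm3)


def oracle_tcl(lesion: SegmentationVolume, prostate: SegmentationVolume,
               threshold_mm: float = 1.0) -> float:
    pos, _, ax, sl = oracle_surface_elements(prostate)
    surf = _surface_voxel_centers(lesion)
    dmin = cdist(pos, surf).min(axis=1)
    spacing = prostate.spacing_mm
    best = 0.0
    for k in np.unique(sl):
        sel = (sl == k) & (ax != 2) & (dmin <= threshold_mm)
        step = np.where(ax[sel] == 0, spacing[1], spacing[0])
        best = max(best, float(step.sum()))
    return best


def oracle_lesion_truth(prostate: SegmentationVolume,
                        lesion: SegmentationVolume,
                        distances_mm=(1.0, 2.0, 3.0, 4.0, 5.0),
                        tcl_threshold_mm: float = 1.0) -> dict:
    """All geometric ground-truth features of one synthetic lesion."""
    pos, area, ax, sl = oracle_surface_elements(prostate)
    surf = _surface_voxel_centers(lesion)
    elem_d = cdist(pos, surf).min(axis=1)
    centers = lesion.voxel_centers_mm()
    les_d = cdist(centers, pos).min(axis=1)
    spacing = prostate.spacing_mm

    truth: dict = {}
    for d in distances_mm:
        truth[f"true_tcsa_{d:g}mm_mm2"] = float(area[elem_d <= d].sum())
        truth[f"true_tcv_{d:g}mm_mm3"] = float(
            (les_d <= d).sum() * lesion.voxel_volume_mm3)
    best = 0.0
    contact = elem_d <= tcl_threshold_mm
    for k in np.unique(sl):
        sel = (sl == k) & (ax != 2) & contact
        step = np.where(ax[sel] == 0, spacing[1], spacing[0])
        best = max(best, float(step.sum()))
    truth["true_tcl_mm"] = best
    truth["true_volume_mm3"] = lesion.volume_mm3()
    diff = surf[:, None, :] - surf[None, :, :]
    truth["true_diameter_mm"] = float(np.sqrt((diff ** 2).sum(-1)).max()) \
        if len(surf) > 1 else 0.0
    return truth
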