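"""Capsule-contact geometry: the novel radiomic features.

The prostate capsule is modelled as the set of exposed voxel faces of the
prostate mask (a face is exposed when its 6-neighbour is background). This
surface model is exact for axis-aligned phantoms and admits a trivially
correct brute-force oracle; the known face-counting overestimate for oblique
surfaces is bounded in the test suite.

Features
--------
TCL
    Tumor contact length: per axial slice, the summed in-plane extent of
    capsule contour faces lying within a contact threshold (default 1 mm)
    of the lesion surface; the reported value is the maximum over slices,
    matching the conventional axial measurement. Purely apical/basal
    ("polar") contact does not register in axial TCL — exactly the blind
    spot of the conventional measurement that motivates the 3D features.
tcl3d
    Maximum 3D Euclidean extent (Feret diameter) of the capsule contact
    patch; a 3D alternative to the axial convention.
TCSA(d)
    Tumor contact surface area: total area of capsule faces whose Euclidean
    distance to the nearest lesion surface voxel center is <= d mm.
TCV(d)
    Tumor contact volume: volume of lesion voxels whose center lies within
    d mm of the capsule.

All distances are voxel-center-to-face-center, spacing-aware (never
computed on a resampled grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, ConvexHull

from .volume import SegmentationVolume, IntensityVolume, require_same_grid

__all__ = [
    "CapsuleSurface", "LesionFeatureVector", "extract_capsule_surface",
    "capsule_distance_map", "tumor_contact_length", "contact_surface_area",
    "contact_volume", "lesion_shape_features", "adc_statistics",
    "extract_feature_vector", "CONTACT_DISTANCES_MM",
]

CONTACT_DISTANCES_MM = (1.0, 2.0, 3.0, 4.0, 5.0)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class CapsuleSurface:
    """Prostate boundary as discrete surface elements (exposed voxel faces).

    ``positions_mm``: face-center world coordinates, shape (n, 3).
    ``areas_mm2``: face areas (product of the two in-plane spacings).
    ``normal_axes``: axis index (0, 1, 2) of each face normal.
    ``slice_index``: the axial (last-axis) voxel index of the owning voxel.
    """

    positions_mm: np.ndarray
    areas_mm2: np.ndarray
    normal_axes: np.ndarray
    slice_index: np.ndarray
    spacing_mm: np.ndarray

    @property
    def n_elements(self) -> int:
        return len(self.areas_mm2)

    @property
    def total_area_mm2(self) -> float:
        return float(self.areas_mm2.sum())


def _count_components(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask, structure=_STRUCT6)
    return n


def extract_capsule_surface(prostate: SegmentationVolume) -> CapsuleSurface:
    """Exposed-face surface of a prostate mask.

    Raises ``ValueError`` on an empty mask or one with more than one
    6-connected component.
    """
    mask = prostate.voxels
    if not mask.any():
        raise ValueError("cannot extract a capsule from an empty prostate mask")
    n_comp = _count_components(mask)
    if n_comp != 1:
        raise ValueError(
            f"prostate mask must be a single connected component, found {n_comp}")

    spacing = prostate.spacing_mm
    positions, areas, axes, slices = [], [], [], []
    for axis in range(3):
        in_plane = [a for a in range(3) if a != axis]
        face_area = spacing[in_plane[0]] * spacing[in_plane[1]]
        for sign in (-1, 1):
            # neighbour along `axis` in direction `sign` is background/outside
            sl_src = [slice(None)] * 3
            sl_dst = [slice(None)] * 3
            if sign == 1:
                sl_src[axis] = slice(1, None)
                sl_dst[axis] = slice(None, -1)
            else:
                sl_src[axis] = slice(None, -1)
                sl_dst[axis] = slice(1, None)
            neighbour = np.zeros_like(mask)
            neighbour[tuple(sl_dst)] = mask[tuple(sl_src)]
            exposed = mask & ~neighbour
            idx = np.argwhere(exposed)
            if idx.size == 0:
                continue
            pos = prostate.origin_mm + idx * spacing
            pos[:, axis] += sign * 0.5 * spacing[axis]
            positions.append(pos)
            areas.append(np.full(len(idx), face_area))
            axes.append(np.full(len(idx), axis, dtype=np.int8))
            slices.append(idx[:, 2].astype(np.int32))
    return CapsuleSurface(
        positions_mm=np.concatenate(positions),
        areas_mm2=np.concatenate(areas),
        normal_axes=np.concatenate(axes),
        slice_index=np.concatenate(slices),
        spacing_mm=spacing.copy(),
    )


def capsule_distance_map(volume_shape: tuple[int, int, int],
                         spacing_mm: np.ndarray,
                         capsule: CapsuleSurface,
                         origin_mm: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest capsule element."""
    if capsule.n_elements == 0:
        raise ValueError("capsule has no surface elements")
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, float)
    grids = np.meshgrid(*[origin[a] + np.arange(volume_shape[a]) * spacing[a]
                          for a in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    tree = cKDTree(capsule.positions_mm)
    d, _ = tree.query(pts, workers=-1)
    return d.reshape(volume_shape)


def _surface_voxel_centers(mask_vol: SegmentationVolume) -> np.ndarray:
    """Centers of foreground voxels that have at least one 6-neighbour background."""
    mask = mask_vol.voxels
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    surf = mask & ~eroded
    idx = np.argwhere(surf)
    return mask_vol.origin_mm + idx * mask_vol.spacing_mm


def _element_lesion_distances(lesion: SegmentationVolume,
                              capsule: CapsuleSurface) -> np.ndarray:
    """Distance from each capsule element to the nearest lesion surface voxel center."""
    if not lesion.voxels.any():
        raise ValueError("lesion mask is empty")
    surf = _surface_voxel_centers(lesion)
    tree = cKDTree(surf)
    d, _ = tree.query(capsule.positions_mm, workers=-1)
    return d


def tumor_contact_length(lesion: SegmentationVolume,
                         capsule: CapsuleSurface,
                         contact_threshold_mm: float = 1.0,
                         element_distances: np.ndarray | None = None) -> float:
    """Axial tumor contact length (mm): max over slices of the in-plane
    contour length of capsule faces within ``contact_threshold_mm`` of the
    lesion surface. Each in-plane face contributes the in-plane step
    perpendicular to its normal; faces with axial normals are part of the
    apical/basal surface, not the axial contour, and are excluded."""
    if element_distances is None:
        element_distances = _element_lesion_distances(lesion, capsule)
    in_plane = capsule.normal_axes != 2
    contact = in_plane & (element_distances <= contact_threshold_mm)
    if not contact.any():
        return 0.0
    # x-normal faces run along y (length dy); y-normal faces run along x (dx)
    step = np.where(capsule.normal_axes[contact] == 0,
                    capsule.spacing_mm[1], capsule.spacing_mm[0])
    lengths = np.bincount(capsule.slice_index[contact],
                          weights=step)
    return float(lengths.max())


def contact_patch_extent(lesion: SegmentationVolume,
                         capsule: CapsuleSurface,
                         contact_threshold_mm: float = 1.0,
                         element_distances: np.ndarray | None = None) -> float:
    """3D TCL variant: maximum Euclidean extent (mm) of the contact patch."""
    if element_distances is None:
        element_distances = _element_lesion_distances(lesion, capsule)
    pts = capsule.positions_mm[element_distances <= contact_threshold_mm]
    return _max_pairwise_distance(pts)


def contact_surface_area(lesion: SegmentationVolume,
                         capsule: CapsuleSurface,
                         d_mm: float,
                         element_distances: np.ndarray | None = None) -> float:
    """TCSA(d): total area (mm^2) of capsule elements within ``d_mm`` of the lesion."""
    if d_mm <= 0:
        raise ValueError(f"contact distance must be positive, got {d_mm}")
    if element_distances is None:
        element_distances = _element_lesion_distances(lesion, capsule)
    return float(capsule.areas_mm2[element_distances <= d_mm].sum())


def contact_volume(lesion: SegmentationVolume,
                   capsule: CapsuleSurface,
                   d_mm: float,
                   lesion_capsule_distances: np.ndarray | None = None) -> float:
    """TCV(d): volume (mm^3) of lesion voxels with center within ``d_mm`` of the capsule."""
    if d_mm <= 0:
        raise ValueError(f"contact distance must be positive, got {d_mm}")
    if lesion_capsule_distances is None:
        pts = lesion.voxel_centers_mm()
        tree = cKDTree(capsule.positions_mm)
        lesion_capsule_distances, _ = tree.query(pts, workers=-1)
    n = int((lesion_capsule_distances <= d_mm).sum())
    return n * lesion.voxel_volume_mm3


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    # hull vertices suffice for the diameter; fall back to all points for
    # degenerate (coplanar/collinear) sets
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def lesion_shape_features(lesion: SegmentationVolume) -> tuple[float, float]:
    """Lesion volume (mm^3) and 3D Feret diameter (mm).

    The diameter is the maximum pairwise distance between lesion surface
    voxel centers. Raises if the lesion is empty or disconnected.
    """
    if not lesion.voxels.any():
        raise ValueError("lesion mask is empty")
    n_comp = _count_components(lesion.voxels)
    if n_comp != 1:
        raise ValueError(
            f"lesion must be a single connected component, found {n_comp}")
    volume = lesion.volume_mm3()
    surf = _surface_voxel_centers(lesion)
    return volume, _max_pairwise_distance(surf)


def adc_statistics(adc: IntensityVolume,
                   lesion: SegmentationVolume) -> tuple[float, float, float, float]:
    """(mean, median, 10th percentile, min) of ADC over lesion voxels.

    The percentile uses the linear-interpolation convention
    (numpy's default), so 100 voxels valued 1..100 give p10 = 10.9.
    """
    require_same_grid(adc, lesion, "ADC map and lesion mask")
    vals = adc.values[lesion.voxels]
    if vals.size == 0:
        raise ValueError("lesion mask is empty")
    return (float(vals.mean()), float(np.median(vals)),
            float(np.percentile(vals, 10)), float(vals.min()))


@dataclass
class LesionFeatureVector:
    """All per-lesion features with identifiers and the EPE outcome label.

    Geometric lengths in mm, areas in mm^2, volumes in mm^3; ADC statistics
    in 1e-6 mm^2/s (NaN when no ADC map was supplied); PSA in ng/mL.
    """

    patient_id: str
    lesion_id: str
    tcl_mm: float
    tcl3d_mm: float
    tcsa_mm2: dict[float, float]
    tcv_mm3: dict[float, float]
    lesion_volume_mm3: float
    lesion_diameter_mm: float
    adc_mean: float = np.nan
    adc_median: float = np.nan
    adc_p10: float = np.nan
    adc_min: float = np.nan
    psa_ng_ml: float = np.nan
    isup_grade: int | None = None
    location: str | None = None
    epe_label: int | None = None
    reader_call: int | None = None
    adc_available: bool = True

    def to_dict(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "lesion_id": self.lesion_id,
            "psa_ng_ml": self.psa_ng_ml,
            "isup_grade": self.isup_grade,
            "location": self.location,
            "lesion_diameter_mm": self.lesion_diameter_mm,
            "lesion_volume_mm3": self.lesion_volume_mm3,
            "adc_mean": self.adc_mean,
            "adc_median": self.adc_median,
            "adc_p10": self.adc_p10,
            "adc_min": self.adc_min,
            "tcl_mm": self.tcl_mm,
            "tcl3d_mm": self.tcl3d_mm,
        }
        for d in sorted(self.tcsa_mm2):
            row[f"tcsa_{d:g}mm_mm2"] = self.tcsa_mm2[d]
        for d in sorted(self.tcv_mm3):
            row[f"tcv_{d:g}mm_mm3"] = self.tcv_mm3[d]
        row["epe_label"] = self.epe_label
        row["reader_call"] = self.reader_call
        return row


# canonical feature ordering: clinical, then conventional, then novel
# geometric — this order drives correlation-filter tie-breaking
CLINICAL_FEATURES = ["psa_ng_ml", "isup_grade", "location"]
CONVENTIONAL_FEATURES = ["lesion_diameter_mm", "lesion_volume_mm3",
                         "adc_mean", "adc_median", "adc_p10", "adc_min"]
GEOMETRIC_CONTACT_FEATURES = (
    ["tcl_mm", "tcl3d_mm"]
    + [f"tcsa_{d:g}mm_mm2" for d in CONTACT_DISTANCES_MM]
    + [f"tcv_{d:g}mm_mm3" for d in CONTACT_DISTANCES_MM])
FEATURE_ORDER = CLINICAL_FEATURES + CONVENTIONAL_FEATURES + GEOMETRIC_CONTACT_FEATURES
# features scaled in the +/-5% geometric robustness analysis
GEOMETRIC_FEATURES = ["lesion_diameter_mm", "lesion_volume_mm3"] + GEOMETRIC_CONTACT_FEATURES


def extract_feature_vector(prostate: SegmentationVolume,
                           lesion: SegmentationVolume,
                           adc: IntensityVolume | None = None,
                           clinical_row: dict | None = None,
                           capsule: CapsuleSurface | None = None,
                           tcl_threshold_mm: float = 1.0,
                           contact_distances_mm=CONTACT_DISTANCES_MM,
                           ) -> LesionFeatureVector:
    """Assemble the full per-lesion feature vector.

    ``capsule`` may be precomputed (one prostate serves several lesions).
    A missing ADC volume leaves the ADC statistics as NaN with
    ``adc_available=False``; geometric features are always computed.
    """
    require_same_grid(prostate, lesion, "prostate and lesion masks")
    if not (prostate.voxels & lesion.voxels).any():
        raise ValueError("lesion lies entirely outside the prostate mask")
    if capsule is None:
        capsule = extract_capsule_surface(prostate)

    elem_d = _element_lesion_distances(lesion, capsule)
    les_pts = lesion.voxel_centers_mm()
    cap_tree = cKDTree(capsule.positions_mm)
    les_d, _ = cap_tree.query(les_pts, workers=-1)

    tcsa = {d: contact_surface_area(lesion, capsule, d, element_distances=elem_d)
            for d in contact_distances_mm}
    tcv = {d: contact_volume(lesion, capsule, d, lesion_capsule_distances=les_d)
           for d in contact_distances_mm}
    tcl = tumor_contact_length(lesion, capsule, tcl_threshold_mm,
                               element_distances=elem_d)
    tcl3d = contact_patch_extent(lesion, capsule, tcl_threshold_mm,
                                 element_distances=elem_d)
    volume, diameter = lesion_shape_features(lesion)

    clin = clinical_row or {}
    fv = LesionFeatureVector(
        patient_id=str(clin.get("patient_id", "")),
        lesion_id=str(clin.get("lesion_id", "")),
        tcl_mm=tcl, tcl3d_mm=tcl3d, tcsa_mm2=tcsa, tcv_mm3=tcv,
        lesion_volume_mm3=volume, lesion_diameter_mm=diameter,
        psa_ng_ml=float(clin.get("psa_ng_ml", np.nan)),
        isup_grade=clin.get("isup_grade"),
        location=clin.get("location"),
        epe_label=clin.get("epe_label"),
        reader_call=clin.get("reader_call"),
        adc_available=adc is not None,
    )
    if adc is not None:
        fv.adc_mean, fv.adc_median, fv.adc_p10, fv.adc_min = adc_statistics(adc, lesion)
    return fv
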