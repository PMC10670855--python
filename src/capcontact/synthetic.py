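"""Synthetic prostate/lesion cohorts with known geometric ground truth.

Real capsule-contact studies rest on non-public surgical cohorts; this
module generates stand-in cohorts with the statistical structure the
analysis assumes, so the whole pipeline is testable end to end:

* prostate masks: smoothly deformed ellipsoids (low-frequency radial
  perturbation of an ellipsoid implicit surface);
* lesions: spherical blobs placed at a controlled depth below the capsule,
  confined to the prostate interior (extraprostatic extension is a label,
  not a mask breach — features are computed from intra-prostatic
  segmentations, as in practice);
* ADC maps: Gaussian background with a hypointense lesion;
* clinical covariates: PSA log-normal (median ~8 ng/mL), ISUP grade
  multinomial, categorical lesion location;
* EPE labels: Bernoulli draws from a logistic model on standardized *true*
  geometric features (computed by the brute-force oracle, never by the
  code under test) plus ISUP grade and log-PSA;
* a simulated radiologist call: a noisy, thresholded copy of the true EPE
  probability, so paired reader-vs-model comparisons can run end to end.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from . import oracle
from .volume import SegmentationVolume, IntensityVolume, save_volume

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_prostate_mask",
           "generate_lesion_mask", "simulate_adc_map",
           "simulate_clinical_covariates", "assign_epe_labels",
           "generate_cohort"]

# ISUP grade-group frequencies of a contemporary radical-prostatectomy
# cohort (grade groups 1..5)
DEFAULT_ISUP_PROBS = (0.210, 0.359, 0.186, 0.157, 0.088)

DEFAULT_LOCATION_PROBS = {
    "posterior": 0.30, "posterolateral": 0.25, "lateral": 0.15,
    "anterior": 0.20, "apical": 0.10,
}

# logistic label model on standardized true features; slopes sized so the
# held-out AUC of the true-probability model sits near 0.88 at ~37%
# prevalence (see docs/methods.md)
DEFAULT_EPE_COEFFICIENTS = {
    "intercept": -0.75,
    "true_tcl_mm": 0.9,
    "true_tcsa_5mm_mm2": 0.9,
    "true_volume_mm3": 0.5,
    "isup_grade": 0.6,
    "log_psa": 0.4,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; a cohort is a pure function of this."""

    n_patients: int = 100
    p_two_lesions: float = 0.25          # lesions per patient ~ 1 + Bern(p)
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 3.0)
    prostate_radii_mm: tuple[float, float, float] = (22.0, 19.0, 20.0)
    prostate_radii_jitter_mm: float = 2.0
    perturbation_amplitude: float = 0.06  # relative radial deformation
    lesion_radius_mm: tuple[float, float] = (3.5, 8.0)
    contact_depth_mm: tuple[float, float] = (0.0, 6.0)
    psa_log_mean: float = float(np.log(8.0))
    psa_log_sd: float = 0.55
    isup_probs: tuple[float, ...] = DEFAULT_ISUP_PROBS
    location_probs: dict = field(default_factory=lambda: dict(DEFAULT_LOCATION_PROBS))
    epe_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_EPE_COEFFICIENTS))
    adc_background: tuple[float, float] = (1400.0, 150.0)   # mean, sd (1e-6 mm^2/s)
    adc_lesion: tuple[float, float] = (800.0, 100.0)
    reader_noise_sd: float = 1.6          # logit-scale noise of the simulated reader
    reader_threshold: float = 0.5
    tcl_threshold_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        spacing = np.asarray(self.spacing_mm, float)
        if not np.all(spacing > 0):
            raise ValueError("spacing must be strictly positive")
        radii = np.asarray(self.prostate_radii_mm, float)
        extent_vox = (radii + self.prostate_radii_jitter_mm) / spacing
        margin = np.asarray(self.grid_shape) / 2 - extent_vox
        if np.any(margin < 3):
            raise ValueError(
                "grid too small: prostate radii leave less than a 3-voxel "
                f"margin (margins {margin} voxels)")
        if self.lesion_radius_mm[1] >= min(self.prostate_radii_mm):
            raise ValueError("lesion radius must be smaller than the smallest "
                             "prostate radius")
        if not 0 <= self.p_two_lesions <= 1:
            raise ValueError("p_two_lesions must be in [0, 1]")


def _patient_rng(cfg: GeneratorConfig, patient_index: int,
                 stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, patient_index, stream]))


def _grid_center_mm(cfg: GeneratorConfig) -> np.ndarray:
    return (np.asarray(cfg.grid_shape) - 1) / 2 * np.asarray(cfg.spacing_mm)


def generate_prostate_mask(cfg: GeneratorConfig,
                           patient_index: int) -> SegmentationVolume:
    """Smoothly deformed ellipsoid; deterministic given (seed, patient_index)."""
    rng = _patient_rng(cfg, patient_index, stream=0)
    spacing = np.asarray(cfg.spacing_mm, float)
    radii = (np.asarray(cfg.prostate_radii_mm, float)
             + rng.uniform(-1, 1, 3) * cfg.prostate_radii_jitter_mm)
    extent_vox = radii / spacing
    if np.any(np.asarray(cfg.grid_shape) / 2 - extent_vox < 3):
        raise ValueError("grid too small for the requested prostate radii")

    center = _grid_center_mm(cfg)
    coords = np.meshgrid(*[np.arange(n) * s for n, s in
                           zip(cfg.grid_shape, spacing)], indexing="ij")
    # normalized ellipsoid radius at every voxel center
    rho2 = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))

    if cfg.perturbation_amplitude > 0:
        coarse = rng.normal(0.0, 1.0, size=(4, 4, 4))
        zoom = [n / 4 for n in cfg.grid_shape]
        pert = ndimage.zoom(coarse, zoom, order=3, mode="nearest")
        pert *= cfg.perturbation_amplitude / max(np.abs(pert).max(), 1e-12)
    else:
        pert = 0.0
    mask = rho2 <= (1.0 + pert) ** 2

    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:  # keep the main body if the perturbation pinched anything off
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return SegmentationVolume(mask, spacing)


def generate_lesion_mask(prostate: SegmentationVolume,
                         cfg: GeneratorConfig,
                         target_contact_depth_mm: float,
                         lesion_radius_mm: float | None = None,
                         rng: np.random.Generator | None = None,
                         direction: np.ndarray | None = None,
                         ) -> SegmentationVolume:
    """Spherical lesion whose surface sits ``target_contact_depth_mm`` below
    the capsule (0 = abutting), confined inside the prostate mask.

    The center is chosen among voxels whose interior depth matches
    ``radius + target_contact_depth``, preferring the voxel best aligned
    with ``direction`` (random in-plane direction when omitted) so that
    contact geometry varies monotonically with the requested depth.
    """
    if not prostate.voxels.any():
        raise ValueError("prostate mask is empty")
    rng = rng or np.random.default_rng(0)
    if lesion_radius_mm is None:
        lesion_radius_mm = rng.uniform(*cfg.lesion_radius_mm)
    if lesion_radius_mm >= min(cfg.prostate_radii_mm):
        raise ValueError("lesion radius exceeds the prostate interior")

    spacing = prostate.spacing_mm
    depth = ndimage.distance_transform_edt(prostate.voxels, sampling=spacing)
    target_depth = lesion_radius_mm + target_contact_depth_mm
    if target_depth > depth.max():
        raise ValueError(
            f"no interior voxel is {target_depth:.1f} mm deep; lesion of "
            f"radius {lesion_radius_mm:.1f} mm at contact depth "
            f"{target_contact_depth_mm:.1f} mm does not fit")

    err = np.abs(depth - target_depth)
    err[~prostate.voxels] = np.inf
    tol = 0.75 * max(spacing)
    cand = np.argwhere(err <= tol)
    if len(cand) == 0:
        cand = np.argwhere(err == err.min())

    if direction is None:
        phi = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    center_mm = prostate.origin_mm + _mask_centroid(prostate) * spacing
    offsets = (cand * spacing + prostate.origin_mm) - center_mm
    norms = np.linalg.norm(offsets, axis=1)
    score = offsets @ np.asarray(direction, float)
    score = np.where(norms > 0, score / np.maximum(norms, 1e-9), -np.inf)
    center = cand[int(np.argmax(score))]

    coords = np.meshgrid(*[np.arange(n) * s for n, s in
                           zip(prostate.shape, spacing)], indexing="ij")
    c_mm = prostate.origin_mm + center * spacing
    r2 = sum((c - mu) ** 2 for c, mu in zip(coords, c_mm))
    sphere = r2 <= lesion_radius_mm ** 2
    lesion = sphere & prostate.voxels
    labels, n = ndimage.label(lesion, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndimage.sum_labels(lesion, labels, index=np.arange(1, n + 1))
        lesion = labels == (1 + int(np.argmax(sizes)))
    if not lesion.any():
        raise ValueError("lesion placement produced an empty mask")
    return SegmentationVolume(lesion, spacing, prostate.origin_mm)


def _mask_centroid(vol: SegmentationVolume) -> np.ndarray:
    return np.asarray(ndimage.center_of_mass(vol.voxels))


def simulate_adc_map(prostate: SegmentationVolume,
                     lesion: SegmentationVolume,
                     cfg: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> IntensityVolume:
    """Gaussian background with a hypointense lesion, clipped at zero."""
    if prostate.shape != lesion.shape:
        raise ValueError(
            f"prostate and lesion grids differ: {prostate.shape} vs {lesion.shape}")
    rng = rng or np.random.default_rng(0)
    bg_mean, bg_sd = cfg.adc_background
    le_mean, le_sd = cfg.adc_lesion
    values = rng.normal(bg_mean, bg_sd, size=prostate.shape) if bg_sd > 0 \
        else np.full(prostate.shape, float(bg_mean))
    les = rng.normal(le_mean, le_sd, size=prostate.shape) if le_sd > 0 \
        else np.full(prostate.shape, float(le_mean))
    values = np.where(lesion.voxels, les, values)
    return IntensityVolume(np.clip(values, 0, None), prostate.spacing_mm,
                           prostate.origin_mm)


def simulate_clinical_covariates(cfg: GeneratorConfig, n: int,
                                 seed: int | None = None) -> pd.DataFrame:
    """Per-lesion clinical covariates: PSA, ISUP grade group, location."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    psa = rng.lognormal(cfg.psa_log_mean, cfg.psa_log_sd, size=n)
    p = np.asarray(cfg.isup_probs, float)
    p = p / p.sum()
    isup = rng.choice(np.arange(1, 6), size=n, p=p)
    locs = list(cfg.location_probs)
    lp = np.asarray([cfg.location_probs[k] for k in locs], float)
    location = rng.choice(locs, size=n, p=lp / lp.sum())
    return pd.DataFrame({"psa_ng_ml": psa, "isup_grade": isup,
                         "location": location})


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)


def assign_epe_labels(truth: pd.DataFrame, epe_coefficients: dict,
                      seed: int) -> pd.DataFrame:
    """EPE probabilities and Bernoulli labels from the logistic label model.

    Slopes apply to in-sample standardized columns of ``truth``; the key
    ``log_psa`` refers to log(psa_ng_ml). Returns a copy of ``truth`` with
    ``epe_probability`` and ``epe_label`` columns.
    """
    rng = np.random.default_rng(seed)
    out = truth.copy()
    lp = np.full(len(out), float(epe_coefficients.get("intercept", 0.0)))
    for name, slope in epe_coefficients.items():
        if name == "intercept" or slope == 0:
            continue
        if name == "log_psa":
            col = np.log(out["psa_ng_ml"].to_numpy(float))
        else:
            col = out[name].to_numpy(float)
        lp += slope * _standardize(col)
    out["epe_probability"] = expit(lp)
    out["epe_label"] = rng.binomial(1, out["epe_probability"])
    return out


def _simulate_reader(prob: np.ndarray, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Dichotomized noisy copy of the true EPE probability."""
    eps = 1e-6
    noisy = logit(np.clip(prob, eps, 1 - eps)) + rng.normal(
        0, cfg.reader_noise_sd, size=len(prob))
    return (expit(noisy) >= cfg.reader_threshold).astype(int)


@dataclass
class SyntheticCohort:
    """A generated cohort: manifest table plus (optionally in-memory) volumes."""

    manifest: pd.DataFrame
    config: GeneratorConfig
    volumes: dict[str, tuple[SegmentationVolume, SegmentationVolume,
                             IntensityVolume]] | None = None
    out_dir: Path | None = None

    def lesion_volumes(self, lesion_id: str):
        if self.volumes is not None:
            return self.volumes[lesion_id]
        from .volume import load_segmentation, load_intensity
        row = self.manifest.set_index("lesion_id").loc[lesion_id]
        base = self.out_dir
        return (load_segmentation(base / row["prostate_path"]),
                load_segmentation(base / row["lesion_path"]),
                load_intensity(base / row["adc_path"]))


def generate_cohort(cfg: GeneratorConfig,
                    out_dir: str | Path | None = None,
                    keep_volumes: bool = True,
                    with_adc: bool = True) -> SyntheticCohort:
    """Generate a full cohort; pure function of ``cfg`` (including its seed).

    When ``out_dir`` is given, masks and ADC maps are written as NIfTI and a
    ``manifest.csv`` records paths, covariates, oracle truth features and
    labels. Repeated calls with the same config produce identical manifests.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    records: list[dict] = []
    volumes: dict = {}
    lesion_counter = 0
    for pi in range(cfg.n_patients):
        struct_rng = _patient_rng(cfg, pi, stream=1)
        prostate = generate_prostate_mask(cfg, pi)
        elements = oracle.oracle_surface_elements(prostate)
        n_lesions = 1 + (struct_rng.uniform() < cfg.p_two_lesions)
        pid = f"P{pi:04d}"
        for li in range(int(n_lesions)):
            depth = struct_rng.uniform(*cfg.contact_depth_mm)
            radius = struct_rng.uniform(*cfg.lesion_radius_mm)
            lesion = generate_lesion_mask(prostate, cfg, depth, radius,
                                          rng=struct_rng)
            truth = _lesion_truth_from_elements(prostate, lesion, elements, cfg)
            rec = {"patient_id": pid, "lesion_id": f"{pid}_L{li}",
                   "target_contact_depth_mm": depth,
                   "lesion_radius_mm": radius, **truth}
            adc = simulate_adc_map(prostate, lesion, cfg,
                                   rng=struct_rng) if with_adc else None
            if out_path is not None:
                pdir = out_path / pid
                pdir.mkdir(exist_ok=True)
                ppath = pdir / "prostate.nii.gz"
                if li == 0:
                    save_volume(prostate, ppath)
                lpath = pdir / f"lesion_{li}.nii.gz"
                save_volume(lesion, lpath)
                rec["prostate_path"] = str(ppath.relative_to(out_path))
                rec["lesion_path"] = str(lpath.relative_to(out_path))
                if adc is not None:
                    apath = pdir / f"adc_{li}.nii.gz"
                    save_volume(adc, apath)
                    rec["adc_path"] = str(apath.relative_to(out_path))
            if keep_volumes:
                volumes[rec["lesion_id"]] = (prostate, lesion, adc)
            records.append(rec)
            lesion_counter += 1

    if not records:
        manifest = pd.DataFrame(columns=["patient_id", "lesion_id"])
    else:
        manifest = pd.DataFrame.from_records(records)
        clin = simulate_clinical_covariates(
            cfg, len(manifest),
            seed=int(np.random.SeedSequence([cfg.seed, 2 ** 20]).generate_state(1)[0] % (2 ** 31)))
        manifest = pd.concat([manifest.reset_index(drop=True), clin], axis=1)
        label_seed = int(np.random.SeedSequence([cfg.seed, 2 ** 20 + 1])
                         .generate_state(1)[0] % (2 ** 31))
        manifest = assign_epe_labels(manifest, cfg.epe_coefficients, label_seed)
        reader_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2 ** 20 + 2]))
        manifest["reader_call"] = _simulate_reader(
            manifest["epe_probability"].to_numpy(), cfg, reader_rng)

    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return SyntheticCohort(manifest=manifest, config=cfg,
                           volumes=volumes if keep_volumes else None,
                           out_dir=out_path)


def _lesion_truth_from_elements(prostate, lesion, elements, cfg) -> dict:
    """Oracle truth features, reusing precomputed capsule elements."""
    from scipy.spatial.distance import cdist
    pos, area, ax, sl = elements
    surf = oracle._surface_voxel_centers(lesion)
    elem_d = cdist(pos, surf).min(axis=1)
    centers = lesion.voxel_centers_mm()
    les_d = cdist(centers, pos).min(axis=1)
    spacing = prostate.spacing_mm
    truth: dict = {}
    for d in (1.0, 2.0, 3.0, 4.0, 5.0):
        truth[f"true_tcsa_{d:g}mm_mm2"] = float(area[elem_d <= d].sum())
        truth[f"true_tcv_{d:g}mm_mm3"] = float(
            (les_d <= d).sum() * lesion.voxel_volume_mm3)
    best = 0.0
    contact = elem_d <= cfg.tcl_threshold_mm
    for k in np.unique(sl):
        sel = (sl == k) & (ax != 2) & contact
        step = np.where(ax[sel] == 0, spacing[1], spacing[0])
        best = max(best, float(step.sum()))
    truth["true_tcl_mm"] = best
    truth["true_volume_mm3"] = lesion.volume_mm3()
    if len(surf) > 1:
        d2 = cdist(surf, surf)
        truth["true_diameter_mm"] = float(d2.max())
    else:
        truth["true_diameter_mm"] = 0.0
    return truth
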