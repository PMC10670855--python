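# Methods

## Contact geometry

**Capsule model.** The prostate capsule is the set of exposed voxel faces of
the prostate mask: a face is exposed when the 6-neighbour across it is
background (voxels outside the grid count as background). Each surface
element carries its face-center position (mm), its area (the product of the
two in-plane spacings for that face orientation), its normal axis, and the
axial slice index of the owning voxel. This model was chosen over a
marching-cubes mesh because it is exact for axis-aligned phantoms and admits
a brute-force oracle short enough to verify by inspection. Its known cost is
an overestimate of oblique surface areas and contour lengths (up to the
Manhattan factor, ~27 % for a quarter-circle arc); the analytic-shape tests
bound this in practice (≤ 15 % for the 30° cylinder-arc contact phantom,
exact for cuboids).

**Distances.** All distances are Euclidean in world coordinates from voxel
centers to face centers, computed with the anisotropic spacing — masks are
never resampled, avoiding interpolation artifacts in binary data. Fast paths
use a k-d tree; the oracle uses explicit pairwise `cdist`. The two agree to
floating-point precision on randomized phantoms (the acceptance suite allows
half a voxel).

**Features.**

* `tcsa_{d}mm_mm2`: summed area of capsule elements whose distance to the
  nearest lesion *surface* voxel center is ≤ d, d ∈ {1,…,5} mm.
* `tcv_{d}mm_mm3`: voxel volume × count of lesion voxels whose center lies
  ≤ d mm from the nearest capsule element.
* `tcl_mm`: per axial slice, the sum of in-plane steps (dy for x-normal
  faces, dx for y-normal faces) of contour faces within the contact
  threshold (default 1 mm, configurable — adjacency cutoffs in the
  literature are rarely stated explicitly); the maximum over slices is
  reported. Faces with axial normals belong to the apical/basal surface,
  not to an axial contour, and are excluded; consequently purely polar
  contact registers in TCSA/TCV but not in axial TCL. That mirrors the
  clinical blind spot of the axial measurement and is exactly why the 3D
  features exist. `tcl3d_mm` (the Euclidean extent of the contact patch) is
  provided as a 3D alternative; the axial value is the default model
  feature. The package's tested TCL = 0 ⟺ TCSA = 0 equivalence therefore
  holds on the lateral-contact phantom family used in the property tests,
  not for contrived purely-polar contacts.
* `lesion_diameter_mm`: 3D Feret diameter (maximum pairwise distance between
  lesion surface voxel centers, via the convex hull). "Tumor diameter" is
  ambiguous in the literature; the 3D choice is consistent with the package's
  three-dimensional framing.
* `adc_p10` uses the linear-interpolation percentile convention (numpy
  default): 100 voxels valued 1…100 give 10.9.

Degenerate inputs raise: empty or disconnected masks, mismatched grids,
lesions wholly outside the prostate, non-positive contact distances.

## Synthetic cohort generator

The generator is a stand-in for a surgical cohort, not an anatomical
simulator. What it does emulate:

* **Prostate masks**: ellipsoids (default radii 22 × 19 × 20 mm ± 2 mm
  jitter, typical of a 40–50 cc gland) deformed by a smooth low-frequency
  radial perturbation (±6 %), on a 64 × 64 × 24 grid at 1.2 × 1.2 × 3 mm —
  in-plane/through-plane anisotropy typical of axial T2-weighted prostate
  MRI, sized so a full run stays desk-scale.
* **Lesions**: spheres (radius 3.5–8 mm) placed so their surface sits a
  controlled depth (0–6 mm) below the capsule along a random in-plane
  direction, then clipped to the prostate. EPE is a *label*, not a mask
  breach: features are computed from intra-prostatic segmentations, as with
  real data. Oracle TCSA/TCV decrease monotonically in the requested depth.
* **ADC maps**: Gaussian background (1400 ± 150 × 10⁻⁶ mm²/s) with a
  hypointense lesion (800 ± 100), clipped at zero.
* **Clinical covariates**: PSA log-normal with median 8 ng/mL and log-sd
  0.55 (typical of contemporary radical-prostatectomy cohorts);
  ISUP grade-group frequencies (21.0, 35.9, 18.6, 15.7, 8.7) % for groups
  1–5; categorical lesion location.
* **Labels**: p = logistic(β₀ + β·z) on in-sample-standardized true TCL,
  TCSA₅, lesion volume, ISUP grade and log-PSA, with the *true* geometric
  features computed by the brute-force oracle so ground truth never flows
  through the code under test. Default slopes (0.9, 0.9, 0.5, 0.6, 0.4) and
  intercept −0.75 put the true-probability model's held-out AUC near 0.88 at
  ~36 % prevalence — the discrimination regime of contemporary lesion-level
  EPE models — and remain configuration, not constants.
* **Reader calls**: the true probability perturbed by logit-scale noise
  (sd 1.6) and thresholded at 0.5, giving a reference reader with roughly
  0.6 sensitivity / 0.76 specificity, so paired reader-versus-model
  comparisons can run end to end.

Not emulated: MR physics (bias fields, b-value effects), anatomical zonal
structure, multi-reader variability, and segmentation error. Passing tests
on this cohort therefore demonstrate the *pipeline's* correctness and
statistical behaviour, not clinical performance on patients.

All randomness derives from per-patient seed sequences of one config seed;
cohorts, manifests and the full experiment report are byte-reproducible
functions of the configuration.

## Model development

Pipeline order: encode → patient-grouped stratified split → correlation
filter (training rows only) → standardize (training statistics) → SMOTE
(training rows only) → feature selection → 5-fold cross-validated grid
search → refit. The correlation filter runs before SMOTE so interpolated
samples never influence the correlation structure.

* **Split**: patients are stratified by their (lesion count, positive count)
  profile and sampled within strata; no patient straddles the split. The
  prevalence-gap guard (default 0.15) widens by the binomial sd of the
  smaller side so it flags systematic imbalance rather than small-sample
  noise.
* **Encoding**: ISUP as ordinal 1–5; location one-hot with the
  alphabetically-first level as reference. The location vocabulary may be
  fixed a priori (as the generator's is) or learned from training data;
  unseen levels at prediction time raise.
* **SMOTE**: synthetic minority samples x + u(x′−x), u ~ U[0,1], x′ among
  the k = 5 minority nearest neighbors, topped up to exact parity with the
  majority. Distances are computed in standardized space; synthetic points
  are mapped back to native units so tree models consume raw features while
  logistic regression consumes standardized ones. The pipeline caps k at the
  available minority neighbours on small training sides; the low-level
  routine keeps the strict k+1 contract.
* **Correlation filter**: greedy scan at |r| > 0.95 in a declared canonical
  order — clinical, then conventional, then novel geometric — so the
  later-ordered member of a correlated pair is dropped (which member is
  dropped is otherwise arbitrary; this makes it deterministic and keeps the
  clinically established feature).
* **Selection**: trees — impurity importances averaged over 5 CV folds,
  keeping the smallest prefix reaching 95 % cumulative importance (the
  threshold is a configurable design choice); logistic — nonzero
  coefficients of a CV-tuned elastic net, falling back to the full set if
  the tuned penalty zeroes everything.
* **Grids** are deliberately small (trees: depth {4, 8, ∞} × leaf {1, 5} at
  200 trees; elastic net: C ∈ {0.01…10} × l1-ratio {0, 0.5, 1}), sized for
  desk-scale runtime; all randomness is seeded and recorded.

## Evaluation

* Threshold metrics use Wilson score 95 % CIs; empty predictive-value
  denominators are flagged, never reported as 0. The operating threshold for
  dichotomizing model probabilities defaults to 0.5 (clinical operating
  points vary and are rarely reported) and is surfaced in every report.
* AUC uses the tie-corrected Mann–Whitney rank form; the CI is DeLong's.
* Calibration: quantile-binned reliability curve plus a logistic
  recalibration fit of labels on logit(p); slope 1 / intercept 0 indicates
  calibration. Constant predictions or single-class labels yield NaN slope,
  flagged rather than fabricated.
* Decision curves evaluate NB(p_t) = TP/n − FP/n · p_t/(1−p_t) on a 0–0.40
  grid in steps of 0.01, with treat-all and treat-none references.
* McNemar tests use only discordant pairs: exact binomial two-sided p when
  b + c < 25, else continuity-corrected chi-square. Sensitivity and
  specificity comparisons restrict to outcome-positive/-negative cases (the
  standard paired-screening construction).
* Relative PPV/NPV: the model/reader ratio on the log scale with a
  delta-method variance over the 8-cell paired multinomial table; a
  patient-level bootstrap CI is provided as a cross-check and agrees with
  the analytic CI within a fifth of its width on 500-lesion cohorts.
* Geometric robustness rescales all geometric feature columns jointly by
  0.95 and 1.05 and reports the min/max of each metric over the three
  scenarios; a one-at-a-time mode is available.

## Problem sizes

The acceptance suite runs the full pipeline at 640 patients (~800 lesions)
with a 150-patient covariate-shifted external cohort, the geometry oracle
on 50 randomized phantoms at grids ≤ 32³, and full-run determinism at 16 + 10
patients; these sizes keep the whole suite within a few minutes on one CPU
while leaving the statistical checks well-powered.

## Known limitations

* The face-count surface overestimates oblique areas; contour-based TCL
  inherits the Manhattan bias (bounded in tests, worst near 45° arcs).
* Axial TCL is blind to purely apical/basal contact by construction (see
  above); `tcl3d` covers that case.
* SMOTE interpolates one-hot and ordinal columns continuously — standard
  behaviour for vanilla SMOTE, but synthetic samples are not guaranteed to
  be valid category profiles.
* The synthetic cohort's covariates are mutually independent given the
  geometry; real PSA/grade/geometry correlations are not modelled, so
  feature-importance orderings on synthetic data should not be read as
  clinical findings.
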