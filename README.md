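# capcontact

Capsule-contact radiomics and lesion-specific prediction of extraprostatic
extension (EPE) of prostate cancer.

## The problem

Before radical prostatectomy, surgeons must decide whether the neurovascular
bundles adjacent to the prostate capsule can be spared. That decision hinges
on whether a tumor has grown through the capsule (extraprostatic extension).
Radiological reading of MRI has high specificity but limited sensitivity for
EPE, and conventional measurements — maximum tumor contact length on a single
axial slice, tumor diameter, ADC values — ignore most of the 3D relationship
between a lesion and the capsule.

`capcontact` computes that 3D relationship directly from co-registered binary
segmentation masks of the prostate gland and each lesion (NIfTI-1, voxel
spacing in mm), and feeds it into a lesion-level classification pipeline:

* **TCL** — tumor contact length: on each axial slice, the in-plane length of
  capsule contour within a contact threshold (default 1 mm) of the lesion
  surface; the reported value is the maximum over slices.
* **TCSA(d)** — tumor contact surface area: the area of the capsule surface
  whose Euclidean distance to the lesion surface is ≤ *d*, for
  *d* = 1…5 mm.
* **TCV(d)** — tumor contact volume: the volume of lesion tissue lying within
  *d* mm of the capsule.
* Conventional features: lesion volume, 3D Feret diameter, ADC statistics
  (mean, median, 10th percentile, minimum), plus clinical covariates (PSA,
  ISUP biopsy grade group, lesion location).

The capsule is modelled as the exposed voxel faces of the prostate mask; all
distances are anisotropy-aware (voxel center to face center, never on a
resampled grid).

On top of the features sits the model-development and evaluation battery used
in clinical prediction research: a patient-grouped, outcome-stratified 80/20
split; SMOTE rebalancing of the training side; a 95 % correlation filter;
impurity-importance (trees) or elastic-net (logistic) feature selection;
5-fold cross-validated tuning of random forest, extra trees and logistic
regression; and evaluation by accuracy/sensitivity/specificity/PPV/NPV with
Wilson CIs, AUC with DeLong CI, calibration slope and intercept, decision
curve analysis over risk thresholds 0–40 %
(NB(p_t) = TP/n − FP/n · p_t/(1−p_t)), ±5 % geometric robustness, and paired
comparisons against a reference reader (McNemar tests and relative
PPV/NPV ratios with delta-method CIs).

Because surgical cohorts with segmentations and pathology ground truth are
not publicly shareable, the package ships a synthetic-cohort generator
(`capcontact.synthetic`) that produces prostate/lesion masks with
controllable capsule contact, ADC maps, clinical covariates and EPE labels
drawn from a stated logistic model on *true* geometric features computed by
an independent brute-force oracle. Every pipeline stage is tested end to end
against it.

## Worked example

```python
from capcontact import GeneratorConfig, generate_cohort
from capcontact.workbench import extract_cohort_features
from capcontact import modeling as md, evaluation as ev

cfg = GeneratorConfig(n_patients=160, seed=7)
cohort = generate_cohort(cfg)
feats = extract_cohort_features(cohort)
print(feats[["lesion_id", "tcl_mm", "tcsa_5mm_mm2", "tcv_5mm_mm3",
             "lesion_volume_mm3", "adc_mean"]].head(3).round(1).to_string(index=False))

split = md.grouped_stratified_split(feats, test_fraction=0.2, seed=7)
train = feats[feats.lesion_id.isin(split.train_ids)]
test = feats[feats.lesion_id.isin(split.test_ids)]
spec = md.tune_and_fit("random_forest", train, seed=7)
prob = md.predict_probabilities(spec, test)
auc, ci = ev.roc_auc_with_ci(test["epe_label"].to_numpy(), prob)
print(f"held-out AUC {auc:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f}) on {len(test)} lesions")
```

prints

```
lesion_id  tcl_mm  tcsa_5mm_mm2  tcv_5mm_mm3  lesion_volume_mm3  adc_mean
 P0000_L0     1.2         524.9        466.6             1300.3     796.0
 P0001_L0     0.0         192.2         99.4              272.2     809.6
 P0002_L0    10.8         342.7        233.3              259.2     798.7
held-out AUC 0.84 (95% CI 0.70-0.99) on 38 lesions
```

The first lesion touches the capsule over a ~525 mm² patch within 5 mm but
only 1.2 mm of axial contour within 1 mm — a broad shallow contact; the
second sits fully interior on its contact slice; the third has a 10.8 mm
axial contact length. The classifier, trained only on extracted features,
discriminates EPE on held-out patients at AUC 0.84 here (the wide CI reflects
the 38-lesion test side).

A command-line interface mirrors the library:

```
capcontact generate --n-patients 40 --seed 1 --out cohort/
capcontact features --prostate P.nii.gz --lesion L.nii.gz --adc A.nii.gz --out f.csv
capcontact train    --features features.csv --model rf --out model/
capcontact evaluate --model model/ --features test.csv --out report/
capcontact run      --config experiment.yaml --out exp/
```

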