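"""Experiment orchestration: one config in, one reproducible report out.

A run is a pure function of an :class:`ExperimentConfig`: generate an
internal and a covariate-shifted "external" synthetic cohort, extract the
capsule-contact features, train the three classifiers on the internal
training side, and evaluate on both test cohorts (discrimination,
calibration, decision curves, reader comparisons, geometric robustness).
The output directory carries a manifest with the config hash, seeds and
library versions; identical configs give byte-identical metrics JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import modeling as md
from .geometry import extract_capsule_surface, extract_feature_vector, FEATURE_ORDER
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort
from .volume import load_segmentation, load_intensity  # re-exported surface

__all__ = ["ExperimentConfig", "run_experiment", "extract_cohort_features",
           "write_feature_table", "read_feature_table", "load_segmentation",
           "load_intensity", "cohort_accounting"]


def cohort_accounting(n_screened: int, exclusion_counts,
                      cohort_lesion_counts) -> dict:
    """Study-flow bookkeeping: patients surviving exclusion filters and the
    total number of analyzed lesions across cohorts."""
    if n_screened < 0 or any(e < 0 for e in exclusion_counts):
        raise ValueError("counts must be non-negative")
    included = n_screened - sum(exclusion_counts)
    if included < 0:
        raise ValueError("exclusions exceed the screened population")
    return {"patients_included": int(included),
            "lesions_total": int(sum(cohort_lesion_counts))}

# columns where NaN legitimately encodes "not supplied" (missing ADC volume
# or absent clinical record); computed geometric features must be finite
_NAN_OK_COLUMNS = {"adc_mean", "adc_median", "adc_p10", "adc_min",
                   "psa_ng_ml", "isup_grade", "epe_label", "reader_call"}


@dataclass
class ExperimentConfig:
    """Full experiment description; YAML-serializable."""

    generator: dict = field(default_factory=dict)
    # covariate shift of the external site: different gland sizes and
    # prevalence (via the label-model intercept), echoing a two-site design
    external: dict = field(default_factory=lambda: {
        "n_patients": 40,
        "prostate_radii_mm": (24.0, 20.0, 21.0),
        "intercept_shift": 0.25,
    })
    test_fraction: float = 0.2
    models: tuple[str, ...] = md.MODEL_KINDS
    grids: dict | None = None
    operating_threshold: float = 0.5
    tcl_threshold_mm: float = 1.0
    calibration_bins: int = 5
    dca_max_threshold: float = 0.40
    robustness_perturbation: float = 0.05
    seed: int = 0
    make_plots: bool = False

    _KNOWN = None  # populated below

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must be in [0, 1)")
        for m in self.models:
            if m not in md.MODEL_KINDS:
                raise ValueError(f"unknown model kind '{m}'")
        if not 0 < self.operating_threshold < 1:
            raise ValueError("operating_threshold must be in (0, 1)")
        # constructing the generator validates its geometry early
        self.internal_generator()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_KNOWN", None)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def internal_generator(self) -> GeneratorConfig:
        params = dict(self.generator)
        params.setdefault("seed", self.seed)
        params.setdefault("tcl_threshold_mm", self.tcl_threshold_mm)
        return GeneratorConfig(**params)

    def external_generator(self) -> GeneratorConfig:
        base = self.internal_generator()
        params = dataclasses.asdict(base)
        ext = dict(self.external)
        shift = ext.pop("intercept_shift", 0.0)
        params.update(ext)
        params["seed"] = base.seed + 10_000
        coef = dict(params["epe_coefficients"])
        coef["intercept"] = coef.get("intercept", 0.0) + shift
        params["epe_coefficients"] = coef
        return GeneratorConfig(**params)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# --------------------------------------------------------------------------
# feature tables

CLINICAL_COLUMNS = ["patient_id", "lesion_id", "psa_ng_ml", "isup_grade",
                    "location", "epe_label", "reader_call"]


def extract_cohort_features(cohort: SyntheticCohort,
                            tcl_threshold_mm: float = 1.0) -> pd.DataFrame:
    """Run the contact-geometry feature extractor over every cohort lesion."""
    rows = []
    capsules: dict[str, object] = {}
    prostates: dict[str, object] = {}
    for rec in cohort.manifest.to_dict("records"):
        prostate, lesion, adc = cohort.lesion_volumes(rec["lesion_id"])
        pid = rec["patient_id"]
        if pid not in capsules or prostates.get(pid) is not prostate:
            capsules[pid] = extract_capsule_surface(prostate)
            prostates[pid] = prostate
        fv = extract_feature_vector(
            prostate, lesion, adc,
            clinical_row={k: rec.get(k) for k in CLINICAL_COLUMNS},
            capsule=capsules[pid], tcl_threshold_mm=tcl_threshold_mm)
        rows.append(fv.to_dict())
    return pd.DataFrame(rows)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as CSV (stable column order, lossless floats).

    Non-finite values are rejected with the offending lesion and column
    named; NaN is tolerated only in the ADC statistics, where it encodes a
    missing ADC volume.
    """
    cols = [c for c in CLINICAL_COLUMNS if c in features.columns]
    cols += [c for c in features.columns if c not in cols]
    features = features[cols]
    numeric = features.select_dtypes(include=[np.number])
    for col in numeric.columns:
        vals = numeric[col].to_numpy(float)
        bad = np.isinf(vals) | (np.isnan(vals) & (col not in _NAN_OK_COLUMNS))
        if bad.any():
            i = int(np.argmax(bad))
            lesion = features.iloc[i].get("lesion_id", f"row {i}")
            raise ValueError(
                f"non-finite value in column '{col}' for lesion '{lesion}'")
    features.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# evaluation assembly

def _evaluate_model(spec: md.ModelSpec, features: pd.DataFrame,
                    cfg: ExperimentConfig) -> dict:
    labels = features["epe_label"].to_numpy(int)
    prob = md.predict_probabilities(spec, features)
    thr = cfg.operating_threshold
    report = ev.confusion_metrics_with_ci(labels, prob, thr)
    if labels.min() == labels.max():
        auc, auc_ci = np.nan, (np.nan, np.nan)   # single-class cohort
    else:
        auc, auc_ci = ev.roc_auc_with_ci(labels, prob)
    cal = ev.calibration_curve(labels, prob, n_bins=cfg.calibration_bins)
    dca = ev.decision_curve(labels, prob, np.round(
        np.arange(0.0, cfg.dca_max_threshold + 1e-9, 0.01), 4))
    robust = ev.geometric_robustness(spec, features, labels,
                                     perturbation=cfg.robustness_perturbation,
                                     threshold=thr)
    out = {
        "metrics": report.to_dict(),
        "auc": auc, "auc_ci": list(auc_ci),
        "calibration": {"slope": cal.slope, "intercept": cal.intercept},
        "robustness": {k: list(v) for k, v in robust.items()},
    }
    if "reader_call" in features.columns:
        reader = features["reader_call"].to_numpy(int)
        model_call = (prob >= thr).astype(int)
        cmp: dict = {}
        for metric in ("accuracy", "sensitivity", "specificity"):
            r = ev.mcnemar_compare(labels, reader, model_call, metric)
            cmp[f"mcnemar_{metric}_p"] = r.p_value
        for kind in ("ppv", "npv"):
            try:
                r = ev.relative_predictive_value_test(reader, model_call,
                                                      labels, kind)
                cmp[f"relative_{kind}"] = r.ratio
                cmp[f"relative_{kind}_ci"] = list(r.ratio_ci)
                cmp[f"relative_{kind}_p"] = r.p_value
            except ValueError as exc:
                cmp[f"relative_{kind}_error"] = str(exc)
        out["reader_comparison"] = cmp
    return {"curves": {"calibration": cal, "dca": dca}, "summary": out}


def run_experiment(config: ExperimentConfig | dict,
                   out_dir: str | Path) -> Path:
    """Execute the full pipeline and write a report directory."""
    if isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    else:
        config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    internal = generate_cohort(config.internal_generator(), keep_volumes=True)
    external = generate_cohort(config.external_generator(), keep_volumes=True)
    timings["generate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    feats_int = extract_cohort_features(internal, config.tcl_threshold_mm)
    feats_ext = extract_cohort_features(external, config.tcl_threshold_mm)
    timings["features_s"] = time.perf_counter() - t0
    write_feature_table(feats_int, out / "features_internal.csv")
    write_feature_table(feats_ext, out / "features_external.csv")

    split = md.grouped_stratified_split(feats_int, config.test_fraction,
                                        seed=config.seed)
    train = feats_int[feats_int["lesion_id"].isin(split.train_ids)]
    test = feats_int[feats_int["lesion_id"].isin(split.test_ids)]

    t0 = time.perf_counter()
    metrics: dict = {"split": split.report, "models": {}}
    levels = sorted(config.internal_generator().location_probs)
    for kind in config.models:
        spec = md.tune_and_fit(kind, train, seed=config.seed,
                               grid=(config.grids or {}).get(kind),
                               location_levels=levels)
        spec.operating_threshold = config.operating_threshold
        entry = {"cv_auc": spec.cv_auc, "best_params": spec.best_params,
                 "selected_features": spec.selected_features, "cohorts": {}}
        for name, feats in (("internal_test", test), ("external_test", feats_ext)):
            if len(feats) == 0:
                continue
            res = _evaluate_model(spec, feats, config)
            entry["cohorts"][name] = res["summary"]
            res["curves"]["calibration"].to_frame().to_csv(
                out / "report" / f"calibration_{kind}_{name}.csv", index=False)
            res["curves"]["dca"].to_frame().to_csv(
                out / "report" / f"dca_{kind}_{name}.csv", index=False)
            if config.make_plots:
                _plot_curves(res["curves"], kind, name, out / "report")
        metrics["models"][kind] = entry
    timings["train_eval_s"] = time.perf_counter() - t0

    # reader reference performance on both test cohorts
    metrics["reader"] = {}
    for name, feats in (("internal_test", test), ("external_test", feats_ext)):
        if len(feats) == 0:
            continue
        rep = ev.confusion_metrics_with_ci(
            feats["epe_label"].to_numpy(int),
            feats["reader_call"].to_numpy(float), threshold=0.5)
        metrics["reader"][name] = rep.to_dict()

    with open(out / "report" / "metrics.json", "w") as fh:
        json.dump(_jsonable(metrics), fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(config.to_dict()), fh, sort_keys=True)

    import sklearn, scipy, statsmodels
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__,
                     "statsmodels": statsmodels.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _plot_curves(curves: dict, kind: str, cohort: str, report_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cal = curves["calibration"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.errorbar(cal.bin_mean_predicted, cal.bin_observed_fraction,
                yerr=np.abs(cal.bin_ci.T - cal.bin_observed_fraction),
                fmt="o-", capsize=2)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed EPE fraction")
    ax.set_title(f"{kind} calibration ({cohort})")
    fig.tight_layout()
    fig.savefig(report_dir / f"calibration_{kind}_{cohort}.svg")
    plt.close(fig)

    dca = curves["dca"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(dca.thresholds, dca.model, label=kind)
    ax.plot(dca.thresholds, dca.treat_all, label="treat all")
    ax.plot(dca.thresholds, dca.treat_none, label="treat none")
    ax.set_xlabel("risk threshold")
    ax.set_ylabel("net benefit")
    ax.legend()
    ax.set_title(f"decision curve ({cohort})")
    fig.tight_layout()
    fig.savefig(report_dir / f"dca_{kind}_{cohort}.svg")
    plt.close(fig)
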