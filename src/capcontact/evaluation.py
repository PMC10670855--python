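"""Evaluation battery: discrimination, calibration, decision curves, and
paired comparisons against a reference reader.

Conventions: proportions get Wilson score 95% CIs; the AUC CI is DeLong's;
net benefit is TP/n - (FP/n) * pt/(1-pt) with positivity at probability
>= pt; paired predictive values are compared on the log-ratio scale with a
multinomial delta-method variance (a patient-level bootstrap is available
as a cross-check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .geometry import GEOMETRIC_FEATURES
from .modeling import ModelSpec, predict_probabilities

__all__ = ["MetricReport", "NetBenefitCurve", "CalibrationCurve",
           "PairedComparisonResult", "confusion_metrics_with_ci",
           "roc_auc_with_ci", "calibration_curve", "decision_curve",
           "mcnemar_test", "mcnemar_compare", "relative_predictive_value_test",
           "bootstrap_relative_pv", "geometric_robustness"]


# --------------------------------------------------------------------------
# discrimination

@dataclass
class MetricReport:
    """Threshold metrics with Wilson 95% CIs, plus AUC with DeLong CI."""

    threshold: float
    n: int
    estimates: dict[str, float]
    cis: dict[str, tuple[float, float]]
    counts: dict[str, int]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "n": self.n,
                "estimates": self.estimates,
                "cis": {k: list(v) for k, v in self.cis.items()},
                "counts": self.counts, "flags": self.flags}


def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def confusion_metrics_with_ci(labels: np.ndarray, probabilities: np.ndarray,
                              threshold: float = 0.5) -> MetricReport:
    """Dichotomize at ``threshold`` and report accuracy/sens/spec/PPV/NPV.

    An empty predicted-positive (or -negative) set leaves the corresponding
    predictive value NaN and adds a flag rather than silently reporting 0.
    """
    labels = np.asarray(labels, int)
    pred = np.asarray(probabilities, float) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n = tp + fp + fn + tn
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name} undefined (empty denominator)")
            return np.nan, (np.nan, np.nan)
        return num / den, _wilson(num, den)

    acc, acc_ci = ratio(tp + tn, n, "accuracy")
    sens, sens_ci = ratio(tp, tp + fn, "sensitivity")
    spec, spec_ci = ratio(tn, tn + fp, "specificity")
    ppv, ppv_ci = ratio(tp, tp + fp, "ppv")
    npv, npv_ci = ratio(tn, tn + fn, "npv")
    return MetricReport(
        threshold=threshold, n=n,
        estimates={"accuracy": acc, "sensitivity": sens, "specificity": spec,
                   "ppv": ppv, "npv": npv},
        cis={"accuracy": acc_ci, "sensitivity": sens_ci, "specificity": spec_ci,
             "ppv": ppv_ci, "npv": npv_ci},
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn}, flags=flags)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_with_ci(labels: np.ndarray, probabilities: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC by the Mann-Whitney rank formulation (tie-corrected) with a
    DeLong 95% confidence interval, clipped to [0, 1]."""
    labels = np.asarray(labels, int)
    scores = np.asarray(probabilities, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(auc), (float(max(0.0, auc - z * se)),
                        float(min(1.0, auc + z * se)))


# --------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationCurve:
    bin_mean_predicted: np.ndarray
    bin_observed_fraction: np.ndarray
    bin_counts: np.ndarray
    bin_ci: np.ndarray                 # (n_bins, 2) Wilson
    slope: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_predicted": self.bin_mean_predicted,
            "observed_fraction": self.bin_observed_fraction,
            "n": self.bin_counts,
            "ci_low": self.bin_ci[:, 0], "ci_high": self.bin_ci[:, 1]})


def calibration_curve(labels: np.ndarray, probabilities: np.ndarray,
                      n_bins: int = 10) -> CalibrationCurve:
    """Quantile-binned reliability curve plus logistic recalibration.

    The slope/intercept come from refitting ``label ~ logit(p)``: a
    well-calibrated model gives slope 1, intercept 0.
    """
    labels = np.asarray(labels, int)
    p = np.asarray(probabilities, float)
    df = pd.DataFrame({"y": labels, "p": p})
    if np.ptp(p) == 0:
        # constant predictions collapse to a single bin
        df["bin"] = 0
    else:
        df["bin"] = pd.qcut(df["p"], q=n_bins, duplicates="drop")
    grouped = df.groupby("bin", observed=True)
    mean_p = grouped["p"].mean().to_numpy()
    obs = grouped["y"].mean().to_numpy()
    counts = grouped["y"].size().to_numpy()
    ks = grouped["y"].sum().to_numpy()
    cis = np.array([_wilson(int(k), int(n)) for k, n in zip(ks, counts)])

    eps = 1e-10
    lp = np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps))
    import statsmodels.api as sm
    if labels.min() == labels.max() or np.ptp(lp) == 0:
        # single-class labels or constant predictions: slope undefined
        slope, intercept = np.nan, np.nan
    else:
        fit = sm.Logit(labels, sm.add_constant(lp)).fit(disp=0)
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    return CalibrationCurve(mean_p, obs, counts, cis, slope, intercept)


# --------------------------------------------------------------------------
# decision curve analysis

@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "net_benefit_model": self.model,
                             "net_benefit_treat_all": self.treat_all,
                             "net_benefit_treat_none": self.treat_none})


def decision_curve(labels: np.ndarray, probabilities: np.ndarray,
                   thresholds: np.ndarray | None = None) -> NetBenefitCurve:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt), positivity at p >= pt,
    over a clinically relevant grid (default 0 to 0.40 in steps of 0.01)."""
    labels = np.asarray(labels, int)
    p = np.asarray(probabilities, float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.401, 0.01), 4)
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds >= 1):
        raise ValueError("risk thresholds must be < 1")
    n = len(labels)
    prev = labels.mean() if n else np.nan
    model_nb, all_nb = [], []
    for pt in thresholds:
        w = pt / (1 - pt)
        pred = p >= pt
        tp = np.sum(pred & (labels == 1)) / n
        fp = np.sum(pred & (labels == 0)) / n
        model_nb.append(tp - fp * w)
        all_nb.append(prev - (1 - prev) * w)
    return NetBenefitCurve(thresholds, np.asarray(model_nb),
                           np.asarray(all_nb), np.zeros_like(thresholds),
                           float(prev))


# --------------------------------------------------------------------------
# paired comparisons

@dataclass
class PairedComparisonResult:
    kind: str                  # mcnemar | relative_ppv | relative_npv
    statistic: float
    p_value: float
    ratio: float | None = None
    ratio_ci: tuple[float, float] | None = None
    n_discordant: int | None = None
    flags: list[str] = field(default_factory=list)


def mcnemar_test(reference_correct: np.ndarray,
                 model_correct: np.ndarray) -> PairedComparisonResult:
    """McNemar test on paired correctness flags.

    Uses only discordant pairs: exact binomial two-sided p when b + c < 25,
    else the continuity-corrected chi-square version.
    """
    ref = np.asarray(reference_correct, bool)
    mod = np.asarray(model_correct, bool)
    if ref.shape != mod.shape:
        raise ValueError("paired flag arrays must have equal length")
    b = int(np.sum(mod & ~ref))   # model right, reference wrong
    c = int(np.sum(~mod & ref))
    if b + c == 0:
        return PairedComparisonResult("mcnemar", statistic=0.0, p_value=1.0,
                                      n_discordant=0,
                                      flags=["degenerate: no discordant pairs"])
    table = [[0, b], [c, 0]]   # only off-diagonals matter
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return PairedComparisonResult("mcnemar", statistic=float(res.statistic),
                                  p_value=float(min(1.0, res.pvalue)),
                                  n_discordant=b + c)


def mcnemar_compare(labels: np.ndarray, reference_calls: np.ndarray,
                    model_calls: np.ndarray,
                    metric: str = "accuracy") -> PairedComparisonResult:
    """Compare accuracy/sensitivity/specificity of two binary raters.

    Sensitivity restricts the paired test to outcome-positive cases,
    specificity to outcome-negative ones (the standard paired-screening
    construction).
    """
    labels = np.asarray(labels, int)
    ref = np.asarray(reference_calls, int)
    mod = np.asarray(model_calls, int)
    if metric == "accuracy":
        mask = np.ones_like(labels, bool)
    elif metric == "sensitivity":
        mask = labels == 1
    elif metric == "specificity":
        mask = labels == 0
    else:
        raise ValueError(f"unknown metric '{metric}'")
    return mcnemar_test((ref == labels)[mask], (mod == labels)[mask])


def _paired_pv_log_ratio(reference_calls, model_calls, labels, kind):
    ref = np.asarray(reference_calls, int)
    mod = np.asarray(model_calls, int)
    y = np.asarray(labels, int)
    if kind == "ppv":
        num_m = np.sum((mod == 1) & (y == 1)); den_m = np.sum(mod == 1)
        num_r = np.sum((ref == 1) & (y == 1)); den_r = np.sum(ref == 1)
    elif kind == "npv":
        num_m = np.sum((mod == 0) & (y == 0)); den_m = np.sum(mod == 0)
        num_r = np.sum((ref == 0) & (y == 0)); den_r = np.sum(ref == 0)
    else:
        raise ValueError("kind must be 'ppv' or 'npv'")
    if den_m == 0 or den_r == 0 or num_m == 0 or num_r == 0:
        raise ValueError(
            f"relative {kind.upper()} undefined: a predictive value is zero "
            "or has an empty denominator")
    g = np.log(num_m) - np.log(den_m) - np.log(num_r) + np.log(den_r)
    # delta-method variance over the 8-cell paired multinomial
    var = 0.0
    for a in (0, 1):
        for b_ in (0, 1):
            for d in (0, 1):
                n_j = int(np.sum((mod == a) & (ref == b_) & (y == d)))
                if n_j == 0:
                    continue
                grad = 0.0
                if kind == "ppv":
                    if a == 1 and d == 1:
                        grad += 1 / num_m
                    if a == 1:
                        grad -= 1 / den_m
                    if b_ == 1 and d == 1:
                        grad -= 1 / num_r
                    if b_ == 1:
                        grad += 1 / den_r
                else:
                    if a == 0 and d == 0:
                        grad += 1 / num_m
                    if a == 0:
                        grad -= 1 / den_m
                    if b_ == 0 and d == 0:
                        grad -= 1 / num_r
                    if b_ == 0:
                        grad += 1 / den_r
                var += n_j * grad ** 2
    return float(g), float(var)


def relative_predictive_value_test(reference_calls, model_calls, labels,
                                   kind: str = "ppv") -> PairedComparisonResult:
    """Paired comparison of predictive values as a ratio (model / reference).

    The log ratio gets a delta-method variance from the 8-cell paired
    multinomial table; the Wald z-test addresses ratio = 1. A zero or
    undefined predictive value on either side raises.
    """
    g, var = _paired_pv_log_ratio(reference_calls, model_calls, labels, kind)
    flags = []
    if var <= 0:
        z, p = 0.0, 1.0
        ci = (float(np.exp(g)), float(np.exp(g)))
        flags.append("degenerate: zero variance (identical classifications)")
    else:
        se = np.sqrt(var)
        z = g / se
        p = 2 * stats.norm.sf(abs(z))
        ci = (float(np.exp(g - 1.959963984540054 * se)),
              float(np.exp(g + 1.959963984540054 * se)))
    return PairedComparisonResult(f"relative_{kind}", statistic=float(z),
                                  p_value=float(p), ratio=float(np.exp(g)),
                                  ratio_ci=ci, flags=flags)


def bootstrap_relative_pv(reference_calls, model_calls, labels,
                          kind: str = "ppv", patient_ids=None,
                          n_boot: int = 2000, seed: int = 0
                          ) -> tuple[float, float]:
    """Percentile bootstrap CI for the predictive-value ratio, resampling
    patients (rows when no patient ids are given)."""
    ref = np.asarray(reference_calls, int)
    mod = np.asarray(model_calls, int)
    y = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    if patient_ids is None:
        groups = [np.array([i]) for i in range(len(y))]
    else:
        pid = pd.Series(patient_ids)
        groups = [np.asarray(ix) for _, ix in
                  pid.groupby(pid, sort=True).indices.items()]
    ratios = []
    for _ in range(n_boot):
        take = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[t] for t in take])
        try:
            g, _ = _paired_pv_log_ratio(ref[idx], mod[idx], y[idx], kind)
            ratios.append(np.exp(g))
        except ValueError:
            continue
    if not ratios:
        raise ValueError("bootstrap produced no valid resamples")
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# geometric robustness

def geometric_robustness(spec: ModelSpec, test_features: pd.DataFrame,
                         labels: np.ndarray, perturbation: float = 0.05,
                         threshold: float = 0.5,
                         per_feature: bool = False) -> dict:
    """Metric ranges under +/-``perturbation`` scaling of the geometric features.

    Default mode scales all geometric feature columns jointly by
    (1 - perturbation) and (1 + perturbation); ``per_feature`` scales one
    column at a time instead. Returns ``{metric: (min, max)}`` over the
    unperturbed and perturbed predictions.
    """
    labels = np.asarray(labels, int)
    geo_cols = [c for c in GEOMETRIC_FEATURES if c in test_features.columns]
    scenarios: list[pd.DataFrame] = [test_features]
    for factor in (1 - perturbation, 1 + perturbation):
        if factor == 1.0:
            continue
        if per_feature:
            for col in geo_cols:
                t = test_features.copy()
                t[col] = t[col] * factor
                scenarios.append(t)
        else:
            t = test_features.copy()
            t[geo_cols] = t[geo_cols] * factor
            scenarios.append(t)
    metrics: dict[str, list[float]] = {}
    for t in scenarios:
        prob = predict_probabilities(spec, t)
        rep = confusion_metrics_with_ci(labels, prob, threshold)
        for k, v in rep.estimates.items():
            metrics.setdefault(k, []).append(v)
    out = {}
    for k, v in metrics.items():
        arr = np.asarray(v, float)
        if np.isnan(arr).all():
            out[k] = (np.nan, np.nan)   # metric undefined in every scenario
        else:
            out[k] = (float(np.nanmin(arr)), float(np.nanmax(arr)))
    return out
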