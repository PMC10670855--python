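"""Model development: split, rebalance, filter, select, tune, fit.

The pipeline order is fixed as

    encode -> grouped split -> correlation filter (train only)
           -> standardize (train statistics) -> SMOTE (train only)
           -> feature selection -> 5-fold CV tuning -> refit

so synthetic minority samples never influence the correlation structure and
nothing computed from the test rows ever reaches training. Logistic
regression consumes standardized features; the tree models consume raw
features (SMOTE interpolation happens in standardized space and is mapped
back, so neighbor distances are scale-free while tree inputs keep their
units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .geometry import FEATURE_ORDER

__all__ = ["CohortSplit", "ModelSpec", "grouped_stratified_split",
           "smote_oversample", "correlation_filter", "CategoricalEncoder",
           "select_features", "tune_and_fit", "predict_probabilities",
           "MODEL_KINDS", "DEFAULT_GRIDS"]

MODEL_KINDS = ("random_forest", "extra_trees", "logistic_regression")

# deliberately small, desk-scale grids
DEFAULT_GRIDS = {
    "random_forest": {"n_estimators": [200], "max_depth": [4, 8, None],
                      "min_samples_leaf": [1, 5]},
    "extra_trees": {"n_estimators": [200], "max_depth": [4, 8, None],
                    "min_samples_leaf": [1, 5]},
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0],
                            "l1_ratio": [0.0, 0.5, 1.0]},
}


@dataclass
class CohortSplit:
    """Patient-grouped, label-stratified lesion split."""

    train_ids: list[str]
    test_ids: list[str]
    report: dict = field(default_factory=dict)


def grouped_stratified_split(records: pd.DataFrame, test_fraction: float = 0.2,
                             seed: int = 0,
                             prevalence_tolerance: float = 0.15) -> CohortSplit:
    """Split lesions into train/test keeping each patient wholly on one side
    and approximately preserving EPE prevalence.

    ``records`` needs columns ``lesion_id``, ``patient_id``, ``epe_label``.
    Patients are stratified by their (lesion count, positive count) profile
    and sampled within strata. Raises when one patient owns more lesions
    than the whole training side, or when the achieved prevalence gap
    exceeds ``prevalence_tolerance``.
    """
    for col in ("lesion_id", "patient_id", "epe_label"):
        if col not in records.columns:
            raise ValueError(f"records must carry a '{col}' column")
    n = len(records)
    if test_fraction == 0 or n == 0:
        return CohortSplit(train_ids=list(records["lesion_id"]), test_ids=[],
                           report={"n_train": n, "n_test": 0})

    by_patient = records.groupby("patient_id")["epe_label"].agg(["count", "sum"])
    max_lesions = by_patient["count"].max()
    if max_lesions > (1 - test_fraction) * n:
        raise ValueError(
            "stratification infeasible: one patient holds more lesions than "
            "the whole training side")

    rng = np.random.default_rng(seed)
    test_patients: list = []
    for _, stratum in by_patient.groupby(["count", "sum"]):
        pats = list(stratum.index)
        order = rng.permutation(len(pats))
        k = int(round(test_fraction * len(pats)))
        test_patients.extend(pats[i] for i in order[:k])

    test_set = set(test_patients)
    is_test = records["patient_id"].isin(test_set)
    train = records.loc[~is_test]
    test = records.loc[is_test]
    prev_train = train["epe_label"].mean() if len(train) else np.nan
    prev_test = test["epe_label"].mean() if len(test) else np.nan
    # the guard targets systematic imbalance, not small-sample noise: widen
    # the tolerance by the binomial sd of the smaller side
    eff_tol = max(prevalence_tolerance, 1.0 / np.sqrt(max(len(test), 1)))
    if len(test) and abs(prev_train - prev_test) > eff_tol:
        raise ValueError(
            f"stratified split failed: prevalence gap "
            f"{abs(prev_train - prev_test):.3f} exceeds tolerance")
    report = {
        "n_train": int(len(train)), "n_test": int(len(test)),
        "train_prevalence": float(prev_train), "test_prevalence": float(prev_test),
        "n_train_patients": int(train["patient_id"].nunique()),
        "n_test_patients": int(test["patient_id"].nunique()),
    }
    return CohortSplit(train_ids=list(train["lesion_id"]),
                       test_ids=list(test["lesion_id"]), report=report)


def smote_oversample(features: np.ndarray, labels: np.ndarray,
                     k_neighbors: int = 5, seed: int = 0,
                     u: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is ``x + u * (x' - x)`` with ``u ~ U[0, 1]``,
    ``x`` a minority sample and ``x'`` one of its ``k_neighbors`` minority
    nearest neighbors. Originals are retained unchanged; the minority class
    is topped up to exact parity with the majority. ``u`` may be forced to
    a constant (used in tests).
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE needs exactly two classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return features.copy(), labels.copy()
    X_min = features[labels == minority]
    if len(X_min) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(X_min)} samples; SMOTE with "
            f"k={k_neighbors} needs at least {k_neighbors + 1}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(X_min), size=n_needed)
    neigh = idx[base, rng.integers(1, k_neighbors + 1, size=n_needed)]
    uu = np.full(n_needed, u) if u is not None else rng.uniform(size=n_needed)
    synth = X_min[base] + uu[:, None] * (X_min[neigh] - X_min[base])
    X_out = np.vstack([features, synth])
    y_out = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    return X_out, y_out


def correlation_filter(features: pd.DataFrame,
                       threshold: float = 0.95) -> list[str]:
    """Greedy Pearson-correlation filter in canonical feature order.

    Scans columns in declared order (clinical, conventional, novel
    geometric — columns not in the canonical list come last, in table
    order) and drops any feature with |r| > threshold against an
    already-retained one. Idempotent by construction.
    """
    order = [c for c in FEATURE_ORDER if c in features.columns]
    order += [c for c in features.columns if c not in order]
    retained: list[str] = []
    corr = features[order].corr().abs()
    for col in order:
        if features[col].nunique() <= 1:
            # constant columns carry no signal and break Pearson r
            continue
        if all(not (corr.loc[col, kept] > threshold) for kept in retained):
            retained.append(col)
    return retained


class CategoricalEncoder:
    """ISUP grade as ordinal 1-5; location as one-hot with a reference level.

    The level mapping is frozen at fit time and reused at prediction;
    unseen location levels raise.
    """

    def __init__(self) -> None:
        self.location_levels_: list[str] | None = None

    def fit(self, table: pd.DataFrame,
            location_levels: list[str] | None = None) -> "CategoricalEncoder":
        if "location" in table.columns:
            # the level vocabulary may be fixed a priori (clinical lexicon);
            # otherwise it is learned from the fitted table
            self.location_levels_ = (sorted(location_levels) if location_levels
                                     else sorted(table["location"].astype(str)
                                                 .unique()))
        else:
            self.location_levels_ = None
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        if "isup_grade" in out.columns:
            out["isup_grade"] = out["isup_grade"].astype(int)
        if self.location_levels_ is not None:
            vals = out["location"].astype(str)
            unseen = set(vals) - set(self.location_levels_)
            if unseen:
                raise ValueError(f"unseen location level(s): {sorted(unseen)}")
            # reference level = first alphabetically; L-1 indicators
            for lev in self.location_levels_[1:]:
                out[f"location_{lev}"] = (vals == lev).astype(float)
            out = out.drop(columns=["location"])
        return out

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    if kind == "logistic_regression":
        return LogisticRegression(solver="saga", l1_ratio=params.pop("l1_ratio", 0.5),
                                  max_iter=5000, random_state=seed, **params)
    raise ValueError(f"unknown model kind '{kind}'; expected one of {MODEL_KINDS}")


def elastic_net_selection(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                          C: float = 1.0, l1_ratio: float = 0.5,
                          seed: int = 0) -> list[str]:
    """Features with nonzero coefficients in a single elastic-net fit."""
    est = LogisticRegression(solver="saga", C=C, l1_ratio=l1_ratio,
                             max_iter=5000, random_state=seed)
    est.fit(X, y)
    coef = est.coef_.ravel()
    return [f for f, c in zip(feature_names, coef) if abs(c) > 1e-8]


def select_features(kind: str, X: np.ndarray, y: np.ndarray,
                    feature_names: list[str], cv_folds: int = 5, seed: int = 0,
                    cumulative_importance: float = 0.95) -> list[str]:
    """Model-specific feature selection on training data only.

    Tree models: impurity importances averaged over CV folds; keep the
    smallest prefix of the importance ranking reaching
    ``cumulative_importance`` of the total. Logistic regression: nonzero
    coefficients of an elastic net tuned by CV AUC.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both classes present")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if kind in ("random_forest", "extra_trees"):
        imps = []
        for tr, _ in cv.split(X, y):
            est = _make_estimator(kind, {"n_estimators": 200}, seed)
            est.fit(X[tr], y[tr])
            imps.append(est.feature_importances_)
        mean_imp = np.mean(imps, axis=0)
        order = np.argsort(mean_imp)[::-1]
        cum = np.cumsum(mean_imp[order]) / mean_imp.sum()
        n_keep = int(np.searchsorted(cum, cumulative_importance) + 1)
        kept = sorted(order[:n_keep])
        return [feature_names[i] for i in kept]
    if kind == "logistic_regression":
        grid = GridSearchCV(
            _make_estimator(kind, {}, seed),
            {"C": DEFAULT_GRIDS[kind]["C"], "l1_ratio": [0.5, 1.0]},
            cv=cv, scoring="roc_auc", n_jobs=1)
        grid.fit(X, y)
        best = grid.best_estimator_
        coef = best.coef_.ravel()
        kept = [f for f, c in zip(feature_names, coef) if abs(c) > 1e-8]
        # an all-zero solution would leave an unusable model; fall back to all
        return kept if kept else list(feature_names)
    raise ValueError(f"unknown model kind '{kind}'")


@dataclass
class ModelSpec:
    """A fitted classifier plus everything needed to reproduce predictions."""

    kind: str
    selected_features: list[str]
    estimator: object
    encoder: CategoricalEncoder
    scaler_mean: pd.Series
    scaler_sd: pd.Series
    feature_names: list[str]            # post-filter features, canonical order
    standardized_input: bool            # True for logistic regression
    best_params: dict
    cv_auc: float
    seed: int
    operating_threshold: float = 0.5

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "selected_features": self.selected_features,
            "feature_names": self.feature_names,
            "standardized_input": self.standardized_input,
            "best_params": {k: (None if v is None else v)
                            for k, v in self.best_params.items()},
            "cv_auc": self.cv_auc,
            "seed": self.seed,
            "operating_threshold": self.operating_threshold,
        }


def tune_and_fit(kind: str, train: pd.DataFrame, label_col: str = "epe_label",
                 feature_cols: list[str] | None = None,
                 grid: dict | None = None, cv_folds: int = 5, seed: int = 0,
                 smote_k: int = 5, correlation_threshold: float = 0.95,
                 location_levels: list[str] | None = None) -> ModelSpec:
    """Run the full training pipeline on (already split) training rows.

    encode -> correlation filter -> standardize -> SMOTE -> select ->
    grid-search 5-fold CV maximizing AUC -> refit at the best setting.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind '{kind}'; expected one of {MODEL_KINDS}")
    y = train[label_col].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    encoder = CategoricalEncoder()
    raw_cols = feature_cols or [c for c in FEATURE_ORDER if c in train.columns]
    encoder.fit(train[raw_cols], location_levels=location_levels)
    enc = encoder.transform(train[raw_cols])
    enc = enc.select_dtypes(include=[np.number]).astype(float)
    feature_names = list(enc.columns)

    kept = correlation_filter(enc, threshold=correlation_threshold)
    enc = enc[kept]
    feature_names = kept

    mean = enc.mean()
    sd = enc.std(ddof=0).replace(0, 1.0)
    Z = ((enc - mean) / sd).to_numpy()

    # cap k at the available minority neighbours on small training sides
    n_min = int(np.bincount(y).min())
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    Xz, yb = smote_oversample(Z, y, k_neighbors=min(smote_k, n_min - 1),
                              seed=seed)
    Xraw = Xz * sd.to_numpy() + mean.to_numpy()   # back to native units

    standardized = kind == "logistic_regression"
    Xsel_all = Xz if standardized else Xraw
    selected = select_features(kind, Xsel_all, yb, feature_names,
                               cv_folds=cv_folds, seed=seed)
    sel_idx = [feature_names.index(f) for f in selected]
    X = Xsel_all[:, sel_idx]

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(_make_estimator(kind, {}, seed),
                          grid or DEFAULT_GRIDS[kind],
                          cv=cv, scoring="roc_auc", n_jobs=1, refit=True)
    search.fit(X, yb)
    return ModelSpec(
        kind=kind, selected_features=selected, estimator=search.best_estimator_,
        encoder=encoder, scaler_mean=mean, scaler_sd=sd,
        feature_names=feature_names, standardized_input=standardized,
        best_params=search.best_params_, cv_auc=float(search.best_score_),
        seed=seed)


def predict_probabilities(spec: ModelSpec, features: pd.DataFrame) -> np.ndarray:
    """Per-lesion EPE probabilities using stored encodings and selections."""
    wanted = set(spec.feature_names)
    if spec.encoder.location_levels_ is not None:
        wanted.add("location")
    enc = spec.encoder.transform(
        features[[c for c in features.columns if c in wanted]])
    missing = [f for f in spec.selected_features if f not in enc.columns]
    if missing:
        raise ValueError(f"missing selected feature column(s): {missing}")
    enc = enc.astype(float)
    sel = spec.selected_features
    if spec.standardized_input:
        enc = (enc[sel] - spec.scaler_mean[sel]) / spec.scaler_sd[sel]
    X = enc[sel].to_numpy()
    return spec.estimator.predict_proba(X)[:, 1]
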