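"""Alignment-free classification arm.

Eight classifier families over composition feature matrices: decision tree,
random forest, extra trees, gradient boosting (XGBoost binding), k-nearest
neighbour, Gaussian naive Bayes, logistic regression and support-vector
classifier. Training is deterministic per seed for every family. Model
selection uses exhaustive grid search scored by stratified five-fold
cross-validation; the production default is extra trees on amino-acid
composition.

Fold assignment is explicit and seed-driven: within each class the row
indices are shuffled by the seed and dealt round-robin to the k folds, so
the partition depends only on (n, y, k, seed).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import metrics as _metrics
from .metrics import MetricsReport

FAMILIES = (
    "decision_tree",
    "random_forest",
    "extra_trees",
    "gradient_boosting",
    "k_nearest_neighbor",
    "gaussian_naive_bayes",
    "logistic_regression",
    "support_vector",
)

#: Editable default hyperparameter grids for tuning each family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"max_depth": [None, 5, 10, 20], "criterion": ["gini", "entropy"]},
    "random_forest": {"n_estimators": [100, 200], "max_depth": [None, 10]},
    "extra_trees": {"n_estimators": [100, 200], "max_depth": [None, 10]},
    "gradient_boosting": {"n_estimators": [100, 200], "max_depth": [3, 6]},
    "k_nearest_neighbor": {"n_neighbors": [3, 5, 9]},
    "gaussian_naive_bayes": {"var_smoothing": [1e-9, 1e-7]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "support_vector": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameters and seed."""

    family: str = "extra_trees"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")

    def with_params(self, **params) -> "ClassifierSpec":
        return ClassifierSpec(self.family, {**self.params, **params}, self.seed)


def _build_estimator(spec: ClassifierSpec):
    p = dict(spec.params)
    s = spec.seed
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=s, **p)
    if spec.family == "random_forest":
        p.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=s, n_jobs=1, **p)
    if spec.family == "extra_trees":
        p.setdefault("n_estimators", 200)
        return ExtraTreesClassifier(random_state=s, n_jobs=1, **p)
    if spec.family == "gradient_boosting":
        p.setdefault("n_estimators", 100)
        return XGBClassifier(
            random_state=s, n_jobs=1, eval_metric="logloss", verbosity=0, **p
        )
    if spec.family == "k_nearest_neighbor":
        p.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**p)
    if spec.family == "gaussian_naive_bayes":
        return GaussianNB(**p)
    if spec.family == "logistic_regression":
        p.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=s, **p)
    if spec.family == "support_vector":
        # SVC has no native probabilities; Platt-calibrate on internal folds
        return CalibratedClassifierCV(SVC(random_state=s, **p), ensemble=False, cv=3)
    raise AssertionError(spec.family)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int8).tobytes())
    return h.hexdigest()


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature columns it was trained on."""

    spec: ClassifierSpec
    estimator: object
    feature_names: list[str]
    train_fingerprint: str

    def _check_columns(self, X: pd.DataFrame) -> None:
        cols = list(X.columns)
        if cols != self.feature_names:
            missing = [c for c in self.feature_names if c not in cols]
            extra = [c for c in cols if c not in self.feature_names]
            raise ValueError(
                "feature columns do not match the training matrix; "
                f"missing={missing[:5]}, unexpected={extra[:5]}"
            )


def _validate_xy(X: pd.DataFrame, y: Sequence[int]) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame with named feature columns")
    yb = np.asarray(y)
    if yb.dtype.kind in "USO":
        yb = (yb == "TF").astype(int)
    yb = yb.astype(int)
    if X.shape[0] != len(yb):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(yb)} labels")
    if np.isnan(X.to_numpy(dtype=float)).any():
        raise ValueError("X contains NaN values")
    if len(np.unique(yb)) < 2:
        raise ValueError("y must contain both classes")
    return X, yb


def train_classifier(X: pd.DataFrame, y: Sequence, spec: ClassifierSpec) -> TrainedModel:
    """Fit a classifier of the requested family on a labelled feature matrix.

    ``y`` may be TF/nonTF strings or 0/1 integers (TF = 1 = positive).
    """
    X, yb = _validate_xy(X, y)
    est = _build_estimator(spec)
    est.fit(X.to_numpy(dtype=float), yb)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(X.columns),
        train_fingerprint=_fingerprint(X.to_numpy(dtype=float), yb),
    )


def predict_score(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Positive-class probability per row, in [0, 1]; higher = more TF-like."""
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame with named feature columns")
    model._check_columns(X)
    proba = model.estimator.predict_proba(X.to_numpy(dtype=float))
    pos_col = list(model.estimator.classes_).index(1)
    return np.clip(proba[:, pos_col], 0.0, 1.0)


def stratified_fold_indices(y: Sequence, k: int, seed: int) -> np.ndarray:
    """Fold id (0..k-1) per row: seeded within-class shuffle, round-robin deal."""
    yb = np.asarray(y)
    if yb.dtype.kind in "USO":
        yb = (yb == "TF").astype(int)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(yb), dtype=int)
    for cls in np.unique(yb):
        idx = np.flatnonzero(yb == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} members; need at least k={k}")
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


@dataclass
class CVResult:
    """Per-fold metric reports and their arithmetic mean."""

    fold_reports: list[MetricsReport]
    mean_report: MetricsReport

    @property
    def k(self) -> int:
        return len(self.fold_reports)


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    def m(attr):
        vals = [getattr(r, attr) for r in reports]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    return MetricsReport(
        sensitivity=m("sensitivity"),
        specificity=m("specificity"),
        accuracy=m("accuracy"),
        f1=m("f1"),
        kappa=m("kappa"),
        mcc=m("mcc"),
        auc=m("auc"),
    )


def cross_validate(
    X: pd.DataFrame, y: Sequence, spec: ClassifierSpec, k: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold cross-validation.

    Each fold serves as the test set exactly once; the reported performance
    is the arithmetic mean of the per-fold reports. Fold metrics are always
    computed on rows unseen by that fold's fit.
    """
    X, yb = _validate_xy(X, y)
    folds = stratified_fold_indices(yb, k, seed)
    reports = []
    for fold in range(k):
        tr = folds != fold
        te = ~tr
        model = train_classifier(X.loc[tr], yb[tr], spec)
        scores = predict_score(model, X.loc[te])
        pred = (scores >= 0.5).astype(int)
        reports.append(_metrics.evaluate(yb[te], pred, scores))
    return CVResult(fold_reports=reports, mean_report=_mean_report(reports))


def grid_search(
    X: pd.DataFrame,
    y: Sequence,
    spec: ClassifierSpec,
    grid: dict[str, list],
    k: int = 5,
    metric: str = "auc",
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by stratified k-fold CV.

    Evaluates every combination in the Cartesian product of ``grid`` and
    returns (best_params, table). Ties go to the first combination in the
    deterministic enumeration order (sorted parameter names, listed values
    in order). ``metric`` is one of auc, mcc, accuracy.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if metric not in ("auc", "mcc", "accuracy"):
        raise ValueError("metric must be one of auc, mcc, accuracy")
    names = sorted(grid)
    rows = []
    best_params, best_score = None, -np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        cv = cross_validate(X, y, spec.with_params(**params), k=k, seed=spec.seed)
        score = getattr(
            cv.mean_report, {"auc": "auc", "mcc": "mcc", "accuracy": "accuracy"}[metric]
        )
        rows.append({**params, f"mean_{metric}": score})
        if score > best_score:
            best_params, best_score = params, score
    return best_params, pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist spec, fitted estimator and feature names in one archive."""
    joblib.dump(
        {
            "format_version": 1,
            "spec": model.spec,
            "estimator": model.estimator,
            "feature_names": model.feature_names,
            "train_fingerprint": model.train_fingerprint,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        spec=blob["spec"],
        estimator=blob["estimator"],
        feature_names=blob["feature_names"],
        train_fingerprint=blob["train_fingerprint"],
    )
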