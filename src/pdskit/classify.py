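"""Classifier training, evaluation, importance ranking and clinical calibration.

Selected pathway scores feed seven classifiers — LDA, SVM (RBF), random
forest (RF), a pruned decision tree (RPART), nearest shrunken centroids
(PAM), L2-regularized logistic regression (LOG) and gradient boosting (GBM).
Each is tuned over a small fixed grid by stratified n-fold cross-validation
maximizing AUC, refitted on the full training split and evaluated on the
stratified hold-out. Reported metrics: AUC (trapezoidal, threshold-free) and
sensitivity / specificity / F1 / balanced accuracy at probability 0.5, with
the non-control phenotype as the positive class.

Feature importance is permutation-based (mean AUC drop, negative drops
floored at 0, max-normalized to 1) so it is comparable across the seven
model families. The clinical-calibration step min-max scales covariates to
[0, 1] using training-set extremes and compares three models: pathways only,
clinical only, and combined.

All randomness (splits, folds, permutations, classifier internals) flows
from explicit integer seeds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import MetricError, SplitError

logger = logging.getLogger(__name__)

ALGORITHM_ORDER = ["LDA", "SVM", "RF", "RPART", "PAM", "LOG", "GBM"]
METRIC_NAMES = ["auc", "f1", "balanced_accuracy", "sensitivity", "specificity"]


def encode_labels(labels, control_label: str) -> np.ndarray:
    """0/1 encoding with the non-control phenotype as the positive class."""
    labels = np.asarray(labels)
    return (labels != control_label).astype(int)


# --------------------------------------------------------------------------
# splitting

@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0


@dataclass
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0


def split_train_test(sample_ids, labels, spec: SplitSpec) -> tuple[list, list]:
    """Seeded stratified partition of samples into train and hold-out sets."""
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 5).any():
        raise SplitError(f"need >=5 samples per class, got {counts.to_dict()}")
    train, test = train_test_split(
        sample_ids,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    by_id = dict(zip(sample_ids, labels))
    for part, name in ((train, "train"), (test, "test")):
        if len({by_id[s] for s in part}) < 2:
            raise SplitError(f"class absent from {name} partition")
    return list(train), list(test)


# --------------------------------------------------------------------------
# PAM: nearest shrunken centroids

class NearestShrunkenCentroids(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroid classifier.

    Class centroids of features standardized by pooled within-class standard
    deviation (plus the median offset s0) are soft-thresholded toward the
    overall centroid by ``threshold``; classification is by the smallest
    standardized squared distance to a shrunken centroid, with class-prior
    correction. At ``threshold=0`` this is plain nearest-centroid
    classification on standardized features.
    """

    def __init__(self, threshold: float = 0.0):
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        n, p = X.shape
        K = len(self.classes_)
        nk = np.bincount(codes)
        overall = X.mean(axis=0)
        centroids = np.vstack([X[codes == k].mean(axis=0) for k in range(K)])
        ss = np.zeros(p)
        for k in range(K):
            ss += ((X[codes == k] - centroids[k]) ** 2).sum(axis=0)
        dof = max(n - K, 1)
        s = np.sqrt(ss / dof)
        s0 = float(np.median(s))
        if s0 <= 0:
            s0 = 1e-12
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        denom = mk[:, None] * (s + s0)
        d = (centroids - overall) / denom
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.threshold, 0.0)
        self.centroids_ = overall + denom * d_shrunk
        self.s_ = s
        self.s0_ = s0
        self.priors_ = nk / n
        self.max_shrinkage_ = float(np.abs(d).max())
        return self

    def _discriminant(self, X):
        X = np.asarray(X, dtype=float)
        denom2 = (self.s_ + self.s0_) ** 2
        delta = np.stack([(((X - c) ** 2) / denom2).sum(axis=1) for c in self.centroids_], axis=1)
        return delta - 2.0 * np.log(self.priors_)

    def predict(self, X):
        return self.classes_[np.argmin(self._discriminant(X), axis=1)]

    def predict_proba(self, X):
        z = -0.5 * self._discriminant(X)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# estimators and tuning grids

def _estimator_and_grid(algorithm: str, n_features: int, seed: int, X=None, y=None):
    p = max(n_features, 1)
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis(), {}
    if algorithm == "SVM":
        # sigmoid-calibrated RBF SVM (probabilities needed for the 0.5 threshold)
        return (
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), method="sigmoid", cv=3, ensemble=False),
            {"estimator__C": [0.25, 1.0, 4.0], "estimator__gamma": [1.0 / p, 2.0 / p]},
        )
    if algorithm == "RF":
        mtry = sorted({min(p, math.ceil(math.sqrt(p))), min(p, math.ceil(p / 3)), p})
        return RandomForestClassifier(n_estimators=100, random_state=seed), {"max_features": mtry}
    if algorithm == "RPART":
        return DecisionTreeClassifier(random_state=seed), {"ccp_alpha": [0.001, 0.01, 0.1]}
    if algorithm == "PAM":
        max_shrink = NearestShrunkenCentroids(threshold=0.0).fit(X, y).max_shrinkage_ if X is not None else 1.0
        return NearestShrunkenCentroids(), {"threshold": [float(t) for t in np.linspace(0.0, max_shrink, 10)]}
    if algorithm == "LOG":
        # light L2 (lambda = 1e-3) keeps separable data stable
        return LogisticRegression(C=1000.0, max_iter=5000), {}
    if algorithm == "GBM":
        return (
            GradientBoostingClassifier(learning_rate=0.1, random_state=seed),
            {"n_estimators": [50, 100, 200], "max_depth": [1, 2, 3]},
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _param_combos(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def positive_scores(estimator, X) -> np.ndarray:
    proba = estimator.predict_proba(np.asarray(X, dtype=float))
    idx = int(np.nonzero(estimator.classes_ == 1)[0][0])
    return proba[:, idx]


def _threshold_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {
        "f1": f1,
        "balanced_accuracy": (sen + spec) / 2.0,
        "sensitivity": sen,
        "specificity": spec,
    }


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Point metrics from a confusion table (no AUC: threshold-free)."""
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return {
        "sensitivity": sen,
        "specificity": spec,
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        "balanced_accuracy": (sen + spec) / 2.0,
    }


# --------------------------------------------------------------------------
# training with grid search

@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    selected_params: dict
    cv_metrics: dict[str, float]
    feature_names: list[str]


def train_model(algorithm: str, X, y, cv: CVConfig) -> TrainedModel:
    """Grid search by stratified n-fold CV maximizing AUC, then refit.

    The fold count is reduced (with a warning) when it exceeds the smallest
    class count in the training data.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"f{i}" for i in range(np.shape(X)[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    min_class = int(np.bincount(y).min())
    n_folds = cv.n_folds
    if n_folds > min_class:
        n_folds = max(2, min_class)
        logger.warning("%s: reducing CV folds from %d to %d (smallest class has %d samples)", algorithm, cv.n_folds, n_folds, min_class)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv.seed)
    folds = list(skf.split(X, y))

    base, grid = _estimator_and_grid(algorithm, X.shape[1], cv.seed, X=X, y=y)
    best_auc, best_params, best_metrics = -np.inf, None, None
    for params in _param_combos(grid):
        fold_rows = []
        for tr, va in folds:
            est = clone(base).set_params(**params).fit(X[tr], y[tr])
            s = positive_scores(est, X[va])
            row = _threshold_metrics(y[va], s)
            row["auc"] = roc_auc_score(y[va], s) if len(np.unique(y[va])) == 2 else np.nan
            fold_rows.append(row)
        means = {m: float(np.nanmean([r[m] for r in fold_rows])) for m in METRIC_NAMES}
        if means["auc"] > best_auc + 1e-12:
            best_auc, best_params, best_metrics = means["auc"], params, means
    estimator = clone(base).set_params(**best_params).fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=estimator,
        selected_params=best_params,
        cv_metrics=best_metrics,
        feature_names=feature_names,
    )


# --------------------------------------------------------------------------
# evaluation

@dataclass
class EvalResult:
    metrics: dict[str, float]
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold


def evaluate(model, X_test, y_test) -> EvalResult:
    """Hold-out metrics from continuous scores; AUC is trapezoidal over the
    ROC points, the point metrics use the 0.5 probability threshold."""
    estimator = model.estimator if isinstance(model, TrainedModel) else model
    y_test = np.asarray(y_test, dtype=int)
    if len(np.unique(y_test)) < 2:
        raise MetricError("AUC undefined: test set contains a single class")
    scores = positive_scores(estimator, X_test)
    fpr, tpr, thresholds = roc_curve(y_test, scores)
    metrics = _threshold_metrics(y_test, scores)
    metrics["auc"] = float(trapezoid_auc(fpr, tpr))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return EvalResult(metrics=metrics, roc_points=roc_points)


def variable_importance(model, X, y, n_repeats: int = 20, seed: int = 0) -> pd.Series:
    """Permutation importance: mean AUC drop per shuffled feature, negative
    drops floored at 0, normalized so the maximum equals 1."""
    estimator = model.estimator if isinstance(model, TrainedModel) else model
    names = list(X.columns) if isinstance(X, pd.DataFrame) else (
        model.feature_names if isinstance(model, TrainedModel) else [f"f{i}" for i in range(np.shape(X)[1])]
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    baseline = roc_auc_score(y, positive_scores(estimator, X))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        aucs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            aucs.append(roc_auc_score(y, positive_scores(estimator, Xp)))
        drops[j] = max(0.0, baseline - float(np.mean(aucs)))
    if drops.max() > 0:
        drops = drops / drops.max()
    return pd.Series(drops, index=names)


# --------------------------------------------------------------------------
# the multi-algorithm report

@dataclass
class PerformanceReport:
    cv_metrics: dict[str, dict[str, float]]      # algorithm -> metric -> value
    test_metrics: dict[str, dict[str, float]]
    roc_points: dict[str, pd.DataFrame]
    importance: dict[str, pd.Series]
    selected_params: dict[str, dict]
    models: dict[str, TrainedModel] = field(default_factory=dict)

    def best_algorithm(self, metric: str = "auc") -> str:
        return select_best_model(self.test_metrics, metric)


def select_best_model(metrics_by_algorithm: dict[str, dict[str, float]], metric: str = "auc") -> str:
    """Argmax over algorithms; ties break on the fixed algorithm order."""
    best, best_val = None, -np.inf
    for alg in ALGORITHM_ORDER:
        if alg not in metrics_by_algorithm:
            continue
        val = metrics_by_algorithm[alg][metric]
        if val > best_val + 1e-12:
            best, best_val = alg, val
    if best is None:
        raise ValueError("no algorithm metrics supplied")
    return best


def run_all_algorithms(
    X_train,
    y_train,
    X_test,
    y_test,
    cv: CVConfig,
    algorithms: list[str] | None = None,
    importance_repeats: int = 20,
) -> PerformanceReport:
    """Train, evaluate and rank importance for each requested algorithm."""
    algorithms = algorithms or ALGORITHM_ORDER
    cv_metrics, test_metrics, rocs, importances, params, models = {}, {}, {}, {}, {}, {}
    for alg in algorithms:
        trained = train_model(alg, X_train, y_train, cv)
        ev = evaluate(trained, X_test, y_test)
        cv_metrics[alg] = trained.cv_metrics
        test_metrics[alg] = ev.metrics
        rocs[alg] = ev.roc_points
        importances[alg] = variable_importance(trained, X_train, y_train, n_repeats=importance_repeats, seed=cv.seed)
        params[alg] = trained.selected_params
        models[alg] = trained
        logger.info("%s: CV AUC %.3f, test AUC %.3f", alg, trained.cv_metrics["auc"], ev.metrics["auc"])
    return PerformanceReport(
        cv_metrics=cv_metrics,
        test_metrics=test_metrics,
        roc_points=rocs,
        importance=importances,
        selected_params=params,
        models=models,
    )


# --------------------------------------------------------------------------
# clinical calibration

def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric passthrough + one-hot encoding of categoricals (sorted column
    order for determinism)."""
    if clinical.shape[1] == 0:
        return clinical.copy()
    encoded = pd.get_dummies(clinical, dtype=float)
    return encoded[sorted(encoded.columns)]


def min_max_scale(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Scale each column to [0, 1] by training-set extremes; test values are
    clipped into [0, 1]. Constant columns are dropped with a warning."""
    lo, hi = train.min(axis=0), train.max(axis=0)
    constant = list(lo.index[(hi - lo) <= 0])
    if constant:
        logger.warning("dropping constant clinical covariates: %s", constant)
    keep = [c for c in train.columns if c not in constant]
    span = (hi - lo)[keep]
    train_s = (train[keep] - lo[keep]) / span
    test_s = None
    if test is not None:
        test_s = ((test[keep] - lo[keep]) / span).clip(0.0, 1.0)
    return train_s, test_s


@dataclass
class CalibrationReport:
    """Pathway-only, clinical-only and combined models on shared splits."""

    algorithm: str
    reports: dict[str, tuple[TrainedModel, EvalResult]]  # keys: pathway, clinical, combined

    def aucs(self) -> dict[str, float]:
        return {name: ev.metrics["auc"] for name, (_, ev) in self.reports.items()}


def build_combined_models(
    pds_selected: pd.DataFrame,
    clinical: pd.DataFrame,
    y,
    train_ids,
    test_ids,
    cv: CVConfig,
    algorithm: str,
) -> CalibrationReport:
    """Three-model confounding comparison.

    ``pds_selected`` is samples × selected pathways; ``clinical`` is samples ×
    covariates (numeric or categorical). Covariates are min-max scaled to
    [0, 1] on training extremes so they are commensurate with PDS scores.
    With an empty clinical table only the pathway model is built.
    """
    y = pd.Series(np.asarray(y, dtype=int), index=pds_selected.index)
    clin = encode_clinical(clinical.loc[pds_selected.index] if len(clinical) else clinical)
    if clin.shape[1]:
        clin_train, clin_test = min_max_scale(clin.loc[train_ids], clin.loc[test_ids])
    else:
        clin_train = clin_test = pd.DataFrame(index=train_ids)

    designs = {"pathway": (pds_selected.loc[train_ids], pds_selected.loc[test_ids])}
    if clin_train.shape[1]:
        designs["clinical"] = (clin_train, clin_test)
        designs["combined"] = (
            pd.concat([pds_selected.loc[train_ids], clin_train], axis=1),
            pd.concat([pds_selected.loc[test_ids], clin_test], axis=1),
        )
    else:
        logger.warning("no usable clinical covariates; building the pathway model only")

    reports = {}
    for name, (Xtr, Xte) in designs.items():
        trained = train_model(algorithm, Xtr, y.loc[train_ids].to_numpy(), cv)
        reports[name] = (trained, evaluate(trained, Xte, y.loc[test_ids].to_numpy()))
    return CalibrationReport(algorithm=algorithm, reports=reports)


def correlation_matrix(clinical_scaled: pd.DataFrame, pds_selected: pd.DataFrame):
    """Pearson correlations over all pairs of clinical + selected-pathway
    variables. Zero-variance variables get correlation 0 (flagged); the
    diagonal is 1 and the matrix symmetric."""
    combined = pd.concat([clinical_scaled, pds_selected], axis=1)
    if combined.shape[0] < 3:
        raise ValueError("correlation matrix needs at least 3 samples")
    X = combined.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    flagged = [c for c, s in zip(combined.columns, sd) if s <= 1e-12]
    safe = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - X.mean(axis=0)) / safe
    corr = Z.T @ Z / X.shape[0]
    corr[sd <= 1e-12, :] = 0.0
    corr[:, sd <= 1e-12] = 0.0
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=combined.columns, columns=combined.columns)
    return frame, flagged
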