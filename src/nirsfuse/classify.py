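"""Two independent one-vs-rest binary decoders with k-fold cross-validation.

The two tasks are detectors: MD (mental drawing, label 2) against everything
else, and SN (spatial navigation, label 3) against everything else.  Each
runs separately per hemoglobin stream (HbO / HbR) and per feature set
(classical / fused).

Learners are scikit-learn estimators behind a uniform spec:

* ``knn``         k-nearest neighbours, k = 10, Euclidean metric, uniform
                  weights (majority vote; vote ties resolve toward the
                  negative class, distance ties toward earlier training rows)
* ``lda``         shared-covariance Gaussian discriminant (SVD solver, which
                  tolerates singular pooled covariance)
* ``gbm_light``   LightGBM gradient-boosted trees, 50 rounds
* ``gbm_xtreme``  XGBoost gradient-boosted trees, 50 rounds

KNN and LDA see standardized features (fit on the training fold only);
tree ensembles consume raw features.  Boosted backends are optional
dependencies — a missing backend raises an error naming the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

LEARNER_KINDS = ("lda", "knn", "gbm_light", "gbm_xtreme")
TASKS = {"MD": 2, "SN": 3}


@dataclass
class LearnerSpec:
    """Validated learner choice + hyperparameters."""

    kind: str = "knn"
    knn_k: int = 10
    knn_metric: str = "euclidean"
    knn_weights: str = "uniform"
    rounds: int = 50  # boosting rounds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; choose from {LEARNER_KINDS}")
        if self.kind == "knn" and self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.kind in ("gbm_light", "gbm_xtreme") and self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class CVReport:
    """Cross-validation outcome for one (task, stream, feature set, learner)."""

    task: str
    fold_accuracies: list[float]
    confusions: list[np.ndarray]  # one 2x2 matrix per fold, rows=true, cols=pred
    seed: int
    stream: str = ""
    feature_set: str = ""
    learner: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def make_binary_task(labels: np.ndarray, positive_class: int) -> np.ndarray:
    """1 for the chosen task label, 0 for rest *and* the other task."""
    labels = np.asarray(labels, dtype=int)
    if positive_class not in (2, 3):
        raise ValueError(f"positive_class must be 2 (MD) or 3 (SN), got {positive_class}")
    y = (labels == positive_class).astype(int)
    if y.sum() == 0:
        raise ValueError(f"no examples of positive class {positive_class} in labels")
    return y


def build_learner(spec: LearnerSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    if spec.kind == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "knn",
                    KNeighborsClassifier(
                        n_neighbors=spec.knn_k, metric=spec.knn_metric, weights=spec.knn_weights
                    ),
                ),
            ]
        )
    if spec.kind == "lda":
        return Pipeline(
            [("scale", StandardScaler()), ("lda", LinearDiscriminantAnalysis(solver="svd"))]
        )
    if spec.kind == "gbm_light":
        try:
            from lightgbm import LGBMClassifier
        except ImportError as e:  # pragma: no cover
            raise ImportError("learner 'gbm_light' requires the optional dependency lightgbm") from e
        return LGBMClassifier(
            n_estimators=spec.rounds, random_state=spec.seed, verbose=-1, min_child_samples=5
        )
    if spec.kind == "gbm_xtreme":
        try:
            from xgboost import XGBClassifier
        except ImportError as e:  # pragma: no cover
            raise ImportError("learner 'gbm_xtreme' requires the optional dependency xgboost") from e
        return XGBClassifier(n_estimators=spec.rounds, random_state=spec.seed, verbosity=0)
    raise ValueError(spec.kind)


# thin named wrappers over the estimator surface -----------------------------

def train_knn(X: np.ndarray, y: np.ndarray, spec: LearnerSpec | None = None):
    spec = spec or LearnerSpec(kind="knn")
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if spec.knn_k > X.shape[0]:
        raise ValueError(f"k = {spec.knn_k} exceeds training size {X.shape[0]}")
    return build_learner(spec).fit(X, y)


def predict_knn(model, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def train_lda(X: np.ndarray, y: np.ndarray):
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if np.any(counts[np.unique(y)] < 2):
        raise ValueError("LDA needs >= 2 rows per class")
    return build_learner(LearnerSpec(kind="lda")).fit(X, y)


def predict_lda(model, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def train_boosted(X: np.ndarray, y: np.ndarray, backend: str = "gbm_light", rounds: int = 50, seed: int = 0):
    spec = LearnerSpec(kind=backend, rounds=rounds, seed=seed)
    return build_learner(spec).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: LearnerSpec,
    k_folds: int = 5,
    seed: int = 0,
    task: str = "",
) -> CVReport:
    """Seeded stratified k-fold CV; folds are disjoint and exhaustive.

    Accuracy is the per-fold fraction correct, averaged over folds.  A class
    with fewer rows than folds is an error (stratification impossible).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to cross-validate")
    if counts.min() < k_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has only {counts.min()} rows, fewer than k_folds = {k_folds}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs, cms = [], []
    base = build_learner(spec)
    for train_idx, test_idx in skf.split(X, y):
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper mis-detects feature names on ndarray input
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            model = clone(base).fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        cms.append(confusion_matrix(y[test_idx], pred, labels=[0, 1]))
    return CVReport(task=task, fold_accuracies=accs, confusions=cms, seed=seed, learner=spec.kind)


def evaluate_tasks(
    table: pd.DataFrame,
    specs: list[LearnerSpec],
    k_folds: int = 5,
    seed: int = 0,
) -> list[CVReport]:
    """Run both binary tasks on one feature table for every learner spec."""
    from .features_classic import as_feature_matrix

    X, labels, _ = as_feature_matrix(table)
    reports = []
    for task, pos in TASKS.items():
        y = make_binary_task(labels, pos)
        for spec in specs:
            rep = cross_validate(X, y, spec, k_folds=k_folds, seed=seed, task=task)
            rep.stream = table.attrs.get("stream", "")
            rep.feature_set = table.attrs.get("feature_set", "")
            reports.append(rep)
    return reports


def reports_frame(reports: list[CVReport]) -> pd.DataFrame:
    """Long-format fold table: task,stream,feature_set,learner,fold,accuracy."""
    rows = [
        {
            "task": r.task,
            "stream": r.stream,
            "feature_set": r.feature_set,
            "learner": r.learner,
            "fold": i,
            "accuracy": a,
        }
        for r in reports
        for i, a in enumerate(r.fold_accuracies)
    ]
    return pd.DataFrame(rows)
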