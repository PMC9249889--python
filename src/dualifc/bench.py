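"""Stratified cross-validation benchmark of seven conventional classifiers.

Seven standard models (logistic regression, k-nearest neighbors, RBF SVC,
random forest, gradient boosting, Gaussian naive Bayes, Gaussian process)
are evaluated on the 55-feature panel under stratified 4-fold CV. Folds are
stratified on (subject, class) so every fold holds about a quarter of each
subject's cells; feature z-scoring is fitted on training folds only, so no
statistics of the held-out fold leak into the model.

Metrics follow the balanced convention: balanced accuracy is the arithmetic
mean of per-class recall, and precision/recall/F1 are macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureTable
from .texture import zscore_columns

MODEL_NAMES = (
    "logistic_regression",
    "k_nearest_neighbors",
    "svc_rbf",
    "random_forest",
    "gradient_boosting",
    "naive_bayes",
    "gaussian_process",
)


def stratified_folds(
    labels: np.ndarray,
    k: int = 4,
    seed: int = 0,
    subjects: np.ndarray | None = None,
) -> np.ndarray:
    """Fold assignment (0..k-1 per cell), stratified on class and subject.

    Each subject's cells are shuffled and dealt into k nearly equal parts;
    the folds that receive a subject's remainder cells rotate per class so
    per-fold class counts stay within one of exact proportionality for
    class-balanced designs.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    if subjects is None:
        subjects = np.zeros(n, dtype=int)
    subjects = np.asarray(subjects)

    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=int)
    class_offset = {c: 0 for c in classes}
    keys = sorted(set(zip(subjects.tolist(), labels.tolist())))
    for subject, label in keys:
        idx = np.flatnonzero((subjects == subject) & (labels == label))
        rng.shuffle(idx)
        base, rem = divmod(len(idx), k)
        offset = class_offset[label]
        sizes = [base + (1 if (f - offset) % k < rem else 0) for f in range(k)]
        class_offset[label] = (offset + rem) % k
        start = 0
        for f, size in enumerate(sizes):
            folds[idx[start : start + size]] = f
            start += size
    assert (folds >= 0).all()
    return folds


def confusion(y_true: np.ndarray, y_pred: np.ndarray, classes) -> np.ndarray:
    """Confusion matrix with rows = truth, columns = prediction."""
    return _sk_confusion(y_true, y_pred, labels=list(classes))


def metrics(cm: np.ndarray) -> dict[str, float]:
    """Macro precision/recall/F1 and balanced accuracy from a confusion matrix.

    Balanced accuracy is the arithmetic mean of the class-specific
    accuracies (per-class recall).
    """
    cm = np.asarray(cm, dtype=float)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("confusion matrix has an empty truth row")
    col_sums = cm.sum(axis=0)
    diag = np.diag(cm)
    recall = diag / row_sums
    precision = np.where(col_sums > 0, diag / np.where(col_sums == 0, 1, col_sums), 0.0)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom == 0, 1, denom), 0.0)
    return {
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
        "balanced_accuracy": float(recall.mean()),
    }


@dataclass
class CVResult:
    """Per-fold confusion matrices and metric summaries for one model."""

    model: str
    classes: tuple[str, ...]
    fold_confusions: list[np.ndarray]
    fold_metrics: list[dict[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fold_metrics:
            self.fold_metrics = [metrics(cm) for cm in self.fold_confusions]

    @property
    def k(self) -> int:
        return len(self.fold_confusions)

    def mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.fold_metrics]))

    @property
    def mean_f1(self) -> float:
        return self.mean("f1")

    @property
    def mean_balanced_accuracy(self) -> float:
        return self.mean("balanced_accuracy")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "classes": list(self.classes),
            "seed": self.seed,
            "fold_confusions": [cm.tolist() for cm in self.fold_confusions],
            "fold_metrics": self.fold_metrics,
            "mean_metrics": {
                key: self.mean(key)
                for key in ("precision", "recall", "f1", "balanced_accuracy")
            },
        }


def default_models(seed: int = 0, gp_subsample: int = 2000) -> dict[str, object]:
    """The seven benchmark classifiers with fixed, reproducible settings.

    The Gaussian process classifier is O(n^3) in training-set size; its
    training set is capped at ``gp_subsample`` points (see
    :func:`benchmark`).
    """
    return {
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "k_nearest_neighbors": KNeighborsClassifier(n_neighbors=15),
        "svc_rbf": SVC(kernel="rbf", random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        "gaussian_process": GaussianProcessClassifier(random_state=seed),
    }


def benchmark(
    table: FeatureTable,
    folds: np.ndarray,
    models: dict[str, object] | None = None,
    seed: int = 0,
    gp_subsample: int = 2000,
) -> dict[str, CVResult]:
    """Fit/evaluate each model per CV fold on the raw (un-normalized) table.

    Z-score parameters are estimated on the training folds only and applied
    to the held-out fold. Raises on non-finite features, listing the
    offending columns.
    """
    if table.state != "raw":
        raise ValueError("benchmark expects a raw table; z-scoring is done per fold")
    X = table.values
    bad = ~np.isfinite(X).all(axis=0)
    if bad.any():
        from .registry import FEATURE_NAMES

        names = [FEATURE_NAMES[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"non-finite values in feature columns: {names}")
    y = table.labels
    classes = tuple(sorted(np.unique(y)))
    folds = np.asarray(folds)
    if models is None:
        models = default_models(seed=seed, gp_subsample=gp_subsample)

    results: dict[str, CVResult] = {}
    rng = np.random.default_rng(seed)
    for name, model in models.items():
        fold_cms = []
        for f in sorted(np.unique(folds)):
            train, test = folds != f, folds == f
            X_train, mean, sigma = zscore_columns(X[train])
            X_test, _, _ = zscore_columns(X[test], mean, sigma)
            y_train = y[train]
            if name == "gaussian_process" and len(y_train) > gp_subsample:
                pick = rng.choice(len(y_train), size=gp_subsample, replace=False)
                X_fit, y_fit = X_train[pick], y_train[pick]
            else:
                X_fit, y_fit = X_train, y_train
            est = clone(model)
            est.fit(X_fit, y_fit)
            y_pred = est.predict(X_test)
            fold_cms.append(confusion(y[test], y_pred, classes))
        results[name] = CVResult(
            model=name, classes=classes, fold_confusions=fold_cms, seed=seed
        )
    return results


def holdout_split(
    labels: np.ndarray, test_fraction: float = 0.2, seed: int = 0,
    subjects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optional stratified 80/20 train/test split (per subject and class)."""
    k = int(round(1.0 / test_fraction))
    folds = stratified_folds(labels, k=k, seed=seed, subjects=subjects)
    test = folds == 0
    return ~test, test
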