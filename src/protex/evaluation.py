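"""Stratified cross-validation harness for structural-class experiments.

The harness keeps the resampling protocol honest: folds are stratified,
SMOTE balancing is applied inside each iteration to the training folds
only, and every fold records how many synthetic instances it added so the
absence of synthetic data in test folds can be audited structurally.

Classifier internals are delegated to scikit-learn; the registry pins the
parameter choices used throughout (polynomial-kernel SVM with C = 1,
AdaBoost over full decision trees, a 100-tree random forest, brute-force
KNN without distance weighting, Gaussian naive Bayes), each behind a
min-max normalisation step fitted on the training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .resampling import balance_training_set

__all__ = [
    "MetricReport",
    "FoldResult",
    "ExperimentResult",
    "CLASSIFIER_NAMES",
    "make_classifier",
    "stratified_folds",
    "confusion_counts",
    "compute_metrics",
    "run_class_experiment",
]


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, sensitivity, specificity and F1, all in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float


@dataclass
class FoldResult:
    test_indices: np.ndarray
    n_synthetic: int
    confusion: np.ndarray
    report: MetricReport


@dataclass
class ExperimentResult:
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def mean_report(self) -> MetricReport:
        return MetricReport(
            accuracy=float(np.mean([f.report.accuracy for f in self.folds])),
            sensitivity=float(np.mean([f.report.sensitivity for f in self.folds])),
            specificity=float(np.mean([f.report.specificity for f in self.folds])),
            f1=float(np.mean([f.report.f1 for f in self.folds])),
        )


CLASSIFIER_NAMES = ("knn", "nb", "svm", "adaboost", "rf")


def make_classifier(name: str, seed: int = 0):
    """Pipeline of min-max normalisation plus one of the supported classifiers."""
    if name == "svm":
        clf = SVC(kernel="poly", degree=1, C=1.0, random_state=seed)
    elif name == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5, weights="uniform", algorithm="brute")
    elif name == "nb":
        clf = GaussianNB()
    elif name == "adaboost":
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=50,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}; supported: {CLASSIFIER_NAMES}")
    return Pipeline([("scale", MinMaxScaler()), ("clf", clf)])


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into stratified folds (per-class counts within 1).

    Raises
    ------
    ValueError
        Listing any class with fewer members than ``n_folds``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    offenders = [str(c) for c, n in zip(classes, counts) if n < n_folds]
    if offenders:
        raise ValueError(
            f"classes with fewer than {n_folds} members cannot be stratified: {offenders}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def confusion_counts(y_true, y_pred, classes=None) -> np.ndarray:
    """k x k confusion matrix, rows true class, columns predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def compute_metrics(cm: np.ndarray, positive_index: int = 1) -> MetricReport:
    """Metrics from a confusion matrix, in percent.

    Binary matrices use the plain positive-class convention (row/column
    ``positive_index`` is the positive class): sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), F1 of the positive class. Multi-class
    matrices report class-support-weighted one-vs-rest averages.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = 100.0 * np.trace(cm) / total

    k = cm.shape[0]
    if k == 2:
        class_range = [positive_index]
        weights = np.array([1.0])
    else:
        class_range = list(range(k))
        weights = cm.sum(axis=1) / total

    sens, spec, f1s = [], [], []
    for c in class_range:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = sens[-1]
        f1s.append(2 * precision * recall / (precision + recall) if precision + recall else 0.0)
    return MetricReport(
        accuracy=float(accuracy),
        sensitivity=float(100.0 * np.average(sens, weights=weights)),
        specificity=float(100.0 * np.average(spec, weights=weights)),
        f1=float(100.0 * np.average(f1s, weights=weights)),
    )


def run_class_experiment(
    X,
    y,
    classifier: str = "svm",
    n_folds: int = 10,
    seed: int = 0,
    smote: bool = True,
) -> ExperimentResult:
    """Stratified k-fold experiment with train-fold-only SMOTE balancing.

    For each fold: the remaining folds form the training partition, which
    is SMOTE-balanced (unless ``smote=False``); the classifier is fitted on
    the balanced partition and evaluated on the untouched test fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    result = ExperimentResult()
    for i, test_idx in enumerate(stratified_folds(y, n_folds=n_folds, seed=seed)):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        X_train, y_train = X[train_mask], y[train_mask]
        n_synthetic = 0
        if smote:
            X_train, y_train, synthetic_mask = balance_training_set(
                X_train, y_train, seed=seed + i
            )
            n_synthetic = int(synthetic_mask.sum())
        model = make_classifier(classifier, seed=seed)
        model.fit(X_train, y_train)
        y_pred = model.predict(X[test_idx])
        cm = confusion_counts(y[test_idx], y_pred, classes=classes)
        result.folds.append(
            FoldResult(
                test_indices=np.asarray(test_idx),
                n_synthetic=n_synthetic,
                confusion=cm,
                report=compute_metrics(cm),
            )
        )
    return result
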