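"""Classification, balanced accuracy and cross-validated model selection.

The read-out is a soft-margin linear support vector machine whose
per-class misclassification penalties are inversely proportional to class
frequency, so a 41:4000 target/distractor imbalance gives the minority
class a ~98x larger penalty and the classifier is not swamped by the
majority class.  Balanced accuracy — the mean of the per-class recalls —
is the matching performance measure: chance level is 0.5 regardless of
imbalance.

Hyperparameters (FIR half-order ``k`` and ridge ``epsilon``) are selected
by stratified 5-fold cross-validation over the grids ``k in [0, 1, 3, 5]``
and ``epsilon in [1e-4, 1e-5, 1e-6]``; ties prefer smaller ``k`` and then
larger ``epsilon`` (the simpler, more regularised model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import core
from .core import FeatureMatrix, extract_features
from .epochs_io import EEGEpochs
from .exceptions import ParameterError, ValidationError

__all__ = [
    "CVResult",
    "balanced_accuracy",
    "class_weights",
    "WeightedLinearSVM",
    "train_weighted_classifier",
    "cross_validate_select",
    "K_GRID",
    "EPSILON_GRID",
]

K_GRID = (0, 1, 3, 5)
EPSILON_GRID = (1e-4, 1e-5, 1e-6)
CV_SEED = 0  # fixed fold seed; all CV randomness lives here


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the per-class recalls: (sensitivity + specificity) / 2.

    Chance level is 0.5 for two classes whatever the class frequencies; the
    always-majority rule scores exactly 0.5.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_pred: length does not match y_true")
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValidationError(
            "y_true: balanced accuracy needs both classes present"
        )
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in classes
    ]
    return float(np.mean(recalls))


def stratified_holdout(labels, test_fraction: float = 0.5, seed: int = 0):
    """Single stratified train/test split; returns ``(train_idx, test_idx)``.

    Each class is shuffled independently with the given seed and split so the
    test set holds ``round(n_c * test_fraction)`` trials of class ``c``.
    """
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise ParameterError(
            f"test_fraction: must be in (0, 1), got {test_fraction}"
        )
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        rng.shuffle(idx)
        n_test = int(round(len(idx) * test_fraction))
        if n_test == 0 or n_test == len(idx):
            raise ValidationError(
                f"labels: class {c} has too few trials ({len(idx)}) to split"
            )
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def class_weights(labels) -> dict:
    """Inverse-frequency penalties: weight(c) = n_total / (n_classes * n_c)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n = labels.size
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


class WeightedLinearSVM:
    """Linear soft-margin SVM with inverse-frequency class weights.

    Thin deterministic wrapper around the libsvm solver (linear kernel,
    unit base cost); exposes the fitted linear decision rule so a trained
    read-out can be serialised alongside the filter bank.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._svc: SVC | None = None

    def fit(self, X, y) -> "WeightedLinearSVM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("labels: training needs both classes present")
        if not np.all(np.isfinite(X)):
            raise ValidationError("features: contains non-finite values")
        self._svc = SVC(kernel="linear", C=self.C, class_weight=class_weights(y))
        self._svc.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        if self._svc is None:
            raise ValidationError("classifier: predict called before fit")
        X = np.asarray(X, dtype=np.float64)
        return self._svc.predict(X)

    @property
    def coef_(self) -> np.ndarray:
        return self._svc.coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self._svc.intercept_[0])

    @property
    def classes_(self) -> np.ndarray:
        return self._svc.classes_


def train_weighted_classifier(features, labels) -> WeightedLinearSVM:
    """Fit the weighted linear SVM on a feature matrix.

    *features* may be a :class:`FeatureMatrix` or a plain 2-D array.
    Deterministic given fixed inputs.
    """
    X = features.values if isinstance(features, FeatureMatrix) else features
    clf = WeightedLinearSVM()
    clf.fit(X, labels)
    return clf


@dataclass
class CVResult:
    """Grid-search record: per-point fold scores, means and the chosen point."""

    grid: list[tuple[int, float]]
    mean_scores: list[float]
    fold_scores: list[list[float]]
    chosen: tuple[int, float]
    metric_name: str
    n_folds: int = 5
    m: int = field(default=core.DEFAULT_M_MI)

    def to_dict(self) -> dict:
        return {
            "grid": [[k, eps] for k, eps in self.grid],
            "mean_scores": self.mean_scores,
            "fold_scores": self.fold_scores,
            "chosen": {"k": self.chosen[0], "epsilon": self.chosen[1]},
            "metric": self.metric_name,
            "n_folds": self.n_folds,
            "m": self.m,
        }


def _score(metric: str, y_true, y_pred) -> float:
    if metric == "balanced_accuracy":
        return balanced_accuracy(y_true, y_pred)
    if metric == "accuracy":
        return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    raise ParameterError(f"metric: unknown metric {metric!r}")


def cross_validate_select(
    epochs: EEGEpochs,
    labels=None,
    k_grid=K_GRID,
    eps_grid=EPSILON_GRID,
    m: int = core.DEFAULT_M_MI,
    n_folds: int = 5,
    metric: str = "accuracy",
) -> CVResult:
    """Select ``(k, epsilon)`` by stratified n-fold cross-validation.

    For every grid point the filter bank and classifier are fitted on the
    training folds only and scored on the held-out fold; the chosen point
    maximises the mean score, with ties broken towards smaller ``k`` and
    then larger ``epsilon``.  Folds are stratified with a fixed seed so the
    procedure is reproducible.
    """
    if n_folds < 2:
        raise ParameterError(f"n_folds: must be >= 2, got {n_folds}")
    labels = epochs.labels if labels is None else np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("labels: need exactly two classes")
    if counts.min() < n_folds:
        raise ValidationError(
            f"labels: class with {counts.min()} trials cannot be split into "
            f"{n_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=CV_SEED)
    splits = list(skf.split(np.zeros(len(labels)), labels))
    grid = [(int(k), float(eps)) for k, eps in product(k_grid, eps_grid)]
    fold_scores: list[list[float]] = []
    for k, eps in grid:
        scores = []
        for train_idx, test_idx in splits:
            train = epochs.subset(train_idx)
            test = epochs.subset(test_idx)
            model = core.fit(train, k=k, epsilon=eps, m=m)
            clf = train_weighted_classifier(
                extract_features(model, train), train.labels
            )
            pred = clf.predict(extract_features(model, test).values)
            scores.append(_score(metric, test.labels, pred))
        fold_scores.append(scores)
    means = [float(np.mean(s)) for s in fold_scores]
    # argmax with tie rule: smaller k first, then larger epsilon
    best = min(
        range(len(grid)), key=lambda i: (-means[i], grid[i][0], -grid[i][1])
    )
    return CVResult(
        grid=grid,
        mean_scores=means,
        fold_scores=fold_scores,
        chosen=grid[best],
        metric_name=metric,
        n_folds=n_folds,
        m=m,
    )
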