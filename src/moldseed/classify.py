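"""Random-forest fitness for the optimizer, final training, and evaluation.

The optimizer searches a continuous 2-D box (tree count, feature-subset
size); rounding to integers happens inside the fitness function so the
position updates stay continuous.  Fitness is 1 minus the mean stratified
k-fold cross-validated accuracy — lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RfHyperparams",
    "EvaluationReport",
    "position_to_params",
    "fitness_from_position",
    "make_fitness",
    "train_final",
    "evaluate",
]


@dataclass(frozen=True)
class RfHyperparams:
    """The two tuned forest hyperparameters."""

    n_trees: int
    n_features_per_split: int

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_features_per_split < 1:
            raise ValueError("n_features_per_split must be >= 1")


@dataclass
class EvaluationReport:
    """Confusion matrix with per-class precision/recall and accuracy."""

    confusion: np.ndarray          # (K, K), rows = true, cols = predicted
    precision: np.ndarray          # (K,), 0 where the column total is 0
    recall: np.ndarray             # (K,)
    support: np.ndarray            # (K,) per-class true counts
    accuracy: float
    labels: np.ndarray
    undefined_precision: np.ndarray  # bool flags for empty prediction columns

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())


def position_to_params(
    position: np.ndarray, n_bands: int, max_trees: int = 100
) -> RfHyperparams:
    """Round a continuous search point to valid integer hyperparameters."""
    position = np.asarray(position, dtype=float).ravel()
    if position.size != 2:
        raise ValueError("position must be a 2-vector (trees, features)")
    n_trees = int(np.clip(round(position[0]), 1, max_trees))
    n_feat = int(np.clip(round(position[1]), 1, n_bands))
    return RfHyperparams(n_trees=n_trees, n_features_per_split=n_feat)


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, params: RfHyperparams,
    cv_folds: int, inner_seed: int,
) -> float:
    counts = np.bincount(y)
    thin = np.flatnonzero((counts > 0) & (counts < cv_folds))
    if thin.size:
        raise ValueError(
            f"class(es) {thin.tolist()} have fewer members than cv_folds={cv_folds}"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
    correct = 0
    for train, test in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features=params.n_features_per_split,
            random_state=inner_seed,
            n_jobs=1,
        )
        clf.fit(X[train], y[train])
        correct += int(np.sum(clf.predict(X[test]) == y[test]))
    return correct / len(y)


def fitness_from_position(
    position: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    inner_seed: int = 0,
    max_trees: int = 100,
) -> float:
    """1 - mean stratified CV accuracy of the forest at the rounded position."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("fitness needs >= 2 classes")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    params = position_to_params(position, n_bands=X.shape[1], max_trees=max_trees)
    return 1.0 - _cv_accuracy(X, y, params, cv_folds, inner_seed)


def make_fitness(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    inner_seed: int = 0,
    max_trees: int = 100,
):
    """Cached fitness callable for the optimizer.

    Rounding makes the search space a small integer lattice, so repeated
    visits are served from a dict keyed on the rounded hyperparameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cache: dict[RfHyperparams, float] = {}

    def fitness(position: np.ndarray) -> float:
        params = position_to_params(position, n_bands=X.shape[1], max_trees=max_trees)
        if params not in cache:
            cache[params] = 1.0 - _cv_accuracy(X, y, params, cv_folds, inner_seed)
        return cache[params]

    fitness.cache = cache  # type: ignore[attr-defined]
    return fitness


def train_final(
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: RfHyperparams,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the final forest with the tuned hyperparameters."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set has a single class")
    if params.n_features_per_split > X_train.shape[1]:
        raise ValueError(
            f"n_features_per_split={params.n_features_per_split} exceeds "
            f"band count {X_train.shape[1]}"
        )
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.n_features_per_split,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X_train, y_train)
    return clf


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Confusion matrix, per-class precision/recall, overall accuracy.

    Precision of a class nobody was predicted as is reported as 0 and
    flagged in ``undefined_precision``.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    labels = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    undefined = col == 0
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=~undefined)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    accuracy = float(diag.sum() / cm.sum()) if cm.sum() else 0.0
    return EvaluationReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        support=row.astype(int),
        accuracy=accuracy,
        labels=labels,
        undefined_precision=undefined,
    )
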