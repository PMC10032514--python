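"""Grid-search benchmarking of subject separability.

Three classifiers — k-nearest-neighbour, radius-nearest-neighbour and random
forest — are tuned by exhaustive grid search with stratified cross-validation
(accuracy scoring) on a stratified 75/25 train/test split, then scored with
macro-averaged F1 on the held-out quarter.  The benchmark can run either on
the raw ratio features or on the first three principal components, with the
PCA fitted on the training split only and the test split projected onto it.

Radius-NN test points with no neighbour inside the radius are assigned a
reserved "outlier" label and count as classification errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, RadiusNeighborsClassifier

from .errors import ValidationError

__all__ = ["GridSpec", "ClassifierReport", "benchmark", "benchmark_on_pcs", "OUTLIER_LABEL"]

OUTLIER_LABEL = "__outlier__"


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids and evaluation protocol for all three learners."""

    knn_k: tuple[int, ...] = tuple(range(1, 20))
    nn_weights: tuple[str, ...] = ("uniform", "distance")
    rnn_radius: tuple[float, ...] = tuple(range(1, 100, 10))
    rf_estimators: tuple[int, ...] = tuple(range(1, 201, 10))
    rf_max_features: tuple[int, ...] = tuple(range(1, 12, 2))
    rf_bootstrap: tuple[bool, ...] = (True, False)
    rf_oob: tuple[bool, ...] = (True, False)  # explored only when bootstrap is on
    cv_folds: int = 5
    test_size: float = 0.25
    seed: int = 0


@dataclass(frozen=True)
class ClassifierReport:
    algorithm: str
    input_space: str  # "ratios" | "first_3_pcs"
    best_params: Mapping[str, object]
    f1: float
    per_class_f1: Mapping[str, float]
    confusion: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.f1 <= 1.0:
            raise ValidationError("F1 out of range")


def _estimator_and_grid(algorithm: str, grid: GridSpec, seed: int, n_features: int):
    if algorithm == "knn":
        return (
            KNeighborsClassifier(),
            {"n_neighbors": list(grid.knn_k), "weights": list(grid.nn_weights)},
        )
    if algorithm == "rnn":
        return (
            RadiusNeighborsClassifier(outlier_label=OUTLIER_LABEL),
            {"radius": list(grid.rnn_radius), "weights": list(grid.nn_weights)},
        )
    if algorithm == "rf":
        max_features = [m for m in grid.rf_max_features if m <= n_features] or [n_features]
        param_grid = [
            {
                "n_estimators": list(grid.rf_estimators),
                "max_features": max_features,
                "bootstrap": [True],
                "oob_score": list(grid.rf_oob),
            },
            {
                "n_estimators": list(grid.rf_estimators),
                "max_features": max_features,
                "bootstrap": [False],
                "oob_score": [False],
            },
        ]
        if True not in grid.rf_bootstrap:
            param_grid = param_grid[1:]
        elif False not in grid.rf_bootstrap:
            param_grid = param_grid[:1]
        return RandomForestClassifier(random_state=seed), param_grid
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _evaluate(x_train, x_test, y_train, y_test, algorithm, grid, seed, input_space):
    estimator, param_grid = _estimator_and_grid(algorithm, grid, seed, x_train.shape[1])
    class_counts = pd.Series(y_train).value_counts()
    n_splits = min(grid.cv_folds, int(class_counts.min()))
    if n_splits < grid.cv_folds:
        warnings.warn(
            f"smallest training class has {class_counts.min()} samples; "
            f"using {n_splits}-fold CV instead of {grid.cv_folds}",
            stacklevel=3,
        )
    search = GridSearchCV(
        estimator,
        param_grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
        error_score=np.nan,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", message="One or more of the test scores are non-finite")
        warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
        search.fit(x_train, y_train)
        y_pred = np.asarray(search.predict(x_test), dtype=object)
    classes = sorted(set(y_train) | set(y_test))
    macro = f1_score(y_test, y_pred, labels=classes, average="macro", zero_division=0)
    per_class = f1_score(y_test, y_pred, labels=classes, average=None, zero_division=0)
    conf_labels = classes + ([OUTLIER_LABEL] if OUTLIER_LABEL in set(y_pred) else [])
    conf = pd.DataFrame(
        confusion_matrix(y_test, y_pred, labels=conf_labels),
        index=conf_labels,
        columns=conf_labels,
    )
    return ClassifierReport(
        algorithm=algorithm,
        input_space=input_space,
        best_params=dict(search.best_params_),
        f1=float(macro),
        per_class_f1=dict(zip(classes, map(float, per_class))),
        confusion=conf,
        seed=seed,
    )


def _check_and_split(x, labels, grid, seed):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if x.shape[0] != len(labels):
        raise ValidationError("x and labels length mismatch")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 classes")
    if x.shape[0] < 8:
        raise ValidationError("need at least 8 samples")
    if counts.min() < 2:
        raise ValidationError(
            f"class {counts.idxmin()!r} has {counts.min()} sample(s); "
            "cannot stratify the split"
        )
    return train_test_split(
        x, labels, test_size=grid.test_size, stratify=labels, random_state=seed
    )


def benchmark(
    x,
    labels: Sequence[str],
    algorithm: str,
    grid: GridSpec | None = None,
    seed: Optional[int] = None,
) -> ClassifierReport:
    """Tune and score one classifier on the raw feature space."""
    grid = grid or GridSpec()
    seed = grid.seed if seed is None else seed
    x_train, x_test, y_train, y_test = _check_and_split(x, labels, grid, seed)
    return _evaluate(x_train, x_test, y_train, y_test, algorithm, grid, seed, "ratios")


def benchmark_on_pcs(
    x,
    labels: Sequence[str],
    algorithm: str,
    grid: GridSpec | None = None,
    seed: Optional[int] = None,
    n_pcs: int = 3,
) -> ClassifierReport:
    """As :func:`benchmark`, on the first ``n_pcs`` principal components.

    The PCA is fitted on the training split only; the test split is
    projected onto it.  When ``n_pcs`` exceeds the training data's rank the
    rank is used instead (with a warning).
    """
    grid = grid or GridSpec()
    seed = grid.seed if seed is None else seed
    x_train, x_test, y_train, y_test = _check_and_split(x, labels, grid, seed)
    rank = min(x_train.shape[0] - 1, x_train.shape[1])
    if n_pcs > rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds training rank {rank}; using {rank}")
        n_pcs = rank
    reducer = PCA(n_components=n_pcs, svd_solver="full").fit(x_train)
    return _evaluate(
        reducer.transform(x_train),
        reducer.transform(x_test),
        y_train,
        y_test,
        algorithm,
        grid,
        seed,
        "first_3_pcs" if n_pcs == 3 else f"first_{n_pcs}_pcs",
    )
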