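"""Personalized gesture classifiers: grids, cross-validated tuning, training.

Four classifier families are supported — a multilayer perceptron (ANN), a
support vector machine, a random forest and multinomial logistic
regression — each tuned over its published hyperparameter grid by a
stratified 10-fold cross-validation grid search, then refitted on the full
training set with the winning parameters.  Standardization is fitted on
training folds only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._mlp import MLPGestureClassifier
from .features import (
    StandardizerState,
    apply_standardizer,
    feature_columns_of,
    fit_standardizer,
)

logger = logging.getLogger(__name__)

METHODS = ("ann", "svm", "rf", "lr")


@dataclass(frozen=True)
class ANNTrainRecipe:
    """Fixed MLP training recipe: Adam, batch 1024, lr 0.001, 2000 epochs.

    ``epochs`` scales down for desk-scale runs; the remaining values are the
    training constants used for every ANN fit.
    """

    batch_size: int = 1024
    learning_rate: float = 1e-3
    epochs: int = 2000

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


#: reduced recipe for tests and quick runs
FAST_RECIPE = ANNTrainRecipe(epochs=60)


def _product(space: dict[str, list]) -> list[dict]:
    keys = list(space)
    return [dict(zip(keys, vals)) for vals in itertools.product(*space.values())]


def full_grid(method: str) -> list[dict]:
    """The published hyperparameter grid of one classifier family."""
    if method == "ann":
        return _product(
            {
                "hidden_layers": [2, 3, 4],
                "hidden_units": [300, 600, 1000],
                "dropout": [0.2, 0.3],
                "batch_norm": [True, False],
            }
        )
    if method == "svm":
        return _product(
            {
                "kernel": ["linear", "rbf"],
                "C": [1, 10, 100, 1000],
                "gamma": [1, 0.1, 0.01, 0.001, 0.0001],
            }
        )
    if method == "rf":
        return _product(
            {
                "n_estimators": [100, 500, 1000],
                "class_weight": ["balanced_subsample", None],
            }
        )
    if method == "lr":
        return _product(
            {
                "penalty": ["l1", "l2", "elasticnet", None],
                "C": [1, 0.1, 0.01, 0.001, 0.0001],
                "class_weight": ["balanced", None],
                "solver": ["lbfgs", "saga"],
            }
        )
    raise ValueError(f"unknown method {method!r}")


def fast_grid(method: str) -> list[dict]:
    """Two-point grids for desk-scale runs (a small subset of the full grid)."""
    grids = {
        "ann": [
            {"hidden_layers": 2, "hidden_units": 300, "dropout": 0.2, "batch_norm": True},
            {"hidden_layers": 3, "hidden_units": 300, "dropout": 0.2, "batch_norm": True},
        ],
        "svm": [
            {"kernel": "rbf", "C": 10, "gamma": 0.1},
            {"kernel": "rbf", "C": 100, "gamma": 0.01},
        ],
        "rf": [
            {"n_estimators": 100, "class_weight": "balanced_subsample"},
            {"n_estimators": 100, "class_weight": None},
        ],
        "lr": [
            {"penalty": "l2", "C": 1, "class_weight": None, "solver": "lbfgs"},
            {"penalty": "l2", "C": 0.1, "class_weight": None, "solver": "lbfgs"},
        ],
    }
    if method not in grids:
        raise ValueError(f"unknown method {method!r}")
    return grids[method]


@dataclass(frozen=True)
class GridSpec:
    """A classifier family plus the parameter grid to search."""

    method: str
    grid: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not self.grid:
            object.__setattr__(self, "grid", full_grid(self.method))


def is_valid_params(method: str, params: dict) -> bool:
    """Reject hyperparameter cells the solver cannot realize (LR only)."""
    if method != "lr":
        return True
    penalty, solver = params.get("penalty"), params.get("solver")
    if solver == "lbfgs" and penalty in ("l1", "elasticnet"):
        return False
    return True


def build_estimator(
    method: str,
    params: dict,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
    seed: int = 0,
):
    """Instantiate an unfitted classifier of the requested family."""
    if not is_valid_params(method, params):
        raise ValueError(f"invalid {method} parameter combination: {params}")
    if method == "ann":
        return MLPGestureClassifier(
            hidden_layers=params["hidden_layers"],
            hidden_units=params["hidden_units"],
            dropout=params["dropout"],
            batch_norm=params["batch_norm"],
            epochs=recipe.epochs,
            batch_size=recipe.batch_size,
            learning_rate=recipe.learning_rate,
            seed=seed,
        )
    if method == "svm":
        return SVC(
            kernel=params["kernel"], C=params["C"], gamma=params["gamma"],
            random_state=seed,
        )
    if method == "rf":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            class_weight=params["class_weight"],
            random_state=seed,
            n_jobs=1,
        )
    if method == "lr":
        # penalty names map onto the elastic-net mixing parameter
        # (l1 -> 1, l2 -> 0, elasticnet -> 0.5, none -> unregularized)
        penalty = params["penalty"]
        kw: dict[str, Any] = dict(
            class_weight=params["class_weight"],
            solver=params["solver"],
            max_iter=2000,
            random_state=seed,
        )
        if penalty is None:
            kw["C"] = np.inf
            kw["l1_ratio"] = 0.0
        else:
            kw["C"] = params["C"]
            kw["l1_ratio"] = {"l1": 1.0, "l2": 0.0, "elasticnet": 0.5}[penalty]
        return LogisticRegression(**kw)
    raise ValueError(f"unknown method {method!r}")


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = feature_columns_of(table)
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy(), cols


@dataclass
class GridSearchResult:
    best_params: dict
    fold_accuracies: np.ndarray  # accuracies of the winning point, one per fold
    mean_accuracy: float
    all_results: list[tuple[dict, float]]  # (params, mean CV accuracy) per point


def cv_grid_search(
    train: pd.DataFrame,
    gridspec: GridSpec,
    folds: int = 10,
    seed: int = 0,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
) -> GridSearchResult:
    """Stratified k-fold grid search over one family's parameter grid.

    Each grid point is scored by mean validation accuracy over the folds
    (standardizer refitted on the training folds each time); the argmax is
    returned, ties broken by grid enumeration order.  Invalid LR cells are
    skipped with a log message.
    """
    X, y, _ = _xy(train)
    counts = pd.Series(y).value_counts()
    lacking = counts[counts < folds]
    if not lacking.empty:
        raise ValueError(
            f"classes with fewer than {folds} members: {list(lacking.index)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    results: list[tuple[dict, float, np.ndarray]] = []
    for params in gridspec.grid:
        if not is_valid_params(gridspec.method, params):
            logger.info("skipping invalid %s cell %s", gridspec.method, params)
            continue
        accs = np.empty(folds)
        for i, (tr, va) in enumerate(splits):
            std = fit_standardizer(X[tr])
            est = build_estimator(gridspec.method, params, recipe, seed)
            est.fit(std.transform(X[tr]), y[tr])
            accs[i] = accuracy(est.predict(std.transform(X[va])), y[va])
        results.append((params, float(accs.mean()), accs))
    if not results:
        raise ValueError("no valid grid points to evaluate")
    best = max(range(len(results)), key=lambda i: results[i][1])
    params, mean_acc, accs = results[best]
    return GridSearchResult(
        best_params=params,
        fold_accuracies=accs,
        mean_accuracy=mean_acc,
        all_results=[(p, m) for p, m, _ in results],
    )


@dataclass
class TrainedModel:
    """A fitted classifier together with its fitted standardizer."""

    method: str
    params: dict
    estimator: Any
    standardizer: StandardizerState
    seed: int = 0
    cv_fold_accuracies: np.ndarray | None = None

    def manifest(self) -> dict:
        return {
            "method": self.method,
            "params": {k: v for k, v in self.params.items()},
            "seed": self.seed,
            "cv_fold_accuracies": (
                None
                if self.cv_fold_accuracies is None
                else [float(a) for a in self.cv_fold_accuracies]
            ),
        }


def train_final(
    train: pd.DataFrame,
    method: str,
    params: dict,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
    seed: int = 0,
    cv_fold_accuracies: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the standardizer and classifier on the entire training table."""
    X, y, _ = _xy(train)
    std = fit_standardizer(X)
    est = build_estimator(method, params, recipe, seed)
    est.fit(std.transform(X), y)
    return TrainedModel(method, params, est, std, seed, cv_fold_accuracies)


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    X = table[feature_columns_of(table)].to_numpy(dtype=float)
    return model.estimator.predict(model.standardizer.transform(X))


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred == truth))


def tune_and_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    method: str,
    grid: list[dict] | None = None,
    folds: int = 10,
    seed: int = 0,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
) -> tuple[TrainedModel, float, np.ndarray]:
    """Grid-search on the training set, refit, and score the test set.

    A single-point grid skips cross-validation and trains directly.
    Returns (model, test accuracy, test predictions).
    """
    spec = GridSpec(method, grid if grid is not None else fast_grid(method))
    if len(spec.grid) == 1:
        result = GridSearchResult(spec.grid[0], np.array([]), float("nan"), [])
    else:
        result = cv_grid_search(train, spec, folds, seed, recipe)
    model = train_final(
        train, method, result.best_params, recipe, seed, result.fold_accuracies
    )
    preds = predict(model, test)
    return model, accuracy(preds, test["label"].to_numpy()), preds
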