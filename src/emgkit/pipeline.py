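"""End-to-end convenience wrappers: recording -> balanced feature table ->
trained classifier -> accuracy."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthdata import EMGRecording
from .preprocess import apply_filters
from .segmentlabel import WindowingSpec, label_recording
from .features import extract_feature_table
from .datasetprep import undersample_rest, split_holdout, split_by_round
from .models import ANNTrainRecipe, tune_and_evaluate


def recording_to_features(
    recording: EMGRecording,
    spec: WindowingSpec = WindowingSpec(),
    lam: float | str = "auto",
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    zero_phase: bool = False,
) -> pd.DataFrame:
    """Filter, segment, annotate and featurize one raw recording."""
    filtered = apply_filters(recording, zero_phase=zero_phase)
    labeled, _calib, _timeline = label_recording(filtered, spec, lam)
    return extract_feature_table(
        filtered, labeled, spec, zc_threshold, ssc_threshold
    )


def subject_dataset(
    recording: EMGRecording, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Balanced (rest-undersampled) feature table of one subject."""
    table = recording_to_features(recording, **kwargs)
    return undersample_rest(table, seed=seed)


def evaluate_subject(
    table: pd.DataFrame,
    method: str,
    grid: list[dict] | None = None,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
    seed: int = 0,
    split: str = "holdout",
    folds: int = 10,
) -> dict:
    """Train and score one subject with one classifier family.

    ``split`` is ``holdout`` (stratified 90/10) or ``rounds`` (train on
    rounds 1-3, test on round 4).  Returns a dict with the fitted model,
    accuracy and test predictions/labels.
    """
    if split == "holdout":
        train, test = split_holdout(table, seed=seed)
    elif split == "rounds":
        train, test = split_by_round(table)
    else:
        raise ValueError(f"unknown split {split!r}")
    model, acc, preds = tune_and_evaluate(
        train, test, method, grid, folds=folds, seed=seed, recipe=recipe
    )
    return {
        "model": model,
        "accuracy": acc,
        "predictions": preds,
        "truth": test["label"].to_numpy(),
    }


def evaluate_cohort(
    tables: Mapping[str, pd.DataFrame],
    methods: Sequence[str],
    grids: Mapping[str, list[dict]] | None = None,
    recipe: ANNTrainRecipe = ANNTrainRecipe(),
    seed: int = 0,
    split: str = "holdout",
    folds: int = 10,
) -> pd.DataFrame:
    """Accuracy of every (subject, method) pair; subjects x methods frame."""
    out: dict[str, dict[str, float]] = {}
    for sid, table in tables.items():
        out[sid] = {}
        for method in methods:
            grid = None if grids is None else grids.get(method)
            res = evaluate_subject(
                table, method, grid, recipe, seed=seed, split=split, folds=folds
            )
            out[sid][method] = res["accuracy"]
    return pd.DataFrame(out).T


def chance_level(table: pd.DataFrame, seed: int = 0,
                 recipe: ANNTrainRecipe = ANNTrainRecipe()) -> float:
    """Holdout accuracy of a random forest after shuffling the labels —
    an empirical floor near 1/n_classes."""
    rng = np.random.default_rng(seed)
    shuffled = table.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    res = evaluate_subject(
        shuffled,
        "rf",
        grid=[{"n_estimators": 100, "class_weight": None}],
        recipe=recipe,
        seed=seed,
    )
    return res["accuracy"]
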