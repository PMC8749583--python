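"""Class balancing and evaluation splits for per-subject datasets.

The protocol yields roughly nine rest windows for every non-rest window,
so rest is randomly under-sampled to the median non-rest class count
before training.  Two evaluation splits are provided: a stratified 90/10
holdout, and a round-based split (train on rounds 1-3, test on round 4)
that emulates real-time use on later data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .synthdata import REST


def class_counts(ds: pd.DataFrame) -> pd.Series:
    return ds["label"].value_counts()


def undersample_rest(ds: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Randomly subsample rest rows (without replacement) down to the median
    non-rest class count; non-rest rows are untouched.  Reproducible."""
    counts = class_counts(ds)
    if REST not in counts.index:
        warnings.warn("dataset has no rest rows; under-sampling is a no-op",
                      stacklevel=2)
        return ds
    non_rest = counts.drop(REST)
    if non_rest.empty:
        raise ValueError("dataset has only rest rows")
    target = int(round(float(non_rest.median())))
    rest_idx = ds.index[ds["label"] == REST].to_numpy()
    if len(rest_idx) <= target:
        return ds
    rng = np.random.default_rng(seed)
    keep = rng.choice(rest_idx, size=target, replace=False)
    mask = ds["label"] != REST
    mask |= ds.index.isin(keep)
    return ds[mask]


def split_holdout(
    ds: pd.DataFrame, train_frac: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split (default 90 % / 10 %), disjoint by row."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    if class_counts(ds).min() < 2:
        raise ValueError("every class needs at least 2 rows for a stratified split")
    train, test = train_test_split(
        ds,
        train_size=train_frac,
        stratify=ds["label"],
        random_state=seed,
        shuffle=True,
    )
    return train, test


def split_by_round(
    ds: pd.DataFrame, test_round: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by acquisition round: earlier rounds train, the last tests.

    Requires all rounds 1..test_round to be present, so the split emulates
    training on the first three rounds and deploying on the fourth.
    """
    present = set(ds["round"].unique())
    missing = set(range(1, test_round + 1)) - present
    if missing:
        raise ValueError(f"missing rounds: {sorted(missing)}")
    train = ds[ds["round"] < test_round]
    test = ds[ds["round"] == test_round]
    return train, test
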