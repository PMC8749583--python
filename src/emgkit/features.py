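"""Time-domain EMG features and feature-table utilities.

Six classical features are computed per channel per window: root mean
square (RMS), variance under the zero-mean convention (VAR = RMS^2), mean
absolute value (MAV), slope sign changes (SSC), zero crossings (ZC) and
waveform length (WL).  ZC and SSC take an optional amplitude threshold
(default 0) guarding against noise-induced counts.  A 250-ms window at
2000 Hz gives N = 500 samples; three channels give 18 features per window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import EMGRecording, N_CHANNELS
from .segmentlabel import WindowingSpec

#: canonical per-channel feature order (channel-major across channels)
FEATURE_NAMES: tuple[str, ...] = ("rms", "var", "mav", "ssc", "zc", "wl")

#: all 18 feature-table column names, channel-major
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"ch{c + 1}_{f}" for c in range(N_CHANNELS) for f in FEATURE_NAMES
)

META_COLUMNS: tuple[str, ...] = ("subject", "gesture", "round", "start_sample", "label")


def _check(x: np.ndarray, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.shape[-1]}")
    return x


def rms(x: np.ndarray) -> np.ndarray | float:
    """Root mean square, sqrt(mean(x_i^2)); reduces the last axis."""
    x = _check(x, 1)
    return np.sqrt(np.mean(x**2, axis=-1))


def var(x: np.ndarray) -> np.ndarray | float:
    """Mean square power: the variance under the zero-mean convention,
    identical to RMS^2 (bandpassed EMG has no DC component)."""
    x = _check(x, 1)
    return np.mean(x**2, axis=-1)


def mav(x: np.ndarray) -> np.ndarray | float:
    """Mean absolute value."""
    x = _check(x, 1)
    return np.mean(np.abs(x), axis=-1)


def waveform_length(x: np.ndarray) -> np.ndarray | float:
    """Cumulative length of the waveform, sum |x_{i+1} - x_i|."""
    x = _check(x, 2)
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def zero_crossings(x: np.ndarray, threshold: float = 0.0) -> np.ndarray | int:
    """Sign-flip count: pairs with x_i * x_{i+1} < 0 and |x_i - x_{i+1}| >=
    threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = _check(x, 2)
    a, b = x[..., :-1], x[..., 1:]
    hits = (a * b < 0) & (np.abs(a - b) >= threshold)
    out = np.sum(hits, axis=-1)
    return int(out) if out.ndim == 0 else out


def slope_sign_changes(
    x: np.ndarray, threshold: float = 0.0, mode: str = "strict"
) -> np.ndarray | int:
    """Local-extremum count: interior samples where the slope changes sign.

    ``strict`` (default) counts (x_i - x_{i-1}) * (x_i - x_{i+1}) > threshold,
    so flat segments never count; ``literal`` uses >=, under which a constant
    signal scores N - 2.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("strict", "literal"):
        raise ValueError(f"unknown SSC mode {mode!r}")
    x = _check(x, 3)
    d = (x[..., 1:-1] - x[..., :-2]) * (x[..., 1:-1] - x[..., 2:])
    hits = d > threshold if mode == "strict" else d >= threshold
    out = np.sum(hits, axis=-1)
    return int(out) if out.ndim == 0 else out


def extract_features(
    window: np.ndarray,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    ssc_mode: str = "strict",
) -> np.ndarray:
    """18-value feature vector of one 3-channel window, channel-major
    (ch1: RMS, VAR, MAV, SSC, ZC, WL; then ch2, ch3)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != N_CHANNELS:
        raise ValueError(f"window must be ({N_CHANNELS}, N)")
    if window.shape[1] < 3:
        raise ValueError("window must have at least 3 samples")
    out = np.empty(N_CHANNELS * len(FEATURE_NAMES))
    for c in range(N_CHANNELS):
        x = window[c]
        out[c * 6 : (c + 1) * 6] = (
            rms(x),
            var(x),
            mav(x),
            slope_sign_changes(x, ssc_threshold, ssc_mode),
            zero_crossings(x, zc_threshold),
            waveform_length(x),
        )
    return out


def extract_feature_table(
    recording: EMGRecording,
    labeled_windows: pd.DataFrame,
    spec: WindowingSpec = WindowingSpec(),
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    ssc_mode: str = "strict",
    chunk: int = 4096,
) -> pd.DataFrame:
    """Feature table for every labeled window of a recording.

    Output columns: subject, gesture, round, start_sample, label, then the
    18 feature columns.  Windows are gathered in chunks to bound memory.
    """
    fs = recording.sampling_rate
    w = spec.window_samples(fs)
    starts = labeled_windows["start_sample"].to_numpy(dtype=int)
    feats = np.empty((len(starts), len(FEATURE_COLUMNS)))
    for lo in range(0, len(starts), chunk):
        idx = starts[lo : lo + chunk, None] + np.arange(w)[None, :]
        for c in range(N_CHANNELS):
            x = recording.samples[c][idx]  # (chunk, w)
            feats[lo : lo + chunk, c * 6 + 0] = rms(x)
            feats[lo : lo + chunk, c * 6 + 1] = var(x)
            feats[lo : lo + chunk, c * 6 + 2] = mav(x)
            feats[lo : lo + chunk, c * 6 + 3] = slope_sign_changes(
                x, ssc_threshold, ssc_mode
            )
            feats[lo : lo + chunk, c * 6 + 4] = zero_crossings(x, zc_threshold)
            feats[lo : lo + chunk, c * 6 + 5] = waveform_length(x)
    meta = labeled_windows.reset_index(drop=True)
    table = pd.concat(
        [meta[list(META_COLUMNS)], pd.DataFrame(feats, columns=list(FEATURE_COLUMNS))],
        axis=1,
    )
    return table


class StandardizerState:
    """Column-wise standardization fitted on a training table.

    Transform is (x - mean) / sd with population (ddof=0) standard
    deviation; constant columns map to zero.
    """

    def __init__(self, mean: np.ndarray, scale: np.ndarray, columns: list[str]):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.columns = list(columns)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} feature columns, got {X.shape[-1]}"
            )
        return (X - self.mean) / self.scale


def fit_standardizer(table: pd.DataFrame | np.ndarray) -> StandardizerState:
    """Fit per-column mean/sd on a training feature table (>= 2 rows)."""
    if isinstance(table, pd.DataFrame):
        cols = feature_columns_of(table)
        X = table[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        cols = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: unit population variance after transform
    scale = np.where(sd == 0, 1.0, sd)
    return StandardizerState(mean, scale, cols)


def apply_standardizer(
    state: StandardizerState, table: pd.DataFrame | np.ndarray
) -> pd.DataFrame | np.ndarray:
    """Standardize the feature columns of a table (or a bare array)."""
    if isinstance(table, pd.DataFrame):
        out = table.copy()
        out[state.columns] = state.transform(out[state.columns].to_numpy(dtype=float))
        return out
    return state.transform(table)


def feature_columns_of(table: pd.DataFrame) -> list[str]:
    """Feature columns present in a table, in canonical order."""
    return [c for c in FEATURE_COLUMNS if c in table.columns] or [
        c for c in table.columns if c not in META_COLUMNS
    ]


def select_combination(
    table: pd.DataFrame, combo: set[str] | frozenset[str]
) -> pd.DataFrame:
    """Restrict a feature table to the named features on all 3 channels.

    ``combo`` is a non-empty subset of {rms, var, mav, ssc, zc, wl}; column
    order (channel-major, canonical feature order) is preserved.
    """
    combo = {f.lower() for f in combo}
    if not combo:
        raise ValueError("feature combination must not be empty")
    unknown = combo - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    keep = [
        f"ch{c + 1}_{f}"
        for c in range(N_CHANNELS)
        for f in FEATURE_NAMES
        if f in combo
    ]
    meta = [c for c in META_COLUMNS if c in table.columns]
    return table[meta + keep]
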