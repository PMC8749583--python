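"""Overlapping-window segmentation and threshold-based activation labeling.

A 250-ms moving window advancing in 25-ms steps (90 % overlap) segments
each (gesture, round) span.  Muscle activation is detected with an
amplitude threshold ``lambda * Baseline_max`` per channel, where
Baseline_max is the peak rest-state magnitude measured over the first 4 s
of each round's leading rest block.  From each gesture command onward, the
earliest threshold crossing across the three channels marks the activation
point; the signal is taken as activated for 5 s from that point.  A window
is annotated with the round's gesture iff more than 50 % of its samples
are activated, and with rest otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import EMGRecording, ProtocolSchedule, REST, N_CHANNELS

logger = logging.getLogger(__name__)

#: filter startup span skipped when scanning rest baselines, seconds
TRANSIENT_SKIP_S = 0.25


class CalibrationError(ValueError):
    """Raised when a valid activation threshold cannot be derived."""


@dataclass(frozen=True)
class WindowingSpec:
    """Moving-window geometry (defaults: 250-ms window, 25-ms step)."""

    window_s: float = 0.25
    step_s: float = 0.025

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("need 0 < step_s <= window_s")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_s * fs))

    def overlap(self) -> float:
        return (self.window_s - self.step_s) / self.window_s


def segment(signal_length: int, spec: WindowingSpec = WindowingSpec(),
            fs: float = 2000.0) -> np.ndarray:
    """Window start samples: 0, step, 2*step, ... while start+window <= length."""
    w = spec.window_samples(fs)
    s = spec.step_samples(fs)
    if signal_length < w:
        raise ValueError(
            f"signal ({signal_length} samples) shorter than one window ({w})"
        )
    n = (signal_length - w) // s + 1
    return np.arange(n) * s


def segment_rounds(
    schedule: ProtocolSchedule, spec: WindowingSpec = WindowingSpec()
) -> pd.DataFrame:
    """Windows confined to each (gesture, round) span.

    Returns a frame with columns gesture, round, start_sample; windows never
    straddle two rounds and inter-round rest is not segmented.
    """
    rows = []
    for rs in schedule.round_boundaries:
        starts = rs.start_sample + segment(
            rs.end_sample - rs.start_sample, spec, schedule.sampling_rate
        )
        rows.append(
            pd.DataFrame(
                {"gesture": rs.gesture, "round": rs.round_index, "start_sample": starts}
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ThresholdCalibration:
    """Activation-threshold state: Baseline_max table and the lambda multiplier.

    The per-channel threshold is ``lam * max over (gesture, round) of
    baseline_max`` — the highest rest-state peak observed anywhere in the
    session, scaled by the empirical coefficient lambda.
    """

    baseline_max: dict[tuple[str, int, int], float]  # (gesture, round, channel) -> peak
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not self.baseline_max:
            raise CalibrationError("empty baseline table")
        if min(self.baseline_max.values()) <= 0:
            raise CalibrationError("Baseline_max must be strictly positive")
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")

    @property
    def lambda_max(self) -> float:
        vals = list(self.baseline_max.values())
        return max(vals) / min(vals)

    def channel_baseline(self, channel: int) -> float:
        vals = [v for (g, r, c), v in self.baseline_max.items() if c == channel]
        if not vals:
            raise CalibrationError(f"no baseline entries for channel {channel}")
        return max(vals)

    @property
    def thresholds(self) -> np.ndarray:
        """Per-channel activation threshold (amplitude units)."""
        return np.array(
            [self.lam * self.channel_baseline(c) for c in range(N_CHANNELS)]
        )

    def with_lambda(self, lam: float) -> "ThresholdCalibration":
        return ThresholdCalibration(dict(self.baseline_max), lam)


def compute_baseline_max(
    recording: EMGRecording,
    baseline_span_s: float = 4.0,
    skip_s: float = TRANSIENT_SKIP_S,
) -> ThresholdCalibration:
    """Peak |signal| over the first ``baseline_span_s`` of every round's
    leading rest block, per channel (skipping ``skip_s`` of filter startup)."""
    fs = recording.sampling_rate
    spans = recording.schedule.block_spans()
    table: dict[tuple[str, int, int], float] = {}
    for rs in recording.schedule.round_boundaries:
        first = next(
            ((label, a, b) for label, a, b in spans if a == rs.start_sample), None
        )
        if first is None or first[0] != REST:
            raise ValueError(
                f"round {rs.round_index} of {rs.gesture!r} does not start with rest"
            )
        label, a, b = first
        lo = a + int(round(skip_s * fs))
        hi = lo + int(round(baseline_span_s * fs))
        if hi > b:
            raise ValueError(
                f"leading rest of round {rs.round_index} ({rs.gesture!r}) is shorter "
                f"than skip + baseline span ({skip_s}+{baseline_span_s} s)"
            )
        for c in range(N_CHANNELS):
            table[(rs.gesture, rs.round_index, c)] = float(
                np.max(np.abs(recording.samples[c, lo:hi]))
            )
    return ThresholdCalibration(table)


def _rest_mask_in_rounds(
    schedule: ProtocolSchedule, skip_s: float = TRANSIENT_SKIP_S
) -> np.ndarray:
    """Commanded-rest samples inside round spans (minus round-start skip)."""
    fs = schedule.sampling_rate
    mask = np.zeros(schedule.n_samples, dtype=bool)
    skip = int(round(skip_s * fs))
    for rs in schedule.round_boundaries:
        mask[rs.start_sample : rs.end_sample] = True
        mask[rs.start_sample : rs.start_sample + skip] = False
    command = schedule.command_labels()
    mask &= command == REST
    return mask


def select_lambda(
    calibration: ThresholdCalibration,
    recording: EMGRecording,
    grid: np.ndarray | None = None,
) -> float:
    """Smallest grid lambda producing no threshold crossing inside any
    commanded rest span; falls back to lambda_max with a warning.

    Lambda trades onset sensitivity against rest-state false positives: the
    rule here maximizes sensitivity subject to zero false activations over
    the session's rest data.
    """
    if grid is None:
        grid = np.linspace(1.0, calibration.lambda_max, 21)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must not be empty")
    if np.min(grid) < 1.0:
        raise ValueError("lambda grid values must be >= 1")
    rest = _rest_mask_in_rounds(recording.schedule)
    peak_rest = np.array(
        [np.max(np.abs(recording.samples[c, rest]), initial=0.0) for c in range(N_CHANNELS)]
    )
    base = np.array([calibration.channel_baseline(c) for c in range(N_CHANNELS)])
    for lam in np.sort(grid):
        if not np.any(peak_rest > lam * base):
            return float(lam)
    lam_max = calibration.lambda_max
    warnings.warn(
        "every lambda in the grid yields rest-span threshold crossings; "
        f"falling back to lambda_max = {lam_max:.3f}",
        stacklevel=2,
    )
    return float(lam_max)


@dataclass
class ActivationTimeline:
    """Per-sample activated mask plus the activation points that created it."""

    activated: np.ndarray  # bool per sample
    activation_points: list[tuple[str, int, int]] = field(default_factory=list)
    activation_duration_s: float = 5.0


def detect_activation(
    recording: EMGRecording,
    calibration: ThresholdCalibration,
    activation_duration_s: float = 5.0,
) -> ActivationTimeline:
    """Threshold-crossing onset detection per commanded gesture block.

    For each gesture block, each channel is scanned from the rest-to-gesture
    command boundary for its first sample with |signal| > threshold; the
    earliest crossing across the three channels is the activation point, and
    the activated state holds for ``activation_duration_s`` from it.  Blocks
    with no crossing contribute no activated samples.
    """
    thr = calibration.thresholds
    n = recording.n_samples
    dur = int(round(activation_duration_s * recording.sampling_rate))
    activated = np.zeros(n, dtype=bool)
    points: list[tuple[str, int, int]] = []
    for g, r, a, b in recording.schedule.gesture_blocks():
        onset = None
        for c in range(N_CHANNELS):
            hits = np.flatnonzero(np.abs(recording.samples[c, a:b]) > thr[c])
            if hits.size:
                cand = a + int(hits[0])
                onset = cand if onset is None else min(onset, cand)
        if onset is not None:
            activated[onset : min(onset + dur, n)] = True
            points.append((g, r, onset))
    return ActivationTimeline(activated, points, activation_duration_s)


def ideal_timeline(schedule: ProtocolSchedule) -> ActivationTimeline:
    """Noise-free reference timeline: activated exactly during commanded
    gesture blocks (zero latency, perfect detection)."""
    activated = np.zeros(schedule.n_samples, dtype=bool)
    points = []
    for g, r, a, b in schedule.gesture_blocks():
        activated[a:b] = True
        points.append((g, r, a))
    return ActivationTimeline(activated, points)


def annotate(
    windows: pd.DataFrame,
    timeline: ActivationTimeline,
    schedule: ProtocolSchedule,
    spec: WindowingSpec = WindowingSpec(),
    subject_id: str = "S01",
) -> pd.DataFrame:
    """Label each window: the round's gesture iff >50 % of its samples are
    activated, rest otherwise.

    ``windows`` needs a start_sample column; gesture/round are filled from
    the schedule when missing (a window overlapping two rounds is assigned
    to the round owning the majority of its span, and logged).
    """
    fs = schedule.sampling_rate
    w = spec.window_samples(fs)
    starts = windows["start_sample"].to_numpy(dtype=int)
    if len(starts) and (starts.min() < 0 or starts.max() + w > schedule.n_samples):
        raise ValueError("window out of recording bounds")

    if {"gesture", "round"}.issubset(windows.columns):
        gestures = windows["gesture"].to_numpy(dtype=object)
        rounds = windows["round"].to_numpy(dtype=int)
    else:
        gestures = np.empty(len(starts), dtype=object)
        rounds = np.zeros(len(starts), dtype=int)
        for i, s in enumerate(starts):
            best, overlap = None, 0
            for rs in schedule.round_boundaries:
                ov = min(s + w, rs.end_sample) - max(s, rs.start_sample)
                if ov > overlap:
                    best, overlap = rs, ov
            if best is None:
                raise ValueError(f"window at {s} overlaps no round")
            if overlap < w:
                logger.info(
                    "window at %d straddles round boundaries; assigned to %s round %d",
                    s, best.gesture, best.round_index,
                )
            gestures[i] = best.gesture
            rounds[i] = best.round_index

    # activated-sample count per window via a cumulative sum
    csum = np.concatenate([[0], np.cumsum(timeline.activated.astype(np.int64))])
    active = csum[starts + w] - csum[starts]
    labels = np.where(active > w / 2, gestures, REST)
    return pd.DataFrame(
        {
            "subject": subject_id,
            "gesture": gestures,
            "round": rounds,
            "start_sample": starts,
            "label": labels,
        }
    )


def label_recording(
    recording: EMGRecording,
    spec: WindowingSpec = WindowingSpec(),
    lam: float | str = "auto",
    lambda_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ThresholdCalibration, ActivationTimeline]:
    """Calibrate, detect activation and annotate one (filtered) recording."""
    calib = compute_baseline_max(recording)
    if lam == "auto":
        calib = calib.with_lambda(select_lambda(calib, recording, lambda_grid))
    else:
        calib = calib.with_lambda(float(lam))
    timeline = detect_activation(recording, calib)
    windows = segment_rounds(recording.schedule, spec)
    labeled = annotate(windows, timeline, recording.schedule, spec, recording.subject_id)
    return labeled, calib, timeline
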