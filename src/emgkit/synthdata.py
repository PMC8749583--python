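"""Protocol-faithful synthetic surface-EMG generation.

Emulates a three-channel forearm recording session in which a subject
alternates 5-s rest and 5-s gesture blocks (five such sets per round, four
rounds per gesture, a 10-s rest between rounds) for nine non-rest gestures.
Each channel is a band-limited (20-450 Hz) zero-mean stochastic carrier,
amplitude-modulated by a trapezoidal activation envelope, with additive
60-Hz line interference.  Amplitudes are in arbitrary units: only the
gesture/rest gain ratios matter downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

REST = "rest"
GESTURES: tuple[str, ...] = (
    "rock",
    "scissors",
    "paper",
    "one",
    "three",
    "four",
    "good",
    "okay",
    "finger_gun",
)
CLASSES: tuple[str, ...] = GESTURES + (REST,)
N_CHANNELS = 3
DEFAULT_FS = 2000.0

# Per-gesture carrier amplitudes (channels = flexor carpi radialis, flexor
# carpi ulnaris, brachioradialis).  Values are arbitrary units chosen so
# every gesture activates at least one muscle well above the rest baseline
# and no two gestures share the same three-channel pattern.
_DEFAULT_GESTURE_GAIN: dict[str, tuple[float, float, float]] = {
    "rock": (6.0, 6.0, 6.0),
    "scissors": (6.0, 1.5, 1.5),
    "paper": (1.5, 6.0, 1.5),
    "one": (1.5, 1.5, 6.0),
    "three": (6.0, 6.0, 1.5),
    "four": (6.0, 1.5, 6.0),
    "good": (1.5, 6.0, 6.0),
    "okay": (3.5, 3.5, 1.5),
    "finger_gun": (1.5, 3.5, 3.5),
}


@dataclass(frozen=True)
class RoundSpan:
    """Half-open sample span [start, end) of one round of one gesture."""

    gesture: str
    round_index: int  # 1-based
    start_sample: int
    end_sample: int


@dataclass
class ProtocolSchedule:
    """Commanded block sequence of a recording session.

    ``blocks`` is an ordered list of ``(label, duration_s)`` pairs where the
    label is either a gesture name or ``"rest"``.  ``round_boundaries`` maps
    every (gesture, round) pair to its sample span; inter-round rest blocks
    lie outside all rounds.
    """

    blocks: list[tuple[str, float]]
    sampling_rate: float
    round_boundaries: list[RoundSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for label, dur in self.blocks:
            if dur <= 0:
                raise ValueError(f"block {label!r} has non-positive duration {dur}")
            n = dur * self.sampling_rate
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"block {label!r}: duration {dur} s is not an integer number "
                    f"of samples at {self.sampling_rate} Hz"
                )

    @property
    def n_samples(self) -> int:
        return int(round(sum(d for _, d in self.blocks) * self.sampling_rate))

    def block_spans(self) -> list[tuple[str, int, int]]:
        """(label, start_sample, end_sample) for every block, in order."""
        spans = []
        pos = 0
        for label, dur in self.blocks:
            n = int(round(dur * self.sampling_rate))
            spans.append((label, pos, pos + n))
            pos += n
        return spans

    def command_labels(self) -> np.ndarray:
        """Per-sample commanded label (object array of str)."""
        out = np.empty(self.n_samples, dtype=object)
        for label, a, b in self.block_spans():
            out[a:b] = label
        return out

    def gesture_blocks(self) -> list[tuple[str, int, int, int]]:
        """(gesture, round_index, start, end) of every non-rest block."""
        out = []
        for rs in self.round_boundaries:
            for label, a, b in self.block_spans():
                if label != REST and a >= rs.start_sample and b <= rs.end_sample:
                    out.append((rs.gesture, rs.round_index, a, b))
        return out

    def round_of_sample(self, sample: int) -> RoundSpan | None:
        for rs in self.round_boundaries:
            if rs.start_sample <= sample < rs.end_sample:
                return rs
        return None

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "blocks": [[label, float(dur)] for label, dur in self.blocks],
            "round_boundaries": [
                [rs.gesture, rs.round_index, rs.start_sample, rs.end_sample]
                for rs in self.round_boundaries
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolSchedule":
        return cls(
            blocks=[(str(l), float(t)) for l, t in d["blocks"]],
            sampling_rate=float(d["sampling_rate"]),
            round_boundaries=[
                RoundSpan(str(g), int(r), int(a), int(b))
                for g, r, a, b in d.get("round_boundaries", [])
            ],
        )


def build_schedule(
    gestures: Sequence[str] = GESTURES,
    rounds: int = 4,
    sets_per_round: int = 5,
    rest_s: float = 5.0,
    gesture_s: float = 5.0,
    interround_rest_s: float = 10.0,
    fs: float = DEFAULT_FS,
) -> ProtocolSchedule:
    """Build the commanded block schedule of a full recording session.

    For each gesture, each round consists of ``sets_per_round`` sets of
    (rest ``rest_s``, gesture ``gesture_s``); a rest of
    ``interround_rest_s`` separates consecutive rounds (and consecutive
    gestures).  Deterministic.
    """
    if not gestures:
        raise ValueError("gesture list must not be empty")
    if len(set(gestures)) != len(gestures):
        raise ValueError("gesture names must be unique")
    if REST in gestures:
        raise ValueError(f"{REST!r} cannot be a commanded gesture")
    if rounds < 1 or sets_per_round < 1:
        raise ValueError("rounds and sets_per_round must be >= 1")
    if min(rest_s, gesture_s, interround_rest_s) <= 0:
        raise ValueError("all durations must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")

    blocks: list[tuple[str, float]] = []
    boundaries: list[RoundSpan] = []
    pos = 0

    def n_of(dur: float) -> int:
        return int(round(dur * fs))

    n_total = len(gestures) * rounds
    done = 0
    for g in gestures:
        for r in range(1, rounds + 1):
            start = pos
            for _ in range(sets_per_round):
                blocks.append((REST, rest_s))
                pos += n_of(rest_s)
                blocks.append((g, gesture_s))
                pos += n_of(gesture_s)
            boundaries.append(RoundSpan(g, r, start, pos))
            done += 1
            if done < n_total:  # no trailing rest after the final round
                blocks.append((REST, interround_rest_s))
                pos += n_of(interround_rest_s)
    return ProtocolSchedule(blocks=blocks, sampling_rate=fs, round_boundaries=boundaries)


@dataclass
class SubjectProfile:
    """Amplitude model of one simulated subject.

    gesture_gain maps each gesture to its three per-channel carrier
    amplitudes; rest_gain is the per-channel baseline amplitude.
    onset_latency_s bounds the uniform delay between a gesture command and
    muscle activation (drawn per block per channel); ramp_s is the linear
    envelope rise/fall time; line_amp the 60-Hz interference amplitude.
    """

    gesture_gain: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GESTURE_GAIN)
    )
    rest_gain: tuple[float, float, float] = (0.3, 0.3, 0.3)
    onset_latency_s: tuple[float, float] = (0.0, 0.3)
    ramp_s: float = 0.2
    line_amp: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.rest_gain):
            raise ValueError("rest_gain must be strictly positive")
        for g, gains in self.gesture_gain.items():
            if len(gains) != N_CHANNELS:
                raise ValueError(f"gesture {g!r}: expected {N_CHANNELS} channel gains")
            if not any(gains[c] >= self.rest_gain[c] for c in range(N_CHANNELS)):
                raise ValueError(f"gesture {g!r} activates no channel above rest")
        lo, hi = self.onset_latency_s
        if lo < 0 or hi < lo:
            raise ValueError("onset_latency_s must satisfy 0 <= low <= high")
        if self.ramp_s < 0 or self.line_amp < 0:
            raise ValueError("ramp_s and line_amp must be non-negative")

    def to_dict(self) -> dict:
        return {
            "gesture_gain": {
                g: [float(x) for x in v] for g, v in self.gesture_gain.items()
            },
            "rest_gain": [float(x) for x in self.rest_gain],
            "onset_latency_s": [float(x) for x in self.onset_latency_s],
            "ramp_s": float(self.ramp_s),
            "line_amp": float(self.line_amp),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubjectProfile":
        kw = dict(d)
        kw["gesture_gain"] = {g: tuple(v) for g, v in kw["gesture_gain"].items()}
        kw["rest_gain"] = tuple(kw["rest_gain"])
        kw["onset_latency_s"] = tuple(kw["onset_latency_s"])
        return cls(**kw)


@dataclass
class EMGRecording:
    """A multi-channel EMG time series plus the schedule it was recorded under."""

    samples: np.ndarray  # (3, n) float
    sampling_rate: float
    schedule: ProtocolSchedule
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(f"samples must be ({N_CHANNELS}, n)")
        if self.samples.shape[1] != self.schedule.n_samples:
            raise ValueError(
                f"recording length {self.samples.shape[1]} does not match "
                f"schedule total {self.schedule.n_samples}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def copy_with(self, samples: np.ndarray) -> "EMGRecording":
        return EMGRecording(samples, self.sampling_rate, self.schedule, self.subject_id)


def _carrier(rng: np.random.Generator, n: int, fs: float,
             band: tuple[float, float] = (20.0, 450.0), order: int = 4) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise carrier (zero-phase shaped)."""
    white = rng.standard_normal(n)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def activation_envelope(
    schedule: ProtocolSchedule,
    profile: SubjectProfile,
    latencies_s: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel trapezoidal amplitude envelope, shape (3, n).

    With zero latency and zero ramp this equals rest_gain outside commanded
    gesture blocks and gesture_gain inside them, exactly.
    """
    fs = schedule.sampling_rate
    n = schedule.n_samples
    env = np.tile(np.asarray(profile.rest_gain, dtype=float)[:, None], (1, n))
    gblocks = schedule.gesture_blocks()
    if latencies_s is None:
        latencies_s = np.zeros((len(gblocks), N_CHANNELS))
    ramp = int(round(profile.ramp_s * fs))
    for (g, _r, a, b), lats in zip(gblocks, latencies_s):
        gains = profile.gesture_gain[g]
        for c in range(N_CHANNELS):
            rest = profile.rest_gain[c]
            gain = gains[c]
            onset = min(a + int(round(lats[c] * fs)), b)
            rise_end = min(onset + ramp, b)
            if rise_end > onset:
                k = np.arange(1, rise_end - onset + 1)
                env[c, onset:rise_end] = rest + (gain - rest) * k / ramp
            env[c, rise_end:b] = gain
            fall_end = min(b + ramp, n)
            if fall_end > b and ramp > 0:
                k = np.arange(1, fall_end - b + 1)
                env[c, b:fall_end] = gain + (rest - gain) * k / ramp
    return env


def synthesize_recording(
    schedule: ProtocolSchedule,
    profile: SubjectProfile,
    subject_id: str = "S01",
    carrier_band: tuple[float, float] = (20.0, 450.0),
) -> EMGRecording:
    """Simulate one subject's recording under the given schedule.

    Each channel is ``envelope * carrier + line_amp * sin(2*pi*60*t + phi)``
    where the carrier is unit-RMS band-limited Gaussian noise.  Identical
    (schedule, profile) inputs produce bit-identical output.
    """
    missing = {g for g, *_ in schedule.gesture_blocks()} - set(profile.gesture_gain)
    if missing:
        raise ValueError(f"profile lacks gains for gestures: {sorted(missing)}")
    fs = schedule.sampling_rate
    n = schedule.n_samples
    rng = np.random.default_rng(profile.seed)
    gblocks = schedule.gesture_blocks()
    lo, hi = profile.onset_latency_s
    latencies = rng.uniform(lo, hi, size=(len(gblocks), N_CHANNELS))
    env = activation_envelope(schedule, profile, latencies)
    t = np.arange(n) / fs
    samples = np.empty((N_CHANNELS, n))
    phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    for c in range(N_CHANNELS):
        carrier = _carrier(rng, n, fs, carrier_band)
        samples[c] = env[c] * carrier + profile.line_amp * np.sin(
            2 * np.pi * 60.0 * t + phases[c]
        )
    return EMGRecording(samples, fs, schedule, subject_id)


def make_cohort(
    n_subjects: int,
    base_profile: SubjectProfile | None = None,
    variability: float = 0.2,
    seed: int = 0,
    schedule: ProtocolSchedule | None = None,
) -> list[tuple[SubjectProfile, EMGRecording]]:
    """Simulate a cohort with multiplicative log-normal gain variability.

    Every gain of the base profile is multiplied by exp(N(0, variability^2)),
    independently per subject/gesture/channel, emulating inter-subject
    amplitude differences; variability 0 reproduces the base gains exactly.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if variability < 0:
        raise ValueError("variability must be non-negative")
    base_profile = base_profile or SubjectProfile()
    schedule = schedule or build_schedule()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(1, n_subjects + 1):
        gg = {
            g: tuple(
                v * np.exp(rng.normal(0.0, variability)) for v in gains
            )
            for g, gains in base_profile.gesture_gain.items()
        }
        rg = tuple(v * np.exp(rng.normal(0.0, variability)) for v in base_profile.rest_gain)
        prof = dataclasses.replace(
            base_profile,
            gesture_gain=gg,
            rest_gain=rg,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sid = f"S{i:02d}"
        cohort.append((prof, synthesize_recording(schedule, prof, subject_id=sid)))
    return cohort


# ---------------------------------------------------------------------------
# Delimited-text recording I/O

def write_recording_csv(recording: EMGRecording, path) -> None:
    """Write `time_s, ch1, ch2, ch3, command` CSV (UTF-8, '.' decimals)."""
    t = np.arange(recording.n_samples) / recording.sampling_rate
    df = pd.DataFrame(
        {
            "time_s": t,
            "ch1": recording.samples[0],
            "ch2": recording.samples[1],
            "ch3": recording.samples[2],
            "command": recording.schedule.command_labels(),
        }
    )
    df.to_csv(path, index=False)


def read_recording_csv(
    path,
    schedule: ProtocolSchedule | None = None,
    subject_id: str = "S01",
    sets_per_round: int = 5,
) -> EMGRecording:
    """Read a recording CSV; infer the schedule from the command column if
    one is not supplied (rounds then grouped by consecutive rest/gesture
    sets, ``sets_per_round`` sets per round)."""
    df = pd.read_csv(path)
    required = {"time_s", "ch1", "ch2", "ch3", "command"}
    if not required.issubset(df.columns):
        raise ValueError(f"recording CSV must have columns {sorted(required)}")
    samples = df[["ch1", "ch2", "ch3"]].to_numpy().T
    if schedule is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])
        fs = 1.0 / float(dt[0])
        schedule = infer_schedule(
            df["command"].to_numpy(dtype=object), fs, sets_per_round
        )
    return EMGRecording(samples, schedule.sampling_rate, schedule, subject_id)


def infer_schedule(
    command: np.ndarray, fs: float, sets_per_round: int = 5
) -> ProtocolSchedule:
    """Rebuild a ProtocolSchedule from a per-sample command array.

    Rounds are reconstructed by grouping each gesture's consecutive
    (rest, gesture) set pairs into groups of ``sets_per_round``.  The set
    rest duration is taken as the modal rest length preceding gesture
    blocks; rest blocks of any other length separate rounds.  (If the
    inter-round rest happens to equal the set rest, only the set count
    disambiguates.)
    """
    command = np.asarray(command, dtype=object)
    change = np.flatnonzero(command[1:] != command[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(command)]])
    blocks = [(str(command[a]), (b - a) / fs) for a, b in zip(starts, ends)]
    spans = list(zip(starts, ends))

    pre_gesture = [
        blocks[i][1]
        for i in range(len(blocks) - 1)
        if blocks[i][0] == REST and blocks[i + 1][0] != REST
    ]
    if not pre_gesture:
        return ProtocolSchedule(blocks=blocks, sampling_rate=fs, round_boundaries=[])
    # the set rest is the modal rest length before a gesture block; a longer
    # rest there is an inter-round (or inter-gesture) pause merged with the
    # next round's leading set rest
    durs, freq = np.unique(pre_gesture, return_counts=True)
    set_rest = float(durs[np.argmax(freq)])
    rest_n = int(round(set_rest * fs))

    boundaries: list[RoundSpan] = []
    counts: dict[str, int] = {}
    i = 0
    while i < len(blocks) - 1:
        if (
            blocks[i][0] == REST
            and blocks[i][1] >= set_rest
            and blocks[i + 1][0] != REST
        ):
            g = blocks[i + 1][0]
            round_start = int(spans[i][1]) - rest_n
            round_end = int(spans[i + 1][1])
            nsets = 1
            i += 2
            while (
                i < len(blocks) - 1
                and blocks[i][0] == REST
                and blocks[i][1] == set_rest
                and blocks[i + 1][0] == g
                and nsets < sets_per_round
            ):
                nsets += 1
                round_end = int(spans[i + 1][1])
                i += 2
            counts[g] = counts.get(g, 0) + 1
            boundaries.append(RoundSpan(g, counts[g], round_start, round_end))
        else:
            i += 1
    return ProtocolSchedule(blocks=blocks, sampling_rate=fs, round_boundaries=boundaries)


def save_schedule_yaml(schedule: ProtocolSchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(schedule.to_dict(), fh)


def load_schedule_yaml(path) -> ProtocolSchedule:
    with open(path, encoding="utf-8") as fh:
        return ProtocolSchedule.from_dict(yaml.safe_load(fh))


def save_profile_yaml(profile: SubjectProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(profile.to_dict(), fh)


def load_profile_yaml(path) -> SubjectProfile:
    with open(path, encoding="utf-8") as fh:
        return SubjectProfile.from_dict(yaml.safe_load(fh))
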