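"""Digital filtering of raw EMG recordings.

Two Butterworth filters are applied per channel: a 4th-order 20-500 Hz
bandpass (EMG energy lies almost entirely in this band) and a 7th-order
59.5-60.5 Hz bandstop for power-line interference.  Filtering is causal
single-pass by default, matching a real-time pipeline; a zero-phase
two-pass option is available for offline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthdata import EMGRecording


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth filter stage."""

    kind: str  # "bandpass" | "bandstop"
    order: int
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"filter edge {self.high_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )
        return sps.butter(
            self.order, (self.low_hz, self.high_hz), btype=self.kind, fs=fs,
            output="sos",
        )


DEFAULT_BANDPASS = FilterSpec("bandpass", 4, 20.0, 500.0)
DEFAULT_BANDSTOP = FilterSpec("bandstop", 7, 59.5, 60.5)


def default_filters() -> list[FilterSpec]:
    return [DEFAULT_BANDPASS, DEFAULT_BANDSTOP]


def filter_array(
    x: np.ndarray,
    fs: float,
    specs: list[FilterSpec] | None = None,
    zero_phase: bool = False,
) -> np.ndarray:
    """Apply the filter cascade along the last axis of ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains non-finite values")
    specs = default_filters() if specs is None else specs
    y = x
    for spec in specs:
        sos = spec.sos(fs)  # validates edges against Nyquist
        y = sps.sosfiltfilt(sos, y, axis=-1) if zero_phase else sps.sosfilt(sos, y, axis=-1)
    return y


def apply_filters(
    recording: EMGRecording,
    specs: list[FilterSpec] | None = None,
    zero_phase: bool = False,
) -> EMGRecording:
    """Return a new recording with each channel filtered in the listed order."""
    y = filter_array(recording.samples, recording.sampling_rate, specs, zero_phase)
    return recording.copy_with(y)
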