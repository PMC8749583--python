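"""Windowing arithmetic, threshold calibration and activation labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emgkit.segmentlabel import (
    ActivationTimeline,
    CalibrationError,
    ThresholdCalibration,
    WindowingSpec,
    annotate,
    compute_baseline_max,
    detect_activation,
    ideal_timeline,
    segment,
    segment_rounds,
    select_lambda,
)
from emgkit.synthdata import (
    EMGRecording,
    REST,
    SubjectProfile,
    build_schedule,
    synthesize_recording,
)

FS = 2000.0


class TestSegment:
    def test_single_window(self):
        spec = WindowingSpec(window_s=0.25, step_s=0.025)
        assert list(segment(500, spec, FS)) == [0]

    def test_five_seconds_gives_191_windows(self):
        starts = segment(10_000, WindowingSpec(), FS)
        assert len(starts) == 191  # (10000 - 500) / 50 + 1
        assert starts[0] == 0 and starts[-1] == 9_500

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            segment(499, WindowingSpec(), FS)

    def test_default_overlap_90_percent(self):
        assert WindowingSpec().overlap() == pytest.approx(0.9)

    @given(
        w=st.integers(1, 60),
        s_frac=st.integers(1, 60),
        extra=st.integers(0, 300),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_matches_enumeration(self, w, s_frac, extra):
        s = min(s_frac, w)
        length = w + extra
        spec = WindowingSpec(window_s=float(w), step_s=float(s))
        starts = segment(length, spec, fs=1.0)
        brute = []
        pos = 0
        while pos + w <= length:
            brute.append(pos)
            pos += s
        assert list(starts) == brute


def _single_round_recording(samples: np.ndarray, gesture="g") -> EMGRecording:
    """One round, one set: rest 5 s then gesture 5 s (20 000 samples)."""
    sched = build_schedule([gesture], rounds=1, sets_per_round=1)
    return EMGRecording(samples, FS, sched)


class TestBaselineMax:
    def test_all_zero_signal_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            compute_baseline_max(_single_round_recording(np.zeros((3, 20_000))))

    def test_matches_direct_scan(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 20_000))
        cal = compute_baseline_max(_single_round_recording(x))
        # baseline = first 4 s of the leading rest, after the 0.25-s skip
        for c in range(3):
            assert cal.baseline_max[("g", 1, c)] == np.max(np.abs(x[c, 500:8500]))

    def test_lambda_max_is_ratio_of_round_baselines(self):
        sched = build_schedule(["g"], rounds=2, sets_per_round=1)
        rng = np.random.default_rng(1)
        template = np.tile(rng.standard_normal(20_000), (3, 1))
        x = np.concatenate([template, np.zeros((3, 20_000)), 2 * template], axis=1)
        # blocks: round1 (20k), inter-round rest 10 s (20k), round2 (20k);
        # round-2 rest amplitude is exactly twice round 1's
        rec = EMGRecording(x, FS, sched)
        cal = compute_baseline_max(rec)
        assert cal.lambda_max == pytest.approx(2.0)

    def test_round_not_starting_with_rest_rejected(self):
        sched = build_schedule(["g"], rounds=1, sets_per_round=1, rest_s=3.0)
        rec = EMGRecording(np.ones((3, 16_000)), FS, sched)
        with pytest.raises(ValueError, match="shorter than skip"):
            compute_baseline_max(rec)


def _piecewise_recording(rest_amp=1.0, gest_amp=5.0, rest_spike=None):
    """Two-set single-round recording with controllable rest-span spike.

    Layout (5-s blocks): rest | g | rest | g.  The baseline span lives in
    the first rest block; the optional spike lands mid-way through the
    second rest block.
    """
    sched = build_schedule(["g"], rounds=1, sets_per_round=2)
    n = sched.n_samples
    x = np.zeros((3, n))
    labels = sched.command_labels()
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # keep zero-mean
    x[:] = np.where(labels == "g", gest_amp, rest_amp) * sign
    if rest_spike is not None:
        x[:, 25_000] = rest_spike  # inside the second rest block
    return EMGRecording(x, FS, sched)


class TestSelectLambda:
    def test_clean_rest_selects_one(self):
        rec = _piecewise_recording()
        cal = compute_baseline_max(rec)
        assert select_lambda(cal, rec, np.array([1.0, 1.5, 2.0])) == 1.0

    def test_rest_spike_raises_lambda(self):
        rec = _piecewise_recording(rest_spike=1.4)
        cal = compute_baseline_max(rec)
        assert select_lambda(cal, rec, np.array([1.0, 1.5, 2.0])) == 1.5

    def test_all_failing_falls_back_to_lambda_max(self):
        rec = _piecewise_recording(rest_spike=30.0)
        cal = compute_baseline_max(rec)
        with pytest.warns(UserWarning, match="lambda_max"):
            lam = select_lambda(cal, rec, np.array([1.0, 1.2]))
        assert lam == pytest.approx(cal.lambda_max)

    def test_empty_or_invalid_grid_rejected(self):
        rec = _piecewise_recording()
        cal = compute_baseline_max(rec)
        with pytest.raises(ValueError):
            select_lambda(cal, rec, np.array([]))
        with pytest.raises(ValueError):
            select_lambda(cal, rec, np.array([0.5, 1.0]))


def _crossing_recording(cross_times_s):
    """Single-round recording whose channels first exceed the threshold at
    the given offsets (s) after the gesture command at t = 5 s."""
    sched = build_schedule(["g"], rounds=1, sets_per_round=1)
    n = sched.n_samples
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    x = 0.5 * np.tile(sign, (3, 1))  # rest-level activity everywhere
    for c, dt in enumerate(cross_times_s):
        if dt is not None:
            x[c, 10_000 + int(dt * FS):] = 2.0 * sign[10_000 + int(dt * FS):]
    return EMGRecording(x, FS, sched)


class TestDetectActivation:
    def test_earliest_channel_wins(self):
        rec = _crossing_recording([1.00, 0.95, 1.10])
        cal = compute_baseline_max(rec).with_lambda(1.0)
        tl = detect_activation(rec, cal)
        assert tl.activation_points == [("g", 1, 10_000 + int(0.95 * FS))]

    def test_no_crossing_leaves_block_inactive(self):
        rec = _crossing_recording([None, None, None])
        cal = compute_baseline_max(rec).with_lambda(1.0)
        tl = detect_activation(rec, cal)
        assert tl.activation_points == []
        assert not tl.activated.any()

    def test_activated_run_is_five_seconds(self):
        rec = _crossing_recording([0.0, None, None])
        cal = compute_baseline_max(rec).with_lambda(1.0)
        tl = detect_activation(rec, cal)
        start = 10_000
        assert tl.activated[start : start + 10_000].all()
        assert tl.activated.sum() == 10_000  # exactly 5 s, clipped at the end

    def test_raising_lambda_never_increases_activation(self):
        sched = build_schedule(["g"], rounds=1, sets_per_round=2)
        rec = synthesize_recording(
            sched, SubjectProfile(gesture_gain={"g": (1.5, 0.6, 0.9)}, seed=8)
        )
        cal = compute_baseline_max(rec)
        counts = []
        for lam in [1.0, 1.5, 2.0, 4.0, 8.0]:
            tl = detect_activation(rec, cal.with_lambda(lam))
            counts.append(int(tl.activated.sum()))
        assert counts == sorted(counts, reverse=True)


class TestAnnotate:
    SCHED = build_schedule(["g"], rounds=1, sets_per_round=1)
    SPEC = WindowingSpec()

    def _label_one_window(self, n_active):
        activated = np.zeros(self.SCHED.n_samples, dtype=bool)
        activated[10_000 : 10_000 + n_active] = True
        tl = ActivationTimeline(activated)
        win = pd.DataFrame({"gesture": ["g"], "round": [1], "start_sample": [10_000]})
        return annotate(win, tl, self.SCHED, self.SPEC)["label"].iloc[0]

    def test_majority_rule_boundary(self):
        assert self._label_one_window(251) == "g"   # > 50 %
        assert self._label_one_window(250) == REST  # exactly 50 % is not enough
        assert self._label_one_window(500) == "g"

    def test_idempotent(self):
        tl = ideal_timeline(self.SCHED)
        wins = segment_rounds(self.SCHED, self.SPEC)
        a = annotate(wins, tl, self.SCHED, self.SPEC)
        b = annotate(a, tl, self.SCHED, self.SPEC)
        assert a["label"].tolist() == b["label"].tolist()

    def test_window_out_of_bounds_rejected(self):
        tl = ideal_timeline(self.SCHED)
        win = pd.DataFrame(
            {"gesture": ["g"], "round": [1], "start_sample": [self.SCHED.n_samples]}
        )
        with pytest.raises(ValueError, match="bounds"):
            annotate(win, tl, self.SCHED, self.SPEC)

    def test_round_assignment_from_schedule(self):
        sched = build_schedule(["a", "b"], rounds=1, sets_per_round=1)
        tl = ideal_timeline(sched)
        win = pd.DataFrame({"start_sample": [0, 45_000]})  # one window per round
        out = annotate(win, tl, sched, self.SPEC)
        assert out["gesture"].tolist() == ["a", "b"]
        assert out["round"].tolist() == [1, 1]


def test_segment_rounds_stays_inside_rounds():
    sched = build_schedule(["a", "b"], rounds=2, sets_per_round=1)
    wins = segment_rounds(sched)
    w = WindowingSpec().window_samples(FS)
    for rs in sched.round_boundaries:
        sub = wins[(wins.gesture == rs.gesture) & (wins["round"] == rs.round_index)]
        assert sub.start_sample.min() >= rs.start_sample
        assert sub.start_sample.max() + w <= rs.end_sample


def test_threshold_calibration_validation():
    with pytest.raises(CalibrationError):
        ThresholdCalibration({})
    with pytest.raises(CalibrationError):
        ThresholdCalibration({("g", 1, 0): 0.0})
    cal = ThresholdCalibration({("g", 1, c): 1.0 + c for c in range(3)})
    assert cal.thresholds == pytest.approx([1.0, 2.0, 3.0])
    assert cal.with_lambda(2.0).thresholds == pytest.approx([2.0, 4.0, 6.0])
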