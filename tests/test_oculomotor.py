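"""Filtering, differentiation, saccade detection and classification."""

import numpy as np
import pandas as pd
import pytest

from dualcue.observer import GazeSimParams, GazeTrace, simulate_gaze_trial
from dualcue.oculomotor import (
    SaccadeEvent,
    check_fixation,
    classification_table,
    classify_trial,
    detect_saccades,
    differentiate,
    lowpass_filter,
    summarize_gaze,
)


def make_trace(x, y=None, fs=1000.0, t0=-150.0):
    x = np.asarray(x, dtype=float)
    t = t0 + np.arange(x.size) * 1000.0 / fs
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return GazeTrace(t, x, y, 0.0, "right", "none", {"trial_id": 0})


class TestFilter:
    def test_dc_gain_unity(self):
        tr = make_trace(np.full(1000, 3.7))
        out = lowpass_filter(tr)
        np.testing.assert_allclose(out.x_deg, 3.7, atol=1e-9)

    def test_sinusoid_gains(self):
        """Forward-backward 2nd-order Butterworth: |H|^2 = 1/(1+(f/fc)^4).

        At 2x cutoff the two-pass gain is 1/17; at the cutoff it is 1/2.
        Measured at 8 kHz sampling, where bilinear-transform frequency
        warping of the analog prototype is negligible.
        """
        fs = 8000.0
        t = np.arange(0, int(2 * fs)) / fs
        for f, expected in ((60.0, 1 / 17.0), (30.0, 0.5)):
            tr = make_trace(np.sin(2 * np.pi * f * t), fs=fs)
            out = lowpass_filter(tr)
            mid = slice(2000, -2000)  # steady state away from edges
            gain = out.x_deg[mid].std() / tr.x_deg[mid].std()
            assert gain == pytest.approx(expected, rel=0.01)

    def test_linear_trend_preserved(self):
        tr = make_trace(0.01 * np.arange(2000))
        out = lowpass_filter(tr)
        inner = slice(100, -100)
        slope = np.polyfit(tr.t_ms[inner], out.x_deg[inner], 1)[0]
        assert slope == pytest.approx(0.01, abs=1e-6)

    def test_jittered_timestamps_rejected(self):
        tr = make_trace(np.zeros(100))
        tr.t_ms[50] += 0.5
        with pytest.raises(ValueError, match="jitter"):
            lowpass_filter(tr)


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        t = np.arange(0, 500.0)
        v = differentiate(t, 0.01 * t)  # 10 deg/s
        np.testing.assert_allclose(v, 10.0, atol=1e-9)

    def test_quadratic_exact_at_interior(self):
        t = np.arange(0, 200.0)
        pos = 1e-5 * t**2
        v = differentiate(t, pos)
        np.testing.assert_allclose(v[1:-1], 2e-5 * t[1:-1] * 1000, rtol=1e-9)

    def test_constant_is_zero(self):
        t = np.arange(0, 100.0)
        np.testing.assert_allclose(differentiate(t, np.full(100, 2.0)), 0.0,
                                   atol=1e-9)


class TestDetect:
    def test_fixation_noise_yields_no_events(self, rng):
        tr = make_trace(rng.normal(0, 0.02, 1000), rng.normal(0, 0.02, 1000))
        assert detect_saccades(lowpass_filter(tr)) == []

    def test_single_saccade_roundtrip(self, gaze_trial):
        rng = np.random.default_rng(0)
        p = GazeSimParams(noise_sd_deg=0.05,
                          p_error={"neutral": 0.0},
                          p_anticipatory={"neutral": 0.0})
        tr = simulate_gaze_trial(gaze_trial, p, rng)
        events = detect_saccades(lowpass_filter(tr))
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.onset_ms - tr.meta["regular_onset_ms"]) < 5.0
        assert ev.amplitude_deg == pytest.approx(5.0, abs=0.15)
        assert ev.direction == "right"
        assert ev.peak_velocity_deg_s > 200

    def test_two_event_trace_detected_in_order(self, gaze_trial):
        rng = np.random.default_rng(5)
        p = GazeSimParams(noise_sd_deg=0.0,
                          p_anticipatory={"neutral": 1.0},
                          p_error={"neutral": 0.0})
        tr = simulate_gaze_trial(gaze_trial, p, rng)
        events = detect_saccades(lowpass_filter(tr))
        assert len(events) == 2
        assert events[0].onset_ms < events[1].onset_ms
        assert events[0].amplitude_deg < events[1].amplitude_deg

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            SaccadeEvent(onset_ms=10, offset_ms=5, amplitude_deg=1,
                         peak_velocity_deg_s=100, direction="left")


def event(latency, amp, direction="right"):
    return SaccadeEvent(latency, latency + 40.0, amp, 100.0, direction)


class TestClassify:
    TRIAL = {"trial_id": 3, "target_side": "right", "salient_side": "left",
             "trial_type": "invalid"}

    def test_regular_correct(self):
        c = classify_trial([event(100.0, 3.0)], self.TRIAL)
        assert c.regular is not None and c.regular_label == "correct"
        assert not c.aberrant

    def test_regular_erroneous(self):
        c = classify_trial([event(100.0, 3.0, "left")], self.TRIAL)
        assert c.regular_label == "erroneous"

    def test_anticipatory_window(self):
        c = classify_trial([event(50.0, 1.5)], self.TRIAL)
        assert c.regular is None and c.regular_label == "none"
        assert len(c.anticipatory) == 1

    def test_late_event_unclassified(self):
        c = classify_trial([event(600.0, 4.0)], self.TRIAL)
        assert c.regular is None and not c.anticipatory
        assert c.n_unclassified == 1

    def test_open_boundaries(self):
        # exactly at a window edge -> unclassified
        for lat in (80.0, 500.0, -70.0):
            c = classify_trial([event(lat, 3.0)], self.TRIAL)
            assert c.regular is None
            assert not c.anticipatory or lat != 80.0

    def test_amplitude_floors(self):
        assert classify_trial([event(100.0, 1.5)], self.TRIAL).regular is None
        assert not classify_trial([event(50.0, 0.5)], self.TRIAL).anticipatory

    def test_aberrant_and_partition(self):
        assert classify_trial([], self.TRIAL).aberrant
        evs = [event(-30.0, 1.5), event(150.0, 5.0), event(600.0, 3.0)]
        c = classify_trial(evs, self.TRIAL)
        n = (1 if c.regular else 0) + len(c.anticipatory) + c.n_unclassified
        assert n == len(evs)

    def test_first_qualifying_event_is_regular(self):
        evs = [event(90.0, 3.0, "left"), event(200.0, 4.0, "right")]
        c = classify_trial(evs, self.TRIAL)
        assert c.regular.onset_ms == 90.0 and c.regular_label == "erroneous"


def build_summary_frame():
    """97 correct + 3 erroneous regular saccades in one cell."""
    trials, cls = [], []
    for i in range(100):
        direction = "left" if i < 3 else "right"
        trials.append({"trial_id": i, "task": "gaze", "condition": "experimental",
                       "trial_type": "invalid", "validity_block": 50,
                       "salient_side": "left", "target_side": "right",
                       "soa_ms": 150.0, "cue_eccentricity_deg": 5.0})
        cls.append(classify_trial([event(150.0 + i, 4.0, direction)], trials[-1]))
    return cls, pd.DataFrame(trials)


class TestSummaries:
    def test_error_percentage_counting(self):
        cls, sched = build_summary_frame()
        res = summarize_gaze(cls, sched)
        row = res.iloc[0]
        assert row["pct_direction_errors"] == pytest.approx(3.0)
        assert row["n_saccades"] == 100

    def test_equal_latencies_zero_change(self):
        trials, cls = [], []
        for i, tt in enumerate(["neutral", "valid", "invalid"] * 10):
            trial = {"trial_id": i, "condition": "experimental",
                     "trial_type": tt, "validity_block": 50,
                     "salient_side": "none" if tt == "neutral" else "right",
                     "target_side": "right"}
            trials.append(trial)
            cls.append(classify_trial([event(150.0, 4.0)], trial))
        res = summarize_gaze(cls, pd.DataFrame(trials))
        assert np.allclose(res["latency_change_pct"], 0.0)

    def test_weighted_anticipatory_preference(self):
        """(10 antic, 80% salient) + (30 antic, 60% salient) -> 65%."""
        rows = []
        for pid, (n_antic, n_sal) in enumerate([(10, 8), (30, 18)]):
            rows.append({
                "participant": pid, "condition": "experimental",
                "validity_block": 50, "trial_type": "valid",
                "n_trials": 100, "n_aberrant": 0, "n_regular": 90,
                "n_correct": 90, "n_erroneous": 0,
                "n_anticipatory": n_antic, "n_saccades": 90 + n_antic,
                "mean_latency_ms": 160.0, "sem_latency_ms": 1.0,
                "pct_direction_errors": 0.0,
                "pct_anticipatory": 100 * n_antic / (90 + n_antic),
                "n_anticipatory_nonneutral": n_antic,
                "n_anticipatory_to_salient": n_sal,
                "latency_change_pct": 0.0,
            })
        per = pd.DataFrame(rows)
        w = per["n_anticipatory_nonneutral"]
        pref = 100 * per["n_anticipatory_to_salient"].sum() / w.sum()
        assert pref == pytest.approx(65.0)

    def test_classification_table_shape(self):
        cls, _ = build_summary_frame()
        tab = classification_table(cls)
        assert len(tab) == 100
        assert set(["regular_label", "n_anticipatory", "aberrant"]) <= set(tab.columns)


class TestFixationControl:
    def test_quiet_fixation(self):
        tr = make_trace(np.zeros(500))
        assert not check_fixation(tr)

    def test_excursion_detected(self):
        x = np.zeros(500)
        x[300:] = 2.5
        assert check_fixation(make_trace(x))

    def test_boundary_is_strict(self):
        x = np.zeros(500)
        x[300:] = 2.0
        assert not check_fixation(make_trace(x))
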