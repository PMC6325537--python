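"""Event-triggered windows, gating magnitudes, displacement, timing."""

import numpy as np
import pytest

from riagate.config import SimulationConfig
from riagate.events import (
    PeristimulusTable,
    StimulusEvent,
    bin_by_orientation,
    cross_correlation,
    detect_events,
    extract_peristimulus,
    head_displacement,
    peak_time_difference,
    position_velocity_path,
    sample_no_switch_events,
)
from riagate.recording import Recording


def _recording_from(theta, stimulus, fps=5.0, **traces):
    n = len(theta)
    t = np.arange(n) / fps
    base = dict(F_loop=np.zeros(n), F_nrV=np.zeros(n), F_nrD=np.zeros(n))
    base.update(traces)
    return Recording(time_s=t, theta=np.asarray(theta, float),
                     stimulus=np.asarray(stimulus, int), meta={"fps": fps}, **base)


def _table(data, pre_s=5.0, post_s=5.0, fps=5.0, thetas=None):
    data = np.atleast_2d(np.asarray(data, float))
    if thetas is None:
        thetas = np.zeros(len(data))
    events = [
        StimulusEvent(0, "off", float(th), "bent" if abs(th) > 0.5 else "unbent")
        for th in thetas
    ]
    return PeristimulusTable(events, data, pre_s, post_s, fps)


class TestDetectAndExtract:
    def test_detects_off_and_on_switches(self, wildtype_recording):
        events = detect_events(wildtype_recording)
        kinds = [e.kind for e in events]
        assert kinds == ["off", "on", "off", "on"]
        frames = [e.frame for e in events]
        assert frames == [100, 225, 350, 475]

    def test_window_length_is_51_frames_at_5hz(self, wildtype_recording):
        events = [e for e in detect_events(wildtype_recording) if e.kind == "off"]
        table = extract_peristimulus(wildtype_recording, events, "F_loop", 5.0, 5.0)
        assert table.data.shape == (2, 51)
        assert table.align_index == 25
        assert table.times[25] == 0.0

    def test_edge_events_dropped_and_counted(self):
        rec = _recording_from(np.zeros(100), np.r_[np.ones(3), np.zeros(97)])
        events = detect_events(rec, normalize_theta=False)
        table = extract_peristimulus(rec, events, "F_loop", pre_s=5.0, post_s=5.0)
        assert table.n_dropped == 1 and table.data.shape[0] == 0

    def test_constant_signal_gives_constant_rows(self, wildtype_recording):
        events = detect_events(wildtype_recording)
        rec = wildtype_recording
        flat = Recording(rec.time_s, rec.theta, rec.stimulus,
                         np.full(rec.n_frames, 3.3), rec.F_nrV, rec.F_nrD, rec.meta)
        table = extract_peristimulus(flat, events, "F_loop", 2.0, 2.0)
        np.testing.assert_allclose(table.data, 3.3)

    def test_empty_event_list_rejected(self, wildtype_recording):
        with pytest.raises(ValueError):
            extract_peristimulus(wildtype_recording, [], "F_loop")

    def test_no_switch_events_avoid_switches_and_are_seeded(self, wildtype_recording):
        a = sample_no_switch_events(wildtype_recording, 10, seed=3)
        b = sample_no_switch_events(wildtype_recording, 10, seed=3)
        assert [e.frame for e in a] == [e.frame for e in b]
        switch_frames = {e.frame for e in detect_events(wildtype_recording)}
        for ev in a:
            assert ev.kind == "no_switch"
            assert min(abs(ev.frame - s) for s in switch_frames) >= 25


class TestBinByOrientation:
    def test_single_occupied_bin_holds_grand_mean(self, rng):
        data = rng.normal(size=(12, 51))
        table = _table(data, thetas=np.full(12, 0.9))
        out = bin_by_orientation(table, n_bins=8)
        assert out["count"][7] == 12 and out["count"][:7].sum() == 0
        np.testing.assert_allclose(out["mean"][7], data.mean(axis=0))
        assert np.all(np.isnan(out["mean"][0]))

    def test_two_bins_split_at_zero(self):
        table = _table(np.zeros((4, 11)), pre_s=1.0, post_s=1.0,
                       thetas=[-0.9, -0.1, 0.1, 0.9])
        out = bin_by_orientation(table, n_bins=2)
        np.testing.assert_array_equal(out["count"], [2, 2])
        assert out["edges"][1] == 0.0

    def test_step_gated_data_shows_transient_only_in_outer_bins(self):
        cfg = SimulationConfig(duration_s=40.0, noise_sd=0.0, motor_gain=0.0,
                               switch_schedule=((20.0, "off"),))
        from riagate.synthetic import simulate_calcium, stimulus_series
        rows, thetas = [], []
        for th in (-0.9, -0.2, 0.2, 0.9):
            loop, _, _ = simulate_calcium(np.full(cfg.n_frames, th),
                                          stimulus_series(cfg), cfg)
            i0 = int(20.0 * cfg.fps)
            rows.append(loop[i0 - 25 : i0 + 26])
            thetas.append(th)
        out = bin_by_orientation(_table(rows, thetas=thetas), n_bins=4)
        spans = np.ptp(out["mean"], axis=1)
        assert spans[0] > 0.5 and spans[3] > 0.5  # outer bins: transient
        assert spans[1] < 1e-9 and spans[2] < 1e-9  # inner bins: flat


class TestResponseMagnitude:
    def test_flat_trace_pre_equals_post(self):
        from riagate.events import response_magnitude
        out = response_magnitude(_table(np.full((3, 51), 2.0)))
        np.testing.assert_allclose(out["pre"], out["post"])

    def test_gated_transient_matches_closed_form(self):
        # noiseless step-gated event: post - pre equals the windowed
        # waveform mean computed independently from the transient formula
        from riagate.events import response_magnitude
        cfg = SimulationConfig(duration_s=60.0, noise_sd=0.0, motor_gain=0.0,
                               switch_schedule=((30.0, "off"),))
        from riagate.synthetic import simulate_calcium, stimulus_series
        theta = np.full(cfg.n_frames, 0.9)
        loop, _, _ = simulate_calcium(theta, stimulus_series(cfg), cfg)
        i0 = int(30.0 * cfg.fps)
        table = _table([loop[i0 - 25 : i0 + 26]], thetas=[0.9])
        out = response_magnitude(table)
        # independent closed form of the rise/decay transient
        dt = 1 / cfg.fps
        tt = np.arange(1, 26) * dt
        w = (1 - np.exp(-tt / cfg.sensory_rise_s)) * np.exp(-tt / cfg.sensory_tau_s)
        t_pk = cfg.sensory_rise_s * np.log1p(cfg.sensory_tau_s / cfg.sensory_rise_s)
        w /= (1 - np.exp(-t_pk / cfg.sensory_rise_s)) * np.exp(-t_pk / cfg.sensory_tau_s)
        k = int(out["peak_index"][0]) - table.align_index - 1
        expected = cfg.sensory_amplitude * w[k - 2 : k + 3].mean()
        assert (out["post"] - out["pre"])[0] == pytest.approx(expected, rel=1e-9)

    def test_ungated_event_has_zero_response(self):
        from riagate.events import response_magnitude
        out = response_magnitude(_table(np.zeros((2, 51))))
        np.testing.assert_allclose(out["post"] - out["pre"], 0.0)


class TestDisplacementAndPaths:
    def test_constant_theta_zero_displacement(self):
        rec = _recording_from(np.full(200, 0.4), np.ones(200))
        ev = [StimulusEvent(50, "off", 0.4, "unbent")]
        out = head_displacement(rec, ev, normalize_theta=False)
        assert out["displacement"][0] == 0.0

    def test_signed_arithmetic(self):
        theta = np.zeros(100)
        theta[50], theta[60] = 0.8, -0.1
        rec = _recording_from(theta, np.ones(100))
        ev = [StimulusEvent(50, "off", 0.8, "bent")]
        out = head_displacement(rec, ev, horizon_s=2.0, normalize_theta=False)
        assert out["displacement"][0] == pytest.approx(-0.9)

    def test_insufficient_coverage_dropped(self):
        rec = _recording_from(np.full(20, 0.3), np.ones(20))
        ev = [StimulusEvent(15, "off", 0.3, "unbent")]
        out = head_displacement(rec, ev, horizon_s=2.0)
        assert len(out["displacement"]) == 0

    def test_pure_sinusoid_path_is_closed_ellipse(self):
        fps, period = 5.0, 4.0
        t = np.arange(0, 30, 1 / fps)
        theta = 0.8 * np.sin(2 * np.pi * t / period)
        rec = _recording_from(theta, np.ones(len(t)), fps=fps)
        ev = [StimulusEvent(50, "no_switch", theta[50], "unbent")]
        path = position_velocity_path(rec, ev, span_s=period, normalize_theta=False)[0]
        # harmonic motion: (theta/A)^2 + (v/(A*omega))^2 = 1
        omega = 2 * np.pi / period
        radius = (path["theta"] / 0.8) ** 2 + (path["velocity"] / (0.8 * omega)) ** 2
        np.testing.assert_allclose(radius[1:-1], 1.0, atol=0.06)
        assert path["theta"][0] == pytest.approx(path["theta"][-1], abs=1e-9)


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self, rng):
        x = rng.normal(size=200)
        lags, r = cross_correlation(x, x, max_lag_s=2.0, fps=5.0)
        assert lags[np.argmax(r)] == 0.0
        assert np.max(r) == pytest.approx(1.0)

    def test_delayed_copy_peaks_at_positive_lag(self):
        t = np.arange(0, 60, 0.2)
        y = np.sin(2 * np.pi * t / 4.0)
        x = np.sin(2 * np.pi * (t - 0.6) / 4.0)  # x lags y by 0.6 s
        lags, r = cross_correlation(x, y, max_lag_s=2.0, fps=5.0)
        assert lags[np.argmax(r)] == pytest.approx(0.6)

    def test_matches_brute_force_shifted_pearson(self, rng):
        # oracle: explicit O(n^2) loop over lags with per-overlap sums
        for _ in range(25):
            n = int(rng.integers(20, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            max_lag = 5
            lags, r = cross_correlation(x, y, max_lag_s=1.0, fps=5.0)
            for i, lag in enumerate(range(-max_lag, max_lag + 1)):
                pairs = [(x[t + lag], y[t]) for t in range(n)
                         if 0 <= t + lag < n]
                a = np.array([p[0] for p in pairs])
                b = np.array([p[1] for p in pairs])
                expected = np.sum((a - a.mean()) * (b - b.mean())) / (
                    len(a) * a.std() * b.std())
                assert r[i] == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_argument_swap_mirrors_lags(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        _, r_xy = cross_correlation(x, y, 2.0, 5.0)
        _, r_yx = cross_correlation(y, x, 2.0, 5.0)
        np.testing.assert_allclose(r_xy, r_yx[::-1], rtol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(np.ones(50), np.arange(50.0), 2.0, 5.0)


class TestPeakTiming:
    def test_identical_tables_zero_difference(self, rng):
        data = rng.normal(size=(5, 31))
        ta, tb = _table(data, 2.0, 4.0), _table(data.copy(), 2.0, 4.0)
        np.testing.assert_array_equal(peak_time_difference(ta, tb), 0.0)

    def test_shifted_peak_detected(self):
        a = np.zeros((1, 31))
        b = np.zeros((1, 31))
        a[0, 15], b[0, 18] = 1.0, 1.0  # peaks 3 frames apart
        diff = peak_time_difference(_table(a, 2.0, 4.0), _table(b, 2.0, 4.0))
        assert diff[0] == pytest.approx(-0.6)

    def test_averaging_commutes_with_slicing(self, wildtype_recording):
        # mean of peristimulus rows equals the peristimulus slice of means
        events = [e for e in detect_events(wildtype_recording) if e.kind == "off"]
        table = extract_peristimulus(wildtype_recording, events, "F_nrV", 2.0, 2.0)
        manual = np.mean(
            [wildtype_recording.F_nrV[e.frame - 10 : e.frame + 11] for e in events],
            axis=0,
        )
        np.testing.assert_allclose(table.data.mean(axis=0), manual, rtol=1e-12)
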