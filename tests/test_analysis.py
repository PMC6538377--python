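"""Event detection, speed estimation, decoding and spectra."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import ltpie
from ltpie import EventDetectionParams, SpeedParams
from ltpie.analysis import (attach_spikes, decode_positions, detect_events,
                            event_psd, replay_speed, smooth_population_rate)

DT = 0.5


def boxcar(segments, n=4000, level=1.0):
    """Trace with supra-threshold boxcars at the given (start_ms, len_ms)."""
    x = np.zeros(n)
    for start, length in segments:
        lo, hi = int(start / DT), int((start + length) / DT)
        x[lo:hi] = level
    return x


def reference_detector(trace, params=EventDetectionParams(), dt=DT):
    """Brute-force scan-and-merge oracle for the event detector."""
    above = trace > params.rate_threshold
    runs, start = [], None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start * dt, i * dt))
            start = None
    if start is not None:
        runs.append((start * dt, len(above) * dt))
    runs = [(s, e) for s, e in runs if e - s > params.min_duration]
    merged = True
    while merged:
        merged = False
        for i in range(len(runs) - 1):
            if runs[i + 1][0] - runs[i][1] < params.merge_gap:
                runs[i:i + 2] = [(runs[i][0], runs[i + 1][1])]
                merged = True
                break
    return runs


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(smooth_population_rate(x), x, atol=1e-9)

    def test_impulse_becomes_discrete_gaussian(self):
        x = np.zeros(201)
        x[100] = 1.0
        y = smooth_population_rate(x, smooth_std=2.0, dt=DT)
        assert np.argmax(y) == 100
        # matches the analytic kernel shape
        k = np.arange(-16, 17) * DT
        expect = np.exp(-k**2 / 8.0)
        expect /= expect.sum()
        assert np.allclose(y[84:117], expect, atol=1e-12)

    def test_integral_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.random(2000)
        y = smooth_population_rate(x)
        # away from the edges, mass is conserved to rounding error
        assert abs(y[50:-50].sum() - x[50:-50].sum()) / x.sum() < 1e-3
        assert abs(y.sum() - x.sum()) / x.sum() < 1e-2


class TestDetectEvents:
    def test_silent_trace_yields_nothing(self):
        assert detect_events(np.zeros(1000)) == []

    def test_single_boxcar_single_event(self):
        events = detect_events(boxcar([(500, 100)]))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(100.0)

    def test_merge_rule_on_gap_width(self):
        near = detect_events(boxcar([(500, 40), (545, 40)]))   # 5 ms gap
        far = detect_events(boxcar([(500, 40), (555, 40)]))    # 15 ms gap
        assert len(near) == 1 and len(far) == 2

    def test_short_runs_discarded(self):
        assert detect_events(boxcar([(500, 20)])) == []

    def test_matches_brute_force_oracle_on_random_traces(self):
        """Property check: 1000 random boxcar traces against a brute-force
        scan-and-merge reference."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n_seg = rng.integers(0, 6)
            segs = [(float(rng.integers(0, 1800)),
                     float(rng.integers(5, 120))) for _ in range(n_seg)]
            trace = boxcar(segs, n=2000)
            got = [(e.t_start, e.t_end) for e in detect_events(trace)]
            assert got == reference_detector(trace)


class TestLinearPositions:
    def test_endpoints_and_midpoint(self, z_traj):
        wp = z_traj.waypoints
        pos = ltpie.linear_positions(
            np.array([wp[0], wp[-1], 0.5 * (wp[0] + wp[1])]), z_traj)
        assert pos[0] == pytest.approx(0.0, abs=1e-9)
        assert pos[1] == pytest.approx(4.0, abs=1e-9)
        seg1 = np.linalg.norm(wp[1] - wp[0])
        assert pos[2] == pytest.approx(seg1 / 2, abs=1e-9)


def synthetic_event(slope, duration=200.0, n=120, noise=0.0, seed=0):
    """Event whose spikers' positions are (noisily) linear in time."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, duration, n))
    pos = slope * t * 1e-3 + noise * rng.normal(size=n)
    ev = ltpie.ReplayEvent(t_start=0.0, t_end=duration)
    ev.spike_times = t
    ev.spike_ids = np.arange(n)
    return ev, pos


class TestReplaySpeed:
    def test_exact_recovery_and_antisymmetry(self):
        ev, pos = synthetic_event(15.0)
        assert replay_speed(ev, pos) == pytest.approx(15.0, rel=1e-6)
        # time-reverse the same spikes: each neuron keeps its position but
        # fires at 200 - t, so the fitted slope flips sign exactly
        ev_r = ltpie.ReplayEvent(t_start=0.0, t_end=200.0)
        ev_r.spike_times = (200.0 - ev.spike_times)[::-1]
        ev_r.spike_ids = ev.spike_ids[::-1]
        assert replay_speed(ev_r, pos) == pytest.approx(-15.0, rel=1e-6)

    def test_slow_slope_rejected_as_non_propagating(self):
        # regression slopes at or below 10 m/s do not reflect
        # unidirectional propagation and are excluded
        ev, pos = synthetic_event(5.0)
        assert replay_speed(ev, pos) is None

    def test_duration_acceptance_band(self):
        ev, pos = synthetic_event(15.0, duration=30.0)
        assert replay_speed(ev, pos) is None
        ev, pos = synthetic_event(15.0, duration=450.0)
        assert replay_speed(ev, pos) is None

    def test_too_few_spikes_rejected(self):
        ev = ltpie.ReplayEvent(t_start=0.0, t_end=100.0)
        ev.spike_times = np.array([50.0])
        ev.spike_ids = np.array([0])
        assert replay_speed(ev, np.array([1.0])) is None

    @pytest.mark.parametrize("slope", [12.0, 18.0, 25.0, 30.0])
    def test_noisy_recovery_within_three_se(self, slope):
        estimates = [
            replay_speed(*synthetic_event(slope, noise=0.3, seed=s))
            for s in range(8)
        ]
        estimates = np.array([e for e in estimates if e is not None])
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - slope) < 3 * max(se, 1e-3)


class TestDecoder:
    def test_below_min_spikes_no_estimate(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ids = np.arange(4)
        peaks = np.zeros((4, 2))
        assert decode_positions(t, ids, peaks, 0.0, 5.0).size == 0

    def test_median_of_spiker_peaks(self):
        t = np.linspace(0.5, 4.5, 5)
        ids = np.arange(5)
        peaks = np.column_stack([np.arange(5) * 0.1, np.zeros(5)])
        out = decode_positions(t, ids, peaks, 0.0, 5.0)
        assert out.shape == (1, 3)
        assert out[0, 1] == pytest.approx(0.2)

    def test_colocated_spikers_decode_their_location(self):
        t = np.linspace(0.5, 4.5, 5)
        ids = np.arange(5)
        peaks = np.tile([[0.3, -0.4]], (5, 1))
        out = decode_positions(t, ids, peaks, 0.0, 5.0)
        assert np.allclose(out[0, 1:], [0.3, -0.4])

    def test_decoded_replay_progresses_along_trajectory(
            self, pooled_runs, pooled_events, default_model, z_traj):
        """Decoding a real replay event gives monotone arc-length motion
        (|Spearman rho| > 0.8)."""
        for res, events in zip(pooled_runs, pooled_events):
            ev = next((e for e in events if e.speed is not None), None)
            if ev is not None:
                break
        assert ev is not None
        dec = decode_positions(ev.spike_times, ev.spike_ids,
                               default_model.peaks, ev.t_start, ev.t_end)
        assert dec.shape[0] >= 5
        arc = z_traj.arc_position(dec[:, 1:])
        rho = spearmanr(dec[:, 0], arc).statistic
        assert abs(rho) > 0.8


class TestEventPSD:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(1024) * DT * 1e-3
        x = np.sin(2 * np.pi * 40.0 * t)
        freq, power = event_psd(x, DT)
        assert freq[np.argmax(power)] == pytest.approx(
            40.0, abs=freq[1] - freq[0])

    def test_parseval_power_equals_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        freq, power = event_psd(x, DT)
        assert power.sum() == pytest.approx(np.var(x), rel=1e-6)

    def test_short_segment_skipped(self):
        assert event_psd(np.zeros(32), DT) is None


class TestBlowupClassifier:
    def test_confined_event_not_flagged(self):
        profile = np.array([2.0] * 10 + [1.0] * 10)
        ev = ltpie.ReplayEvent(0.0, 100.0)
        ev.spike_ids = np.arange(10)
        ev.spike_times = np.linspace(0, 100, 10)
        assert not ltpie.classify_blowup(ev, profile)

    def test_escaped_event_flagged(self):
        profile = np.array([2.0] * 10 + [1.0] * 10)
        ev = ltpie.ReplayEvent(0.0, 100.0)
        ev.spike_ids = np.arange(10, 20)
        ev.spike_times = np.linspace(0, 100, 10)
        assert ltpie.classify_blowup(ev, profile)


class TestFrequencySweep:
    def test_no_recurrence_no_events_and_sigma_max_trend(self, z_traj):
        """Without recurrent excitation nothing propagates; raising the
        LTP-IE ceiling never reduces spontaneous-event frequency
        (3-point trend, scaled-down trials)."""
        def make_network(name1, p1, name2, p2, seed):
            conn = ltpie.ConnectivityParams(**{name1: p1})
            return ltpie.assemble_network(conn=conn, seed=seed)

        def make_profile(sigma_max):
            def fn(model):
                return ltpie.profile_from_trajectory(
                    model.peaks, z_traj,
                    ltpie=ltpie.LTPIEParams(sigma_max=sigma_max))
            return fn

        table = ltpie.sweep_event_frequency(
            lambda n1, p1, n2, p2, s: make_network(n1, p1, n2, p2, s),
            make_profile(2.0),
            {"w_pc_pc": [0.0], "unused": [0.0]},
            n_trials=1, trial_duration=2_000.0, seed=0)
        assert table["event_frequency"].iloc[0] == 0.0

        freqs = []
        for sigma_max in (1.0, 1.5, 2.0):
            tab = ltpie.sweep_event_frequency(
                lambda n1, p1, n2, p2, s: ltpie.assemble_network(seed=s),
                make_profile(sigma_max),
                {"w_pc_pc": [2.6], "unused": [0.0]},
                n_trials=3, trial_duration=3_000.0, seed=17)
            freqs.append(tab["event_frequency"].iloc[0])
        assert freqs[1] >= freqs[0]
        assert freqs[2] >= freqs[1]
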