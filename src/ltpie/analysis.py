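"""Replay-event detection and quantification.

Pipeline: smooth the cell-averaged PC rate with a 2 ms Gaussian; mark
supra-threshold (0.5 Hz) stretches; keep stretches longer than 30 ms as
events; merge events separated by gaps under 10 ms (iterated to a fixed
point).  Events are then classified (blowup = spiking escaped the tagged
cell set), assigned a virtual replay speed (least-squares slope of linear
trajectory position vs spike time over the middle 80% of the event), an
optional decoded trajectory, and an event power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import Trajectory
from .simulator import SimResult, run_network, trigger_pulse

__all__ = [
    "EventDetectionParams",
    "SpeedParams",
    "ReplayEvent",
    "smooth_population_rate",
    "detect_events",
    "linear_positions",
    "replay_speed",
    "decode_positions",
    "event_psd",
    "classify_blowup",
    "analyze_run",
    "sweep_event_frequency",
    "sweep_replay_speed",
]


@dataclass(frozen=True)
class EventDetectionParams:
    smooth_std: float = 2.0      # ms
    rate_threshold: float = 0.5  # Hz
    min_duration: float = 30.0   # ms
    merge_gap: float = 10.0      # ms

    def __post_init__(self):
        for name in ("smooth_std", "rate_threshold", "min_duration",
                     "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SpeedParams:
    """Acceptance rules for the virtual-speed estimate.

    Events are included only when 50-400 ms long and when the fitted
    speed magnitude exceeds ``min_abs_speed`` (10 m/s): slower slopes
    come from bidirectional or stalled events, whose position-vs-time
    regression cancels toward zero and does not measure unidirectional
    propagation.
    """

    trim_fraction: float = 0.1     # trimmed from each end of the event
    min_event: float = 50.0        # ms
    max_event: float = 400.0       # ms
    min_abs_speed: float = 10.0    # m/s

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")


@dataclass
class ReplayEvent:
    """One detected replay event with optional derived metrics."""

    t_start: float
    t_end: float
    spike_times: np.ndarray | None = None
    spike_ids: np.ndarray | None = None
    speed: float | None = None
    blowup: bool = False
    psd: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_spikes(self) -> int:
        return 0 if self.spike_times is None else len(self.spike_times)


def smooth_population_rate(rate: np.ndarray, smooth_std: float = 2.0,
                           dt: float = 0.5) -> np.ndarray:
    """Gaussian smoothing, kernel truncated at +-4 std, unit-sum.

    Output length equals input length; a constant trace is unchanged and
    the trace integral is preserved (up to edge effects).
    """
    rate = np.asarray(rate, dtype=float)
    half = int(np.ceil(4.0 * smooth_std / dt))
    x = np.arange(-half, half + 1) * dt
    kernel = np.exp(-(x**2) / (2.0 * smooth_std**2))
    kernel /= kernel.sum()
    smoothed = np.convolve(rate, kernel, mode="same")
    # renormalize by the in-window kernel mass so edges are unbiased
    # (a constant trace stays exactly constant)
    coverage = np.convolve(np.ones_like(rate), kernel, mode="same")
    return smoothed / coverage


def detect_events(smoothed: np.ndarray,
                  params: EventDetectionParams = EventDetectionParams(),
                  dt: float = 0.5) -> list[ReplayEvent]:
    """Threshold/duration/merge event detector.

    Strictly supra-threshold runs lasting longer than ``min_duration``
    become events; events whose separating gap is shorter than
    ``merge_gap`` are merged, applied iteratively until stable.  Event
    boundaries sit at the threshold crossings (first/last supra-threshold
    sample, inclusive of the bin width).
    """
    above = np.asarray(smoothed) > params.rate_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    runs = [
        (s * dt, e * dt) for s, e in zip(starts, ends)
        if (e - s) * dt > params.min_duration
    ]
    # Iterated merging of near-adjacent events.
    changed = True
    while changed and len(runs) > 1:
        changed = False
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe < params.merge_gap:
                merged[-1] = (ps, e)
                changed = True
            else:
                merged.append((s, e))
        runs = merged
    return [ReplayEvent(t_start=s, t_end=e) for s, e in runs]


def linear_positions(peaks: np.ndarray, trajectory: Trajectory) -> np.ndarray:
    """Arc-length position (m) along the trajectory of the point nearest
    each place-field peak."""
    return trajectory.arc_position(peaks)


def attach_spikes(event: ReplayEvent, result: SimResult) -> ReplayEvent:
    """Fill the event with the PC spikes falling in its window."""
    t = result.pc_spike_times()
    sel = (t >= event.t_start) & (t <= event.t_end)
    event.spike_times = t[sel]
    event.spike_ids = result.pc_spike_ids()[sel]
    return event


def replay_speed(event: ReplayEvent, positions: np.ndarray,
                 params: SpeedParams = SpeedParams()) -> float | None:
    """Signed virtual replay speed (m/s), or None if the event is rejected.

    Accepts only events with duration in [min_event, max_event]; trims the
    first and last ``trim_fraction`` of the window; fits ordinary least
    squares of spikers' linear positions vs spike time; rejects slope
    magnitudes at or below ``min_abs_speed`` (non-propagating events).
    The sign encodes direction.
    """
    if event.spike_times is None:
        raise ValueError("event has no attached spikes")
    if not (params.min_event <= event.duration <= params.max_event):
        return None
    lo = event.t_start + params.trim_fraction * event.duration
    hi = event.t_end - params.trim_fraction * event.duration
    sel = (event.spike_times >= lo) & (event.spike_times <= hi)
    t = event.spike_times[sel]
    if t.size < 2 or np.ptp(t) == 0:
        return None
    x = positions[event.spike_ids[sel]]
    slope = np.polyfit(t * 1e-3, x, 1)[0]  # m/s
    if abs(slope) <= params.min_abs_speed:
        return None
    return float(slope)


def decode_positions(
    spike_times: np.ndarray,
    spike_ids: np.ndarray,
    peaks: np.ndarray,
    t_start: float,
    t_end: float,
    window: float = 5.0,
    min_spikes: int = 5,
) -> np.ndarray:
    """Median-of-spikers position decoder.

    Tiles [t_start, t_end] with ``window``-ms bins; every bin containing at
    least ``min_spikes`` PC spikes yields the coordinate-wise median of the
    spiking cells' place-field peaks (each spike counted).  Returns an
    ``(n, 3)`` array of (t_center_ms, x, y).
    """
    out = []
    edges = np.arange(t_start, t_end + 1e-9, window)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (spike_times >= lo) & (spike_times < hi)
        if np.count_nonzero(sel) < min_spikes:
            continue
        pts = peaks[spike_ids[sel]]
        out.append([(lo + hi) / 2.0, np.median(pts[:, 0]),
                    np.median(pts[:, 1])])
    return np.asarray(out).reshape(-1, 3)


def event_psd(rate_segment: np.ndarray, dt: float = 0.5):
    """Mean-subtracted periodogram of a rate segment.

    Normalised so that the power sums to the segment variance (Parseval).
    Returns ``(freq_hz, power)`` or None for segments under 64 samples.
    """
    x = np.asarray(rate_segment, dtype=float)
    n = x.size
    if n < 64:
        return None
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # fold the negative frequencies into the one-sided spectrum
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freq = np.fft.rfftfreq(n, d=dt * 1e-3)
    return freq, power


def classify_blowup(event: ReplayEvent, profile: np.ndarray,
                    sigma_max: float = 2.0, f_out: float = 0.25) -> bool:
    """Flag events whose spiking escaped the LTP-IE-tagged cell set.

    A cell counts as tagged when sigma >= the midpoint
    1 + (sigma_max - 1)/2; the event is a blowup when more than ``f_out``
    of its spikes come from untagged cells.  Both knobs are conventions
    (exposed in config) — the qualitative criterion is that confined
    events draw nearly all spikes from tagged cells.
    """
    if event.spike_ids is None or event.spike_ids.size == 0:
        return False
    sigma_tag = 1.0 + (sigma_max - 1.0) / 2.0
    frac_out = np.mean(profile[event.spike_ids] < sigma_tag)
    return bool(frac_out > f_out)


def analyze_run(
    result: SimResult,
    profile: np.ndarray,
    trajectory: Trajectory | None = None,
    detection: EventDetectionParams = EventDetectionParams(),
    speed_params: SpeedParams = SpeedParams(),
    sigma_max: float = 2.0,
    f_out: float = 0.25,
    peaks: np.ndarray | None = None,
    with_psd: bool = False,
) -> list[ReplayEvent]:
    """Full per-run analysis: detect, attach spikes, classify, measure."""
    smoothed = smooth_population_rate(
        result.pc_rate, detection.smooth_std, result.dt)
    events = detect_events(smoothed, detection, result.dt)
    positions = None
    if trajectory is not None and peaks is not None:
        positions = linear_positions(peaks, trajectory)
    for ev in events:
        attach_spikes(ev, result)
        ev.blowup = classify_blowup(ev, profile, sigma_max, f_out)
        if positions is not None and not ev.blowup:
            ev.speed = replay_speed(ev, positions, speed_params)
        if with_psd:
            lo = int(round(ev.t_start / result.dt))
            hi = int(round(ev.t_end / result.dt))
            ev.psd = event_psd(result.pc_rate[lo:hi], result.dt)
    return events


def mean_event_psd(events: list[ReplayEvent]):
    """Average per-event power spectra onto a common frequency grid.

    Events have different lengths (hence different native frequency
    resolutions), so each spectrum is interpolated onto the grid of the
    longest event before averaging.
    """
    specs = [ev.psd for ev in events if ev.psd is not None]
    if not specs:
        return None
    ref = max(specs, key=lambda fp: fp[0].size)
    freq = ref[0]
    acc = np.zeros_like(freq)
    for f, p in specs:
        acc += np.interp(freq, f, p)
    return freq, acc / len(specs)


def sweep_event_frequency(
    make_network,
    profile_fn,
    param_grid: dict[str, list],
    n_trials: int = 10,
    trial_duration: float = 10_000.0,
    seed: int = 0,
    detection: EventDetectionParams = EventDetectionParams(),
    f_out: float = 0.25,
    blowup_majority: float = 0.5,
) -> pd.DataFrame:
    """Spontaneous-event frequency over a 2-D parameter grid.

    ``make_network(p1_name, p1, p2_name, p2, seed)`` must return a
    NetworkModel for one grid cell; ``profile_fn(model)`` the sigma
    profile.  Frequency is the mean over trials of accepted (non-blowup)
    events per second; a cell is flagged blowup when more than
    ``blowup_majority`` of its detected events blew up.
    """
    (name1, grid1), (name2, grid2) = param_grid.items()
    ss = np.random.SeedSequence(seed)
    rows = []
    for p1 in grid1:
        for p2 in grid2:
            model = make_network(name1, p1, name2, p2,
                                 ss.spawn(1)[0].generate_state(1)[0])
            profile = profile_fn(model)
            sigma_max = float(profile.max())
            n_ok = n_blow = 0
            for _ in range(n_trials):
                run_seed = ss.spawn(1)[0].generate_state(1)[0]
                res = run_network(model, profile, trial_duration,
                                  seed=run_seed)
                events = analyze_run(res, profile, detection=detection,
                                     sigma_max=sigma_max, f_out=f_out)
                n_blow += sum(ev.blowup for ev in events)
                n_ok += sum(not ev.blowup for ev in events)
            total = n_ok + n_blow
            rows.append({
                name1: p1, name2: p2,
                "event_frequency": n_ok / (n_trials * trial_duration * 1e-3),
                "n_events": total,
                "blowup_fraction": (n_blow / total) if total else 0.0,
                "blowup": bool(total and n_blow / total > blowup_majority),
            })
    return pd.DataFrame(rows)


def sweep_replay_speed(
    make_network,
    profile_fn,
    trajectory: Trajectory,
    param_grid: dict[str, list],
    max_trials: int = 20,
    max_successes: int = 10,
    min_successes: int = 5,
    trial_duration: float = 600.0,
    trigger_radius: float = 0.15,
    trigger_onset: float = 20.0,
    trigger_window: float = 100.0,
    seed: int = 0,
    detection: EventDetectionParams = EventDetectionParams(),
    speed_params: SpeedParams = SpeedParams(),
) -> pd.DataFrame:
    """Triggered replay speed over a 2-D parameter grid.

    Per cell: trigger at the trajectory start, run up to ``max_trials``
    short trials or until ``max_successes`` successfully triggered events
    (the first non-blowup event starting within ``trigger_window`` ms of
    the trigger, with a measurable speed); report the mean speed magnitude
    only for cells with at least ``min_successes`` successes.  Spontaneous
    events later in a trial are not counted — the measurement concerns the
    triggered sequence.
    """
    (name1, grid1), (name2, grid2) = param_grid.items()
    start = trajectory.waypoints[0]
    ss = np.random.SeedSequence(seed)
    rows = []
    for p1 in grid1:
        for p2 in grid2:
            model = make_network(name1, p1, name2, p2,
                                 ss.spawn(1)[0].generate_state(1)[0])
            profile = profile_fn(model)
            sigma_max = float(profile.max())
            positions = linear_positions(model.peaks, trajectory)
            near = np.linalg.norm(model.peaks - start, axis=1)
            targets = np.flatnonzero(near <= trigger_radius)
            trig = trigger_pulse(targets, onset=trigger_onset)
            speeds = []
            for _ in range(max_trials):
                if len(speeds) >= max_successes:
                    break
                run_seed = ss.spawn(1)[0].generate_state(1)[0]
                res = run_network(model, profile, trial_duration,
                                  triggers=[trig], seed=run_seed)
                events = analyze_run(res, profile, detection=detection,
                                     sigma_max=sigma_max)
                for ev in events:
                    # only the event elicited by the trigger counts
                    if ev.t_start > trigger_onset + trigger_window:
                        break
                    if ev.t_end < trigger_onset or ev.blowup:
                        continue
                    s = replay_speed(ev, positions, speed_params)
                    if s is not None:
                        speeds.append(s)
                    break
            if len(speeds) >= min_successes:
                rows.append({
                    name1: p1, name2: p2,
                    "mean_speed": float(np.mean(np.abs(speeds))),
                    "sem_speed": float(
                        np.std(np.abs(speeds), ddof=1) / np.sqrt(len(speeds))
                    ),
                    "n_events": len(speeds),
                })
    return pd.DataFrame(rows)
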