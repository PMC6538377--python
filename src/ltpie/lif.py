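"""Conductance-based leaky integrate-and-fire dynamics.

Membrane equation (voltages in mV, times in ms, conductances dimensionless
relative to leak):

    tau_m dV/dt = -(V - E_leak) - g_E (V - E_E) - g_I (V - E_I) + I_ext

integrated by forward Euler at dt = 0.5 ms.  Synaptic conductances are
exponentially filtered trains of weighted presynaptic spikes: each step the
conductance decays by exp(-dt/tau) and jumps by the summed weights of
spikes delivered that step.  I_ext is expressed directly in mV of expected
membrane deflection (it sits inside the bracket with the leak term).

Spike semantics: the threshold test follows the voltage update; on a spike
the voltage is reset to E_leak and held there for the refractory period
tau_r, during which conductances keep integrating (incoming spikes are not
lost).  Presynaptic spikes reach postsynaptic conductances on the next
step (one-step delay).

Note these are discrete-time dynamics: results depend (weakly) on dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "StimulusProtocol",
    "PC_PARAMS",
    "INH_PARAMS",
    "DT",
    "step_membrane",
    "generate_poisson_train",
    "simulate_single_cell",
    "voltage_and_rate_statistics",
    "evoked_spike_contrast",
    "epsp_peak",
]

#: Default integration step, ms.
DT = 0.5


@dataclass(frozen=True)
class CellParams:
    """Single-cell membrane and synapse constants (ms / mV)."""

    tau_m: float
    e_leak: float
    v_th: float
    tau_r: float
    e_e: float = 0.0
    e_i: float = -80.0
    tau_e: float = 2.0
    tau_i: float = 2.0

    def __post_init__(self):
        if self.tau_m <= 0 or self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_r < 0:
            raise ValueError("tau_r must be >= 0")
        if not (self.e_i <= self.e_leak < self.v_th < self.e_e):
            raise ValueError("require E_I <= E_leak < v_th < E_E")


#: Pyramidal-cell defaults.
PC_PARAMS = CellParams(tau_m=50.0, e_leak=-68.0, v_th=-36.0, tau_r=8.0)
#: Inhibitory-cell defaults.
INH_PARAMS = CellParams(tau_m=5.0, e_leak=-60.0, v_th=-50.0, tau_r=2.0)


@dataclass
class CellState:
    """Dynamic state of one cell or a vector of cells."""

    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_remaining: np.ndarray

    @classmethod
    def resting(cls, params: CellParams, n: int = 1) -> "CellState":
        return cls(
            v=np.full(n, params.e_leak),
            g_e=np.zeros(n),
            g_i=np.zeros(n),
            refractory_remaining=np.zeros(n),
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Square current pulses into a target set of cells.

    ``pulse_amplitude`` is in units of expected membrane-voltage deflection
    (mV), as I_ext enters the membrane equation directly.
    """

    pulse_onsets: np.ndarray
    pulse_duration: float = 10.0
    pulse_amplitude: float = 65.0
    targets: np.ndarray | None = None  # None = all cells

    def __post_init__(self):
        onsets = np.asarray(self.pulse_onsets, dtype=float)
        if np.any(np.diff(onsets) < 0):
            raise ValueError("pulse onsets must be sorted")
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be > 0")
        object.__setattr__(self, "pulse_onsets", onsets)

    def active(self, t: float) -> bool:
        """Whether any pulse covers time ``t`` (ms)."""
        i = np.searchsorted(self.pulse_onsets, t, side="right") - 1
        return i >= 0 and t < self.pulse_onsets[i] + self.pulse_duration


def step_membrane(
    state: CellState,
    params: CellParams,
    incoming_e=0.0,
    incoming_i=0.0,
    i_ext=0.0,
    dt: float = DT,
):
    """Advance one Euler step; returns ``(new_state, spiked)``.

    ``incoming_e``/``incoming_i`` are the summed synaptic weights of
    presynaptic spikes delivered this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, x in (("state", state.v), ("incoming_e", incoming_e),
                    ("incoming_i", incoming_i), ("i_ext", i_ext)):
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite {name} in membrane step")

    g_e = state.g_e * np.exp(-dt / params.tau_e) + incoming_e
    g_i = state.g_i * np.exp(-dt / params.tau_i) + incoming_i

    refractory = state.refractory_remaining > 0
    dv = (dt / params.tau_m) * (
        -(state.v - params.e_leak)
        - g_e * (state.v - params.e_e)
        - g_i * (state.v - params.e_i)
        + i_ext
    )
    v = np.where(refractory, params.e_leak, state.v + dv)
    refractory_remaining = np.maximum(state.refractory_remaining - dt, 0.0)

    spiked = (~refractory) & (v >= params.v_th)
    v = np.where(spiked, params.e_leak, v)
    refractory_remaining = np.where(spiked, params.tau_r, refractory_remaining)

    return CellState(v, g_e, g_i, refractory_remaining), spiked


def generate_poisson_train(
    rate: float, duration: float, dt: float = DT, seed=None
) -> np.ndarray:
    """Homogeneous Poisson spike times via per-bin Bernoulli draws.

    Consistent with the discrete-time engine: each dt bin spikes
    independently with p = rate * dt.  Spike times are bin-start times (ms).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = rate * dt * 1e-3  # rate in Hz, dt in ms
    if p > 1:
        raise ValueError(f"rate*dt = {p} exceeds 1; decrease dt")
    n = int(round(duration / dt))
    if rate == 0 or n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    hits = rng.random(n) < p
    return np.flatnonzero(hits) * dt


def simulate_single_cell(
    params: CellParams = PC_PARAMS,
    sigma: float = 1.0,
    w_gate: float = 0.8216,
    r_g: float = 125.0,
    protocol: StimulusProtocol | None = None,
    duration: float = 15_000.0,
    dt: float = DT,
    seed=None,
):
    """One cell driven by an independent Poisson gate train.

    The effective gate weight is ``sigma * w_gate`` — the LTP-IE scaling
    acts only on the gating pathway.  Returns ``(t, v, spike_times)``.
    """
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    n = int(round(duration / dt))
    p = r_g * dt * 1e-3
    if p > 1:
        raise ValueError("r_g*dt exceeds 1")
    rng = np.random.default_rng(seed)
    gate = rng.random(n) < p

    # Precompute pulse mask.
    i_ext = np.zeros(n)
    if protocol is not None:
        t_bins = np.arange(n) * dt
        for onset in protocol.pulse_onsets:
            lo = int(np.ceil(onset / dt))
            hi = int(np.ceil((onset + protocol.pulse_duration) / dt))
            i_ext[lo:hi] = protocol.pulse_amplitude

    w_eff = sigma * w_gate
    decay_e = np.exp(-dt / params.tau_e)
    inv_tau = dt / params.tau_m
    e_leak, v_th, tau_r, e_e = params.e_leak, params.v_th, params.tau_r, params.e_e

    v_trace = np.empty(n)
    spikes = []
    v = e_leak
    g_e = 0.0
    refr = 0.0
    for k in range(n):
        g_e = g_e * decay_e + (w_eff if gate[k] else 0.0)
        if refr > 0:
            v = e_leak
            refr -= dt
        else:
            v = v + inv_tau * (-(v - e_leak) - g_e * (v - e_e) + i_ext[k])
            if v >= v_th:
                spikes.append(k * dt)
                v = e_leak
                refr = tau_r
        v_trace[k] = v
    t = np.arange(n) * dt
    return t, v_trace, np.asarray(spikes)


def voltage_and_rate_statistics(trace: np.ndarray, spikes: np.ndarray,
                                duration: float | None = None,
                                dt: float = DT):
    """Mean/std of the voltage trace and the spontaneous spike rate (Hz).

    Refractory-clamped samples are part of the trace (at E_leak) and are
    included in the moments.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty voltage trace")
    if duration is None:
        duration = trace.size * dt
    return {
        "mean_v": float(np.mean(trace)),
        "std_v": float(np.std(trace)),
        "rate": float(len(spikes) / (duration * 1e-3)),
    }


def epsp_peak(params: CellParams = PC_PARAMS, weight: float = 0.8216,
              dt: float = DT, horizon: float = 60.0) -> float:
    """Peak depolarization (mV) after a single gate spike onto a resting cell.

    Deterministic: one excitatory spike of the given weight at t=0, no
    other input; spiking disabled is unnecessary because a single gate
    spike never reaches threshold at physiological weights.
    """
    state = CellState.resting(params)
    peak = 0.0
    n = int(round(horizon / dt))
    for k in range(n):
        state, _ = step_membrane(
            state, params, incoming_e=(weight if k == 0 else 0.0), dt=dt
        )
        peak = max(peak, float(state.v[0]) - params.e_leak)
    return peak


def evoked_spike_contrast(
    sigma: float,
    w_gate: float = 0.8216,
    r_g: float = 125.0,
    pulse_amplitude: float = 65.0,
    pulse_duration: float = 10.0,
    pulse_period: float = 250.0,
    duration: float = 125_000.0,
    params: CellParams = PC_PARAMS,
    dt: float = DT,
    seed=None,
):
    """Pulse-evoked minus spontaneous spike probability.

    Pulses of ``pulse_duration`` ms are presented every ``pulse_period`` ms;
    the evoked probability is the fraction of pulse windows containing at
    least one spike, the spontaneous probability is the same statistic over
    matched no-pulse windows offset half a period from each pulse.

    Returns ``(contrast, p_evoked, p_spontaneous)``.
    """
    onsets = np.arange(0.0, duration - pulse_period, pulse_period) + 50.0
    protocol = StimulusProtocol(onsets, pulse_duration, pulse_amplitude)
    _, _, spikes = simulate_single_cell(
        params, sigma, w_gate, r_g, protocol, duration, dt, seed
    )

    def window_hit_fraction(starts):
        if len(spikes) == 0:
            return 0.0
        idx_lo = np.searchsorted(spikes, starts)
        idx_hi = np.searchsorted(spikes, starts + pulse_duration)
        return float(np.mean(idx_hi > idx_lo))

    p_evoked = window_hit_fraction(onsets)
    p_spont = window_hit_fraction(onsets + pulse_period / 2.0)
    return p_evoked - p_spont, p_evoked, p_spont
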