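"""Replay-epoch simulation of the full spiking network.

Each 0.5 ms step: (1) spikes from the previous step are delivered to
postsynaptic conductances (one-step synaptic delay) together with fresh
per-PC Poisson gate spikes, whose weights are the LTP-IE-scaled gate
weights sigma_i * w_PC_G; (2) all membranes take one Euler step; (3)
threshold, reset and refractory bookkeeping.  Only PCs receive gating
input and trigger current; INH cells are driven purely by PC spikes.

Spike propagation uses a column gather through CSC weight structures when
few cells spiked (the common case) and falls back to a sparse mat-vec
when many did (blowup regimes), so both regimes stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .lif import DT, StimulusProtocol
from .network import NetworkModel

__all__ = ["SimResult", "RegionMask", "run_network", "trigger_pulse",
           "readout_timeseries", "region_mask"]

# Above this many presynaptic spikes per step, use a mat-vec instead of a
# per-column gather.
_GATHER_LIMIT = 48


@dataclass
class SimResult:
    """Raster and rate output of one network run.

    ``pc_spikes``/``inh_spikes`` are ``(neuron_id, t_ms)`` arrays sorted by
    time; ``pc_rate`` is the cell-averaged PC firing rate (Hz) per dt bin.
    """

    pc_spikes: np.ndarray      # (n, 2): neuron_id, t_ms
    inh_spikes: np.ndarray
    pc_rate: np.ndarray        # Hz per bin
    dt: float
    duration: float
    seed: object = None

    @property
    def n_steps(self) -> int:
        return self.pc_rate.size

    def pc_spike_times(self) -> np.ndarray:
        return self.pc_spikes[:, 1]

    def pc_spike_ids(self) -> np.ndarray:
        return self.pc_spikes[:, 0].astype(int)


@dataclass(frozen=True)
class RegionMask:
    """Named circular region of the environment and its member PCs."""

    name: str
    center: tuple[float, float]
    radius: float
    members: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "members", np.asarray(self.members, dtype=int)
        )


def region_mask(name: str, center, radius: float,
                peaks: np.ndarray) -> RegionMask:
    """All PCs whose place-field peak lies within ``radius`` of ``center``."""
    d = np.linalg.norm(peaks - np.asarray(center, dtype=float), axis=1)
    return RegionMask(name, tuple(center), radius, np.flatnonzero(d <= radius))


def trigger_pulse(targets, onset: float, duration: float = 10.0,
                  amplitude: float = 65.0) -> StimulusProtocol:
    """Current pulse into a region or explicit index set.

    Exact trigger parameters are unimportant for sequence propagation as
    long as the pulse elicits spikes at the start of the tagged path;
    defaults are 10 ms and 65 mV (the calibrated moderate drive).
    """
    idx = targets.members if isinstance(targets, RegionMask) else np.asarray(
        targets, dtype=int)
    if idx.size == 0:
        raise ValueError("empty trigger target set")
    return StimulusProtocol(np.array([onset]), duration, amplitude, idx)


class _Propagator:
    """Delivers spikes through a fixed weight matrix, fast in both sparse-
    and dense-spiking regimes."""

    def __init__(self, w: sparse.spmatrix):
        self.csr = w.tocsr()
        csc = w.tocsc()
        self.indptr = csc.indptr
        self.indices = csc.indices
        self.data = csc.data
        self.n_out = w.shape[0]

    def __call__(self, spike_idx: np.ndarray, out: np.ndarray) -> None:
        """Add the weighted contribution of presynaptic ``spike_idx`` to
        ``out`` (length n_out)."""
        k = spike_idx.size
        if k == 0:
            return
        if k <= _GATHER_LIMIT:
            indptr, indices, data = self.indptr, self.indices, self.data
            for j in spike_idx:
                lo, hi = indptr[j], indptr[j + 1]
                # indices within one CSC column are unique, so fancy
                # in-place addition is exact here
                out[indices[lo:hi]] += data[lo:hi]
        else:
            vec = np.zeros(self.csr.shape[1])
            vec[spike_idx] = 1.0
            out += self.csr @ vec


def run_network(
    model: NetworkModel,
    profile: np.ndarray,
    duration: float = 10_000.0,
    triggers: list[StimulusProtocol] | None = None,
    seed=None,
    dt: float = DT,
    record_voltage: bool = False,
) -> SimResult:
    """Simulate the replay epoch.

    Parameters
    ----------
    profile
        Per-PC LTP-IE scaling sigma (length N_PC); effective gate weight
        of PC i is ``profile[i] * w_PC_G``.
    triggers
        Optional list of current-pulse protocols (applied to PCs only).
    seed
        Master seed for the gate-noise stream.

    Raises
    ------
    FloatingPointError
        If the dynamics produce non-finite state.
    """
    profile = np.asarray(profile, dtype=float)
    n_pc, n_inh = model.n_pc, model.n_inh
    if profile.shape != (n_pc,):
        raise ValueError("profile length must equal N_PC")
    pc, inh = model.pc_params, model.inh_params
    conn = model.conn
    n_steps = int(round(duration / dt))
    p_gate = conn.r_g * dt * 1e-3
    if p_gate > 1:
        raise ValueError("r_g * dt exceeds 1")
    rng = np.random.default_rng(seed)

    w_gate_eff = profile * model.gate_weight
    prop_rec = _Propagator(model.w_rec)
    prop_pc_to_inh = _Propagator(model.w_inh_from_pc)
    prop_inh_to_pc = _Propagator(model.w_pc_from_inh)

    # Per-population state.
    v_pc = np.full(n_pc, pc.e_leak)
    g_e_pc = np.zeros(n_pc)
    g_i_pc = np.zeros(n_pc)
    refr_pc = np.zeros(n_pc)
    v_in = np.full(n_inh, inh.e_leak)
    g_e_in = np.zeros(n_inh)
    refr_in = np.zeros(n_inh)

    decay_e_pc = np.exp(-dt / pc.tau_e)
    decay_i_pc = np.exp(-dt / pc.tau_i)
    decay_e_in = np.exp(-dt / inh.tau_e)
    a_pc = dt / pc.tau_m
    a_in = dt / inh.tau_m

    # Precompile triggers into (step range, target idx, amplitude).
    compiled_triggers = []
    for tr in triggers or []:
        idx = np.arange(n_pc) if tr.targets is None else np.asarray(
            tr.targets, dtype=int)
        for onset in tr.pulse_onsets:
            lo = int(np.ceil(onset / dt))
            hi = int(np.ceil((onset + tr.pulse_duration) / dt))
            compiled_triggers.append((lo, hi, idx, tr.pulse_amplitude))

    pc_spike_steps, pc_spike_ids = [], []
    inh_spike_steps, inh_spike_ids = [], []
    rate = np.zeros(n_steps)
    prev_pc = np.empty(0, dtype=int)
    prev_inh = np.empty(0, dtype=int)
    v_rec = np.empty((n_steps, n_pc)) if record_voltage else None

    i_ext = np.zeros(n_pc)
    for k in range(n_steps):
        # (1) synaptic delivery: previous-step spikes + fresh gate spikes
        g_e_pc *= decay_e_pc
        g_i_pc *= decay_i_pc
        g_e_in *= decay_e_in
        gate_hits = rng.random(n_pc) < p_gate
        g_e_pc += w_gate_eff * gate_hits
        prop_rec(prev_pc, g_e_pc)
        prop_pc_to_inh(prev_pc, g_e_in)
        prop_inh_to_pc(prev_inh, g_i_pc)

        # external current
        any_ext = False
        for lo, hi, idx, amp in compiled_triggers:
            if lo <= k < hi:
                if not any_ext:
                    i_ext[:] = 0.0
                    any_ext = True
                i_ext[idx] += amp

        # (2) membrane update, (3) threshold/reset — PCs
        refractory = refr_pc > 0
        dv = a_pc * (
            -(v_pc - pc.e_leak)
            - g_e_pc * (v_pc - pc.e_e)
            - g_i_pc * (v_pc - pc.e_i)
            + (i_ext if any_ext else 0.0)
        )
        v_pc = np.where(refractory, pc.e_leak, v_pc + dv)
        refr_pc = np.maximum(refr_pc - dt, 0.0)
        spiked = (~refractory) & (v_pc >= pc.v_th)
        prev_pc = np.flatnonzero(spiked)
        if prev_pc.size:
            v_pc[prev_pc] = pc.e_leak
            refr_pc[prev_pc] = pc.tau_r
            pc_spike_steps.append(np.full(prev_pc.size, k))
            pc_spike_ids.append(prev_pc)
            rate[k] = prev_pc.size

        # INH population (no gate, no external current)
        refractory_in = refr_in > 0
        dv_in = a_in * (
            -(v_in - inh.e_leak) - g_e_in * (v_in - inh.e_e)
        )
        v_in = np.where(refractory_in, inh.e_leak, v_in + dv_in)
        refr_in = np.maximum(refr_in - dt, 0.0)
        spiked_in = (~refractory_in) & (v_in >= inh.v_th)
        prev_inh = np.flatnonzero(spiked_in)
        if prev_inh.size:
            v_in[prev_inh] = inh.e_leak
            refr_in[prev_inh] = inh.tau_r
            inh_spike_steps.append(np.full(prev_inh.size, k))
            inh_spike_ids.append(prev_inh)

        if record_voltage:
            v_rec[k] = v_pc
        if not np.isfinite(v_pc).all():
            raise FloatingPointError(
                f"non-finite membrane voltage at t = {k * dt} ms"
            )

    def _stack(steps, ids):
        if not steps:
            return np.empty((0, 2))
        return np.column_stack(
            [np.concatenate(ids), np.concatenate(steps) * dt]
        )

    rate *= 1e3 / (n_pc * dt)  # spikes/bin -> Hz per cell
    result = SimResult(
        pc_spikes=_stack(pc_spike_steps, pc_spike_ids),
        inh_spikes=_stack(inh_spike_steps, inh_spike_ids),
        pc_rate=rate,
        dt=dt,
        duration=duration,
        seed=seed,
    )
    if record_voltage:
        result.v_pc = v_rec  # type: ignore[attr-defined]
    return result


def readout_timeseries(
    result: SimResult,
    regions: list[RegionMask],
    normalize: bool = False,
) -> dict[str, np.ndarray]:
    """Per-region spike-count traces (one bin per dt step).

    Each readout unit sums the spikes of its member PCs in every bin;
    with ``normalize=True`` each trace is scaled to its own maximum
    (traces that never fire stay zero).
    """
    n = result.n_steps
    ids = result.pc_spike_ids()
    steps = np.round(result.pc_spike_times() / result.dt).astype(int)
    out = {}
    for region in regions:
        member = np.zeros(
            int(ids.max()) + 1 if ids.size else 1, dtype=bool)
        member[region.members[region.members < member.size]] = True
        sel = member[ids] if ids.size else np.empty(0, dtype=bool)
        trace = np.bincount(steps[sel], minlength=n).astype(float)[:n]
        if normalize and trace.max() > 0:
            trace = trace / trace.max()
        out[region.name] = trace
    return out
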