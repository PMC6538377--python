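"""Run configuration: every simulation symbol as a named key.

Defaults reproduce the published parameter tables; the stimulus-response
mapping regime differs only in the documented overrides (larger network and
environment, higher gate rate, weaker gate weight, smaller sigma_max and
w_PC_INH).  Unknown keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path

import yaml

from .analysis import EventDetectionParams, SpeedParams
from .lif import CellParams
from .network import ConnectivityParams
from .profile import LTPIEParams, TuningParams

__all__ = ["RunConfig", "load_config", "fig4_overrides"]

EXPERIMENTS = (
    "fig1", "replay", "sweep_frequency", "sweep_speed", "mapping",
    "reduced_gamma", "reduced_switchboard",
)


@dataclass(frozen=True)
class RunConfig:
    # cell membranes
    tau_m_pc: float = 50.0
    e_leak_pc: float = -68.0
    v_th_pc: float = -36.0
    tau_r_pc: float = 8.0
    tau_m_inh: float = 5.0
    e_leak_inh: float = -60.0
    v_th_inh: float = -50.0
    tau_r_inh: float = 2.0
    e_e: float = 0.0
    e_i: float = -80.0
    tau_e: float = 2.0
    tau_i: float = 2.0
    # tuning and LTP-IE
    r_max: float = 20.0
    lambda_pl: float = 0.15
    sigma_max: float = 2.0
    r_sigma: float = 10.0
    beta_sigma: float = 1.0
    # network
    n_pc: int = 3000
    bounds: float = 1.0
    w_pc_g: float = 0.8216
    w_pc_pc: float = 2.6
    w_min_pc_pc: float = 0.1
    lambda_pc_pc: float = 0.053
    w_pc_inh: float = 0.02
    w_inh_pc: float = 0.03
    p_pc_inh: float = 0.5
    p_inh_pc: float = 0.5
    r_g: float = 125.0
    # integration
    dt: float = 0.5
    duration: float = 10_000.0
    # stimulation
    pulse_amplitude: float = 65.0
    pulse_duration: float = 10.0
    # event detection / speed
    smooth_std: float = 2.0
    rate_threshold: float = 0.5
    min_event_duration: float = 30.0
    merge_gap: float = 10.0
    trim_fraction: float = 0.1
    min_speed_event: float = 50.0
    max_speed_event: float = 400.0
    min_abs_speed: float = 10.0
    f_out: float = 0.25
    # run metadata
    seed: int = 0
    experiment: str = "replay"
    out_dir: str = "out"

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose one of {EXPERIMENTS}"
            )
        if self.n_pc % 10:
            raise ValueError("n_pc must be a multiple of 10")

    # --- views onto the per-module parameter objects -------------------
    @property
    def pc_params(self) -> CellParams:
        return CellParams(self.tau_m_pc, self.e_leak_pc, self.v_th_pc,
                          self.tau_r_pc, self.e_e, self.e_i,
                          self.tau_e, self.tau_i)

    @property
    def inh_params(self) -> CellParams:
        return CellParams(self.tau_m_inh, self.e_leak_inh, self.v_th_inh,
                          self.tau_r_inh, self.e_e, self.e_i,
                          self.tau_e, self.tau_i)

    @property
    def conn_params(self) -> ConnectivityParams:
        return ConnectivityParams(
            w_pc_pc=self.w_pc_pc, lambda_pc_pc=self.lambda_pc_pc,
            w_min_pc_pc=self.w_min_pc_pc, w_pc_inh=self.w_pc_inh,
            w_inh_pc=self.w_inh_pc, p_pc_inh=self.p_pc_inh,
            p_inh_pc=self.p_inh_pc, w_pc_g=self.w_pc_g, r_g=self.r_g,
        )

    @property
    def tuning_params(self) -> TuningParams:
        return TuningParams(self.r_max, self.lambda_pl)

    @property
    def ltpie_params(self) -> LTPIEParams:
        return LTPIEParams(self.sigma_max, self.r_sigma, self.beta_sigma)

    @property
    def detection_params(self) -> EventDetectionParams:
        return EventDetectionParams(self.smooth_std, self.rate_threshold,
                                    self.min_event_duration, self.merge_gap)

    @property
    def speed_params(self) -> SpeedParams:
        return SpeedParams(self.trim_fraction, self.min_speed_event,
                           self.max_speed_event, self.min_abs_speed)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def fig4_overrides() -> dict:
    """The stimulus-response mapping regime's documented overrides."""
    return dict(n_pc=12_000, bounds=2.0, r_g=200.0, w_pc_g=0.5,
                sigma_max=1.84, w_pc_inh=0.002, experiment="mapping")


def load_config(path) -> RunConfig:
    """Parse a YAML config; missing keys default, unknown keys fail.

    An empty file yields the full default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
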