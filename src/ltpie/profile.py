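"""Trajectory-evoked firing rates and the resulting LTP-IE scaling profile.

The encoding run is never simulated.  A place cell's expected peak firing
rate during a trajectory depends only on the distance from its place-field
centre to the nearest point of the trajectory (Gaussian tuning), and the
excitability scaling sigma follows from that rate through a shifted
logistic.  Both steps are evaluated analytically, with the point-to-polyline
distance computed exactly per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import Trajectory

__all__ = [
    "LTPIEParams",
    "TuningParams",
    "tuning_rate",
    "sigma_from_rate",
    "max_rate_over_trajectory",
    "profile_from_trajectory",
]


@dataclass(frozen=True)
class LTPIEParams:
    """Shifted-logistic map from firing rate to gate-weight scaling.

    sigma(r) = 1 + (sigma_max - 1) / (1 + exp(-beta_sigma * (r - r_sigma)))

    Attributes
    ----------
    sigma_max
        Saturating scaling factor (2 for the replay network, 1.84 for the
        stimulus-response mapping network).
    r_sigma
        Half-activation firing rate, Hz (10).
    beta_sigma
        Steepness, 1/Hz (1).
    """

    sigma_max: float = 2.0
    r_sigma: float = 10.0
    beta_sigma: float = 1.0

    def __post_init__(self):
        if self.sigma_max < 1:
            raise ValueError("sigma_max must be >= 1")
        if self.r_sigma <= 0 or self.beta_sigma <= 0:
            raise ValueError("r_sigma and beta_sigma must be > 0")


@dataclass(frozen=True)
class TuningParams:
    """Gaussian place-field tuning: peak rate and length scale."""

    r_max: float = 20.0     # Hz
    lambda_pl: float = 0.15  # m

    def __post_init__(self):
        if self.r_max <= 0 or self.lambda_pl <= 0:
            raise ValueError("r_max and lambda_pl must be > 0")


def tuning_rate(distance, tuning: TuningParams = TuningParams()):
    """Firing rate at a given distance from the place-field centre.

    r(d) = r_max * exp(-d^2 / (2 lambda_pl^2))
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return tuning.r_max * np.exp(-(d**2) / (2.0 * tuning.lambda_pl**2))


def sigma_from_rate(rate, params: LTPIEParams = LTPIEParams()):
    """Excitability scaling evoked by firing at ``rate`` Hz for ~1 s."""
    r = np.asarray(rate, dtype=float)
    return 1.0 + (params.sigma_max - 1.0) / (
        1.0 + np.exp(-params.beta_sigma * (r - params.r_sigma))
    )


def max_rate_over_trajectory(
    peaks: np.ndarray,
    trajectory: Trajectory,
    tuning: TuningParams = TuningParams(),
) -> np.ndarray:
    """Peak expected rate of each cell over a whole trajectory.

    Since the tuning is a monotone function of distance, the maximum rate
    over the trajectory is the rate at the minimum point-to-polyline
    distance, computed exactly (per-segment projection clamped to
    endpoints) rather than by sampling.
    """
    d = trajectory.distance_to(peaks)
    return tuning_rate(d, tuning)


def profile_from_trajectory(
    peaks: np.ndarray,
    trajectory: Trajectory | tuple,
    tuning: TuningParams = TuningParams(),
    ltpie: LTPIEParams = LTPIEParams(),
) -> np.ndarray:
    """Per-cell sigma profile evoked by a trajectory (or set of branches).

    For a branched layout (tuple of trajectories) the profile is the
    pointwise maximum of the per-branch profiles — a cell is tagged if any
    branch passed close to its place field.

    Returns an array of sigma values in [1, sigma_max].
    """
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    if peaks.size == 0:
        raise ValueError("empty tuning table")
    if isinstance(trajectory, Trajectory):
        branches = (trajectory,)
    else:
        branches = tuple(trajectory)
        if not branches:
            raise ValueError("empty trajectory set")
    r = np.max(
        [max_rate_over_trajectory(peaks, b, tuning) for b in branches], axis=0
    )
    return sigma_from_rate(r, ltpie)
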