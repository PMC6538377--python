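"""Discrete-time reduced network: threshold units with gate-scaled bias.

Dynamics per step:  v_i(t) = sum_j w_ij s_j(t-1) + i_ext_i(t) + i_g sigma_i.
Non-refractory units with v >= v_th are spike candidates; at most n_max
units spike per step (the n_max highest voltages win, ties broken by
lowest index), a winner-take-all cap standing in for inhibition.  Spikers
are refractory for tau_r subsequent steps.

Two instantiations:

* A head-direction-augmented spatial lattice (64 x 64 positions x 8
  preferred headings) whose connectivity and LTP-IE profile live in
  (x, y, theta) space — heading tuning disambiguates self-intersecting
  trajectories.
* A random "switchboard" network routing two stimulus ensembles to two
  motor ensembles through an excitability-tagged subset of an untrained
  intermediary pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import Trajectory, gamma_trajectory

__all__ = [
    "ReducedParams",
    "SPATIAL_PARAMS",
    "SWITCHBOARD_STEP_PARAMS",
    "HDTuning",
    "HDConnectivityParams",
    "HDLTPIEParams",
    "SwitchboardParams",
    "SwitchboardNetwork",
    "reduced_step",
    "build_hd_lattice",
    "hd_weight",
    "hd_position_factor",
    "hd_weight_matrix",
    "hd_ltpie_profile",
    "spatial_trigger",
    "build_switchboard",
    "encode_mapping",
    "run_reduced",
]


@dataclass(frozen=True)
class ReducedParams:
    """Step-rule constants (unitless; time in steps)."""

    v_th: float
    i_g: float
    n_max: int
    tau_r: int
    t_total: int

    def __post_init__(self):
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.tau_r < 0:
            raise ValueError("tau_r must be >= 0")


#: Intersecting-trajectory (head-direction lattice) table.
SPATIAL_PARAMS = ReducedParams(v_th=11.0, i_g=5.0, n_max=10, tau_r=6,
                               t_total=50)
#: Switchboard (non-spatial mapping) table.
SWITCHBOARD_STEP_PARAMS = ReducedParams(v_th=10.0, i_g=3.0, n_max=50,
                                        tau_r=5, t_total=5)


def reduced_step(
    weights: np.ndarray,
    prev_spikes: np.ndarray,
    refractory: np.ndarray,
    sigma: np.ndarray,
    i_ext,
    params: ReducedParams,
):
    """One winner-take-all threshold step.

    Parameters
    ----------
    weights
        (n, n) array, entry [i, j] = weight from j onto i.
    prev_spikes
        Indices of units that spiked the previous step.
    refractory
        Per-unit remaining refractory steps; updated in place semantics
        are avoided — a new array is returned.

    Returns ``(spike_idx, new_refractory)``.
    """
    n = weights.shape[0]
    v = np.asarray(i_ext, dtype=float) + params.i_g * sigma
    if np.isscalar(v) or v.shape == ():
        v = np.full(n, float(v))
    else:
        v = v.copy() if v.shape == (n,) else np.broadcast_to(v, (n,)).copy()
    if prev_spikes.size:
        v += weights[:, prev_spikes].sum(axis=1)
    eligible = refractory <= 0
    candidates = np.flatnonzero(eligible & (v >= params.v_th))
    if candidates.size > params.n_max:
        # highest-voltage winners; ties broken by lowest index
        order = np.lexsort((candidates, -v[candidates]))
        candidates = candidates[order[: params.n_max]]
        candidates.sort()
    new_refr = np.maximum(refractory - 1, 0)
    new_refr[candidates] = params.tau_r
    return candidates, new_refr


def run_reduced(
    weights: np.ndarray,
    sigma: np.ndarray,
    triggers: list[tuple[int, np.ndarray, float]],
    params: ReducedParams,
) -> list[np.ndarray]:
    """Iterate the step rule for ``params.t_total`` steps.

    ``triggers`` is a list of (step, target indices, amplitude); all other
    external input is zero.  Returns the per-step arrays of spiker
    indices.
    """
    n = weights.shape[0]
    sigma = np.asarray(sigma, dtype=float)
    refr = np.zeros(n, dtype=int)
    prev = np.empty(0, dtype=int)
    raster = []
    trigger_map: dict[int, list] = {}
    for step, idx, amp in triggers:
        if step >= params.t_total:
            raise ValueError("trigger beyond simulation horizon")
        trigger_map.setdefault(step, []).append((np.asarray(idx, int), amp))
    for t in range(params.t_total):
        i_ext = np.zeros(n)
        for idx, amp in trigger_map.get(t, []):
            i_ext[idx] += amp
        prev, refr = reduced_step(weights, prev, refr, sigma, i_ext, params)
        raster.append(prev)
    return raster


# --------------------------------------------------------------------------
# Head-direction lattice
# --------------------------------------------------------------------------

#: The eight preferred headings tiling the circle.
HD_ANGLES = np.arange(8) * (np.pi / 4.0)


@dataclass(frozen=True)
class HDTuning:
    """Per-unit (x, y) place preference and preferred heading theta."""

    xy: np.ndarray      # (n, 2) m
    theta: np.ndarray   # (n,) rad

    @property
    def n(self) -> int:
        return self.xy.shape[0]


@dataclass(frozen=True)
class HDConnectivityParams:
    lambda_xy: float = 0.25          # m
    lambda_theta: float = np.pi / 7  # rad

    def __post_init__(self):
        if self.lambda_xy <= 0 or self.lambda_theta <= 0:
            raise ValueError("length scales must be > 0")


@dataclass(frozen=True)
class HDLTPIEParams:
    """(x, y, theta) proximity kernel and logistic for the reduced profile.

    ``z0`` is the logistic midpoint of the proximity score z in (0, 1];
    0.5 centres it mid-range (a package convention — see docs).
    """

    sigma_x: float = 0.2             # m
    sigma_y: float = 0.2             # m
    sigma_theta: float = np.pi / 16  # rad
    beta: float = 20.0
    z0: float = 0.5


def build_hd_lattice(nx: int = 64, ny: int = 64, bounds: float = 1.0,
                     seed=None) -> HDTuning:
    """64 x 64 positions tiling the 2 m x 2 m environment, 8 headings.

    Headings are assigned so that every consecutive window of 8 units
    along a row contains all eight angles.  With ``seed=None`` each window
    carries the angles in a fixed cyclic order; with a seed, each window
    receives an independent random permutation (the assignment is random
    subject to the window constraint).
    """
    if nx % 8:
        raise ValueError("rows must be divisible by 8")
    xs = -bounds + (np.arange(nx) + 0.5) * (2.0 * bounds / nx)
    ys = -bounds + (np.arange(ny) + 0.5) * (2.0 * bounds / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n_windows = (nx * ny) // 8
    if seed is None:
        theta = np.tile(HD_ANGLES, n_windows)
    else:
        rng = np.random.default_rng(seed)
        theta = np.concatenate(
            [rng.permutation(HD_ANGLES) for _ in range(n_windows)]
        )
    return HDTuning(xy=xy, theta=theta)


def circular_distance(a, b):
    """Absolute angular distance on the unit circle, in [0, pi]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def hd_weight(dx, dy, dtheta,
              params: HDConnectivityParams = HDConnectivityParams()):
    """Separable Gaussian tuning-space weight.

    w = exp(-(dx^2 + dy^2) / (2 lambda_xy^2)) * exp(-dtheta^2 /
    (2 lambda_theta^2)), with dtheta a circular distance in [0, pi].
    """
    dx, dy, dtheta = (np.asarray(v, dtype=float) for v in (dx, dy, dtheta))
    return np.exp(-(dx**2 + dy**2) / (2.0 * params.lambda_xy**2)) * np.exp(
        -(dtheta**2) / (2.0 * params.lambda_theta**2)
    )


def hd_position_factor(
    xy: np.ndarray,
    params: HDConnectivityParams = HDConnectivityParams(),
    dtype=np.float32,
) -> np.ndarray:
    """Pairwise spatial Gaussian factor of the lattice weights.

    Depends only on positions, so it can be reused across lattices that
    differ only in their heading assignment.
    """
    dx = (xy[:, 0][:, None] - xy[:, 0][None, :]).astype(dtype)
    dy = (xy[:, 1][:, None] - xy[:, 1][None, :]).astype(dtype)
    return np.exp(-(dx**2 + dy**2) / (2.0 * params.lambda_xy**2))


def hd_weight_matrix(
    tuning: HDTuning,
    params: HDConnectivityParams = HDConnectivityParams(),
    dtype=np.float32,
    position_factor: np.ndarray | None = None,
) -> np.ndarray:
    """Full pairwise weight matrix over the lattice (symmetric).

    Headings take only the 8 lattice angles, so the angular factor is an
    8 x 8 lookup rather than a dense circular-distance computation.
    """
    if position_factor is None:
        position_factor = hd_position_factor(tuning.xy, params, dtype)
    idx = np.rint(tuning.theta / (np.pi / 4.0)).astype(int) % 8
    dth = circular_distance(HD_ANGLES[:, None], HD_ANGLES[None, :])
    table = np.exp(-(dth**2) / (2.0 * params.lambda_theta**2)).astype(dtype)
    w = position_factor * table[np.ix_(idx, idx)]
    np.fill_diagonal(w, 0.0)
    return w


def hd_ltpie_profile(
    tuning: HDTuning,
    trajectory: Trajectory | None = None,
    params: HDLTPIEParams = HDLTPIEParams(),
    sample_spacing: float = 0.02,
) -> np.ndarray:
    """Sigma profile from a heading-annotated trajectory.

    The trajectory is discretized at ``sample_spacing`` metres with
    heading = local tangent; for each unit, the proximity score z is
    maximised over samples and passed through the logistic
    sigma = 1 + 1 / (1 + exp(-beta (z - z0))); entries lie in (1, 2).
    """
    trajectory = trajectory or gamma_trajectory()
    pts, heads = trajectory.sample(sample_spacing)
    z = np.zeros(tuning.n)
    # chunk over trajectory samples to bound memory
    for lo in range(0, len(pts), 256):
        p = pts[lo:lo + 256]
        h = heads[lo:lo + 256]
        dx = tuning.xy[:, 0][:, None] - p[:, 0][None, :]
        dy = tuning.xy[:, 1][:, None] - p[:, 1][None, :]
        dth = circular_distance(tuning.theta[:, None], h[None, :])
        zc = np.exp(
            -0.5 * (
                dx**2 / params.sigma_x**2
                + dy**2 / params.sigma_y**2
                + dth**2 / params.sigma_theta**2
            )
        )
        z = np.maximum(z, zc.max(axis=1))
    return 1.0 + 1.0 / (1.0 + np.exp(-params.beta * (z - params.z0)))


def spatial_trigger(
    tuning: HDTuning,
    focus: tuple[float, float],
    step: int = 0,
    amplitude: float = 15.0,
    length_scale: float = 0.15,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Squared-exponential current bump focused at a point.

    Returns a (step, all-unit indices, per-unit amplitude) trigger whose
    amplitude profile is amplitude * exp(-d^2 / (2 length_scale^2)).
    Exact trigger parameters are unimportant provided cells near the focus
    are driven to spike.
    """
    d2 = np.sum((tuning.xy - np.asarray(focus)) ** 2, axis=1)
    amp = amplitude * np.exp(-d2 / (2.0 * length_scale**2))
    return step, np.arange(tuning.n), amp


# --------------------------------------------------------------------------
# Switchboard network
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchboardParams:
    """Ensemble sizes, fan counts and weights for the switchboard network."""

    n_s: int = 100     # per sensory ensemble
    n_m: int = 100     # per motor ensemble
    n_b: int = 2000    # switchboard pool
    n_bs_pool: int = 200  # switchboard cells receiving from one stimulus
    n_mb_pool: int = 200  # switchboard cells projecting to one motor group
    fan_bs: int = 10   # stimulus cells feeding each selected switchboard cell
    fan_mb: int = 25   # motor cells fed by each projecting switchboard cell
    w_mm: float = 0.35
    w_bs: float = 0.88
    w_mb: float = 2.33

    def __post_init__(self):
        if self.n_bs_pool > self.n_b or self.n_mb_pool > self.n_b:
            raise ValueError("selected subsets exceed the switchboard size")
        if self.fan_bs > self.n_s or self.fan_mb > self.n_m:
            raise ValueError("fan counts exceed ensemble sizes")


@dataclass
class SwitchboardNetwork:
    """Dense weight matrix plus the ensemble index sets.

    ``receivers[s]`` is the set of switchboard cells wired from stimulus
    ``s``; ``projectors[m]`` the set wired to motor ensemble ``m``.
    """

    weights: np.ndarray
    ensembles: dict[str, np.ndarray]
    receivers: dict[str, np.ndarray] = field(default_factory=dict)
    projectors: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def build_switchboard(params: SwitchboardParams = SwitchboardParams(),
                      seed=None) -> SwitchboardNetwork:
    """Random stimulus -> switchboard -> motor wiring.

    Layout: S1, S2, M1, M2 then the switchboard pool B.  Motor ensembles
    are recurrently all-to-all connected within themselves (no self
    connections); there is no recurrence within sensory ensembles or
    within the switchboard.  Subset draws are uniform without replacement
    and independent per ensemble (so they may overlap).
    """
    rng = np.random.default_rng(seed)
    p = params
    offsets = {}
    cursor = 0
    for name, size in (("S1", p.n_s), ("S2", p.n_s),
                       ("M1", p.n_m), ("M2", p.n_m), ("B", p.n_b)):
        offsets[name] = np.arange(cursor, cursor + size)
        cursor += size
    n = cursor
    w = np.zeros((n, n), dtype=np.float32)

    # intra-motor recurrence
    for m in ("M1", "M2"):
        idx = offsets[m]
        w[np.ix_(idx, idx)] = p.w_mm
        w[idx, idx] = 0.0

    receivers, projectors = {}, {}
    for s in ("S1", "S2"):
        chosen = rng.choice(offsets["B"], size=p.n_bs_pool, replace=False)
        receivers[s] = np.sort(chosen)
        for b in chosen:
            src = rng.choice(offsets[s], size=p.fan_bs, replace=False)
            w[b, src] = p.w_bs
    for m in ("M1", "M2"):
        chosen = rng.choice(offsets["B"], size=p.n_mb_pool, replace=False)
        projectors[m] = np.sort(chosen)
        for b in chosen:
            dst = rng.choice(offsets[m], size=p.fan_mb, replace=False)
            w[dst, b] = p.w_mb

    return SwitchboardNetwork(weights=w, ensembles=offsets,
                              receivers=receivers, projectors=projectors)


def encode_mapping(network: SwitchboardNetwork,
                   mapping: dict[str, str]) -> np.ndarray:
    """Sigma profile encoding a stimulus->motor mapping.

    ``mapping`` must be a bijection from {S1, S2} onto {M1, M2}.  Sigma=2
    for switchboard cells that both receive from a stimulus and project to
    its mapped motor ensemble; sigma=1 everywhere else.
    """
    if set(mapping) != {"S1", "S2"} or set(mapping.values()) != {"M1", "M2"}:
        raise ValueError("mapping must biject {S1,S2} onto {M1,M2}")
    sigma = np.ones(network.n)
    for s, m in mapping.items():
        tagged = np.intersect1d(network.receivers[s], network.projectors[m])
        sigma[tagged] = 2.0
    return sigma
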