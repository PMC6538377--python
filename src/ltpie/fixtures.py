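"""Deterministic trajectory and layout generators.

Every object here is a pure function of documented constants, so repeated
calls are bit-identical.  Trajectories are 2-D polylines (metres) with an
exact arc-length parameterization; they are the geometric inputs from which
excitability (LTP-IE) profiles are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "Trajectory",
    "z_trajectory",
    "alternative_trajectory",
    "branched_trajectory",
    "gamma_trajectory",
    "mapping_layout",
    "MAPPING1_PATHS",
    "MAPPING2_VARIANTS",
]


@dataclass(frozen=True)
class Trajectory:
    """An ordered 2-D polyline with exact arc-length parameterization.

    Parameters
    ----------
    waypoints
        ``(n, 2)`` array of (x, y) vertices in metres, ``n >= 2``.
    headings
        Optional per-waypoint travel headings (radians).  When absent,
        headings of sampled points default to the local segment tangent.
    """

    waypoints: np.ndarray
    headings: np.ndarray | None = None
    _line: LineString = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        wp = np.asarray(self.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[1] != 2 or wp.shape[0] < 2:
            raise ValueError("trajectory needs >= 2 (x, y) waypoints")
        if not np.all(np.isfinite(wp)):
            raise ValueError("non-finite waypoint")
        seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("zero-length segment in trajectory")
        object.__setattr__(self, "waypoints", wp)
        object.__setattr__(self, "_line", LineString(wp))

    @property
    def cumulative_length(self) -> np.ndarray:
        """Arc length at each waypoint, starting at 0."""
        seg = np.linalg.norm(np.diff(self.waypoints, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Exact minimum distance from each point to the polyline."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self._line.distance(Point(p)) for p in pts])

    def arc_position(self, points: np.ndarray) -> np.ndarray:
        """Arc length along the polyline of the nearest point to each input."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self._line.project(Point(p)) for p in pts])

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        """Points and tangent headings sampled every ``spacing`` metres.

        Endpoints of every segment are always included, so corners are never
        skipped.  Heading of a sample is the tangent of the segment it lies
        on (corner points take the heading of the incoming segment).
        """
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        pts, heads = [], []
        wp = self.waypoints
        for a, b in zip(wp[:-1], wp[1:]):
            length = float(np.linalg.norm(b - a))
            n = max(int(np.ceil(length / spacing)), 1)
            frac = np.linspace(0.0, 1.0, n + 1)[:-1]
            seg_pts = a[None, :] + frac[:, None] * (b - a)[None, :]
            theta = np.arctan2(b[1] - a[1], b[0] - a[0])
            pts.append(seg_pts)
            heads.append(np.full(len(seg_pts), theta))
        pts.append(wp[-1:])
        heads.append(heads[-1][-1:])
        return np.concatenate(pts), np.concatenate(heads)


# --------------------------------------------------------------------------
# Replay-epoch trajectories (2 m x 2 m environment, bounds [-1, 1]^2)
# --------------------------------------------------------------------------

#: Z-shaped reference trajectory: two 1.25 m horizontals joined by a 1.5 m
#: diagonal, total arc length exactly 4.0 m.
_Z_WAYPOINTS = np.array(
    [
        [-0.80, 0.60],
        [0.45, 0.60],
        [-0.45, -0.60],
        [0.80, -0.60],
    ]
)


def z_trajectory() -> Trajectory:
    """Three-segment Z with total arc length exactly 4.0 m.

    Segment lengths are 1.25 m (top, left-to-right), 1.5 m (diagonal,
    down-left) and 1.25 m (bottom, left-to-right).
    """
    return Trajectory(_Z_WAYPOINTS.copy())


_ALT_WAYPOINTS = np.array(
    [
        [-0.80, 0.85],
        [-0.80, -0.85],
        [0.80, -0.85],
        [0.80, 0.85],
    ]
)


def alternative_trajectory() -> Trajectory:
    """A U-shaped trajectory geometrically distinct from the Z.

    Used to verify that replay follows whatever profile was encoded rather
    than anything intrinsic to the recurrent connectivity; its tagged-cell
    set overlaps the Z's by well under half.
    """
    return Trajectory(_ALT_WAYPOINTS.copy())


#: Three branches radiating from a central junction at the origin
#: (one east, one to the upper left, one to the lower left).
_BRANCH_WAYPOINTS = (
    np.array([[0.0, 0.0], [0.85, 0.0]]),
    np.array([[0.0, 0.0], [-0.55, 0.65]]),
    np.array([[0.0, 0.0], [-0.55, -0.65]]),
)


def branched_trajectory() -> tuple[Trajectory, ...]:
    """Branched layout: >= 3 polylines sharing one junction point.

    The composite excitability profile of a branched layout is the
    pointwise maximum of the per-branch profiles.
    """
    return tuple(Trajectory(w.copy()) for w in _BRANCH_WAYPOINTS)


# --------------------------------------------------------------------------
# Reduced-model gamma trajectory (self-intersecting, with headings)
# --------------------------------------------------------------------------

def _gamma_waypoints() -> np.ndarray:
    # Straight eastbound leg, then a smooth 3/4 circle (radius 0.55 m,
    # centre (0.3, -0.3)) clockwise through the lower-right quadrant,
    # then a straight northbound leg.  The arc keeps successive headings
    # within the theta-coupling scale, so propagation can follow the turn.
    r, cx, cy = 0.55, 0.30, -0.30
    leg_in = np.array([[-1.0, 0.25]])
    # clockwise from the top of the circle (heading east) to its left
    # (heading north): polar angle pi/2 -> -pi (24 segments)
    phi = np.linspace(np.pi / 2.0, -np.pi, 25)
    arc = np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
    leg_out = np.array([[-0.25, 1.0]])
    return np.vstack([leg_in, arc, leg_out])


_GAMMA_WAYPOINTS = _gamma_waypoints()


def gamma_trajectory() -> Trajectory:
    """Self-intersecting 'gamma' trajectory for the head-direction model.

    Starts eastbound at (-1, 0.25) m, loops through the lower-right
    quadrant, crosses itself at (-0.25, 0.25) m — eastbound on the first
    pass, northbound on the second — and ends at (-0.25, 1) m.
    """
    return Trajectory(_GAMMA_WAYPOINTS.copy())


GAMMA_START = (-1.0, 0.25)
GAMMA_END = (-0.25, 1.0)
GAMMA_INTERSECTION = (-0.25, 0.25)


# --------------------------------------------------------------------------
# Stimulus-response mapping layout (4 m x 4 m environment, bounds [-2, 2]^2)
# --------------------------------------------------------------------------

#: Cluster centres and radius for the stimulus (S) and motor (M) regions.
MAPPING_CENTERS = {
    "S1": (-1.0, 1.0),
    "S2": (-1.0, -1.0),
    "M1": (1.0, 1.0),
    "M2": (1.0, -1.0),
}
MAPPING_RADIUS = 0.25

#: Mapping 1 (S1->M1, S2->M2): two parallel straight paths.
MAPPING1_PATHS = {
    "S1->M1": np.array([[-1.0, 1.0], [1.0, 1.0]]),
    "S2->M2": np.array([[-1.0, -1.0], [1.0, -1.0]]),
}

#: Three distinct crossing-free realisations of Mapping 2 (S1->M2, S2->M1).
#: Within each variant the two paths do not intersect; across variants the
#: path lengths differ, so stimulus-to-response delays differ.
MAPPING2_VARIANTS = (
    {
        "S1->M2": np.array(
            [[-1.0, 1.0], [-1.0, 1.7], [1.7, 1.7], [1.7, -1.0], [1.0, -1.0]]
        ),
        "S2->M1": np.array([[-1.0, -1.0], [1.0, 1.0]]),
    },
    {
        "S1->M2": np.array([[-1.0, 1.0], [1.0, -1.0]]),
        "S2->M1": np.array(
            [[-1.0, -1.0], [-1.0, -1.8], [1.8, -1.8], [1.8, 1.0], [1.0, 1.0]]
        ),
    },
    {
        "S1->M2": np.array(
            [[-1.0, 1.0], [-1.7, 1.0], [-1.7, -1.7], [1.0, -1.7], [1.0, -1.0]]
        ),
        "S2->M1": np.array([[-1.0, -1.0], [0.3, -0.3], [1.0, 1.0]]),
    },
)


def mapping_layout() -> tuple[dict, float, dict, tuple]:
    """Region geometry and encoding paths for the mapping experiments.

    Returns
    -------
    centers : dict name -> (x, y)
    radius : float
    mapping1 : dict of path name -> Trajectory
    mapping2_variants : tuple of such dicts (three variants)
    """
    m1 = {k: Trajectory(v.copy()) for k, v in MAPPING1_PATHS.items()}
    m2 = tuple(
        {k: Trajectory(v.copy()) for k, v in var.items()}
        for var in MAPPING2_VARIANTS
    )
    return dict(MAPPING_CENTERS), MAPPING_RADIUS, m1, m2
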