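"""Spiking-network construction.

Place-field lattice, distance-dependent recurrent excitation among
pyramidal cells (PCs), random PC<->INH connectivity, and uniform
gating-input weights.  The recurrent weight between PCs i and j with
place-field peaks separated by d_ij is

    w_ij = w_PC_PC * exp(-d_ij^2 / (2 lambda_PC_PC^2)),  zeroed below
    w_min_PC_PC,

which makes the matrix genuinely sparse: only pairs within the cutoff
radius lambda * sqrt(2 ln(w_PC_PC / w_min)) connect.  Self-connections are
excluded.  INH cells are untuned, receive no gating input and have no
INH<->INH connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .lif import CellParams, PC_PARAMS, INH_PARAMS

__all__ = [
    "ConnectivityParams",
    "NetworkModel",
    "build_place_lattice",
    "recurrent_weights",
    "inhibitory_connectivity",
    "assemble_network",
]


@dataclass(frozen=True)
class ConnectivityParams:
    """Weight scales, length scales and wiring probabilities.

    Weight symbols follow the convention w^{post,pre}: ``w_pc_inh`` is the
    INH->PC weight, ``w_inh_pc`` the PC->INH weight.  All synaptic weights
    are dimensionless conductance jumps relative to the leak conductance.
    """

    w_pc_pc: float = 2.6
    lambda_pc_pc: float = 0.053   # m
    w_min_pc_pc: float = 0.1
    w_pc_inh: float = 0.02        # INH -> PC
    w_inh_pc: float = 0.03        # PC -> INH
    p_pc_inh: float = 0.5         # INH -> PC connection probability
    p_inh_pc: float = 0.5         # PC -> INH connection probability
    w_pc_g: float = 0.8216        # gate weight before LTP-IE scaling
    r_g: float = 125.0            # gate Poisson rate, Hz

    def __post_init__(self):
        for name in ("w_pc_pc", "w_min_pc_pc", "w_pc_inh", "w_inh_pc",
                     "w_pc_g", "r_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.p_pc_inh <= 1 and 0 <= self.p_inh_pc <= 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        if self.lambda_pc_pc <= 0:
            raise ValueError("lambda_pc_pc must be > 0")

    @property
    def cutoff_radius(self) -> float:
        """Peak separation beyond which recurrent weights are zero (m)."""
        if self.w_pc_pc <= self.w_min_pc_pc:
            return 0.0
        return self.lambda_pc_pc * np.sqrt(
            2.0 * np.log(self.w_pc_pc / self.w_min_pc_pc)
        )


@dataclass
class NetworkModel:
    """Assembled network: tuning table, weights, population parameters."""

    peaks: np.ndarray                 # (n_pc, 2) place-field centres, m
    w_rec: sparse.csr_matrix          # PC->PC, symmetric, zero diagonal
    w_inh_from_pc: sparse.csr_matrix  # (n_inh, n_pc): PC -> INH
    w_pc_from_inh: sparse.csr_matrix  # (n_pc, n_inh): INH -> PC
    gate_weight: np.ndarray           # per-PC base gate weight
    conn: ConnectivityParams
    pc_params: CellParams = field(default_factory=lambda: PC_PARAMS)
    inh_params: CellParams = field(default_factory=lambda: INH_PARAMS)
    bounds: float = 1.0               # environment half-width, m

    def __post_init__(self):
        n_pc, n_inh = self.n_pc, self.n_inh
        if n_inh * 10 != n_pc:
            raise ValueError("require N_INH = N_PC / 10")
        if self.w_rec.shape != (n_pc, n_pc):
            raise ValueError("recurrent matrix shape mismatch")
        if (abs(self.w_rec - self.w_rec.T) > 1e-12).nnz:
            raise ValueError("recurrent matrix must be symmetric")
        if np.any(self.w_rec.diagonal() != 0):
            raise ValueError("self-connections are not allowed")
        data = self.w_rec.data
        if data.size and np.min(data) < self.conn.w_min_pc_pc - 1e-12:
            raise ValueError("stored recurrent weights below cutoff")

    @property
    def n_pc(self) -> int:
        return self.peaks.shape[0]

    @property
    def n_inh(self) -> int:
        return self.w_inh_from_pc.shape[0]


def build_place_lattice(n: int, bounds: float = 1.0) -> np.ndarray:
    """Place-field peaks approximately tiling [-bounds, bounds]^2.

    A near-square n_x x n_y grid of cell-centred positions with
    n_x * n_y >= n, truncated (row-major) to n points.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    n_x = int(np.ceil(np.sqrt(n)))
    n_y = int(np.ceil(n / n_x))
    xs = -bounds + (np.arange(n_x) + 0.5) * (2.0 * bounds / n_x)
    ys = -bounds + (np.arange(n_y) + 0.5) * (2.0 * bounds / n_y)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[:n]


def recurrent_weights(
    peaks: np.ndarray, params: ConnectivityParams
) -> sparse.csr_matrix:
    """Sparse symmetric Gaussian-of-distance recurrent weight matrix."""
    peaks = np.asarray(peaks, dtype=float)
    if not np.all(np.isfinite(peaks)):
        raise ValueError("non-finite place-field peaks")
    n = peaks.shape[0]
    r_c = params.cutoff_radius
    if r_c == 0.0:
        return sparse.csr_matrix((n, n))
    tree = cKDTree(peaks)
    pairs = tree.query_pairs(r_c, output_type="ndarray")  # i < j, d <= r_c
    if pairs.size == 0:
        return sparse.csr_matrix((n, n))
    d2 = np.sum((peaks[pairs[:, 0]] - peaks[pairs[:, 1]]) ** 2, axis=1)
    w = params.w_pc_pc * np.exp(-d2 / (2.0 * params.lambda_pc_pc**2))
    keep = w >= params.w_min_pc_pc
    i, j, w = pairs[keep, 0], pairs[keep, 1], w[keep]
    mat = sparse.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    return mat.tocsr()


def inhibitory_connectivity(
    n_pc: int,
    n_inh: int,
    params: ConnectivityParams,
    seed=None,
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Random bidirectional PC<->INH wiring.

    Each directed pair connects independently — PC->INH with probability
    ``p_inh_pc`` and weight ``w_inh_pc``; INH->PC with probability
    ``p_pc_inh`` and weight ``w_pc_inh``.  The two directions use
    independent draws.

    Returns ``(w_inh_from_pc, w_pc_from_inh)`` with shapes
    (n_inh, n_pc) and (n_pc, n_inh).
    """
    if n_pc <= 0 or n_inh <= 0:
        raise ValueError("population sizes must be positive")
    rng = np.random.default_rng(seed)
    a = rng.random((n_inh, n_pc)) < params.p_inh_pc
    b = rng.random((n_pc, n_inh)) < params.p_pc_inh
    w_inh_from_pc = sparse.csr_matrix(a * params.w_inh_pc)
    w_pc_from_inh = sparse.csr_matrix(b * params.w_pc_inh)
    return w_inh_from_pc, w_pc_from_inh


def assemble_network(
    n_pc: int = 3000,
    bounds: float = 1.0,
    conn: ConnectivityParams | None = None,
    pc_params: CellParams = PC_PARAMS,
    inh_params: CellParams = INH_PARAMS,
    seed=None,
) -> NetworkModel:
    """Compose a full network model from population-level parameters."""
    conn = conn or ConnectivityParams()
    if n_pc % 10:
        raise ValueError("n_pc must be divisible by 10 (N_INH = N_PC / 10)")
    n_inh = n_pc // 10
    peaks = build_place_lattice(n_pc, bounds)
    w_rec = recurrent_weights(peaks, conn)
    w_ip, w_pi = inhibitory_connectivity(n_pc, n_inh, conn, seed)
    gate = np.full(n_pc, conn.w_pc_g)
    return NetworkModel(
        peaks=peaks,
        w_rec=w_rec,
        w_inh_from_pc=w_ip,
        w_pc_from_inh=w_pi,
        gate_weight=gate,
        conn=conn,
        pc_params=pc_params,
        inh_params=inh_params,
        bounds=bounds,
    )
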