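"""Synthetic generators emulating the statistical structure of a monolayer
of motile, deformable cell-mimics.

Each cell-mimic is coarse-grained to a single chiral active Brownian
particle: a heading θ advanced by an angular drift ω (circle motion, sign =
handedness) plus rotational diffusion D_r, and a position advanced at speed
v0 along the heading.  The interior chirality χ_cell ∈ [−1, 1] maps
monotonically onto ω, so the persistence time of the generated motion
decreases with |χ_cell|: a racemic interior (χ_cell = 0) gives straight
persistent runs, an enantiopure one (|χ_cell| = 1) tight circles.

Also provided: exact samplers for the unit-mean k-gamma law and a rejection
sampler for the mean-field aspect-ratio law, plus polygon ensembles with
prescribed aspect ratios (elliptical n-gons) for end-to-end tests of the
shape pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Box, Trajectory
from .exceptions import NumericalError, ParameterDomainError
from .shape_stats import PolygonEnsemble, _meanfield_unnorm

__all__ = [
    "ChiralCellParams",
    "EnsembleChirality",
    "OMEGA_MAX",
    "D_R_DEFAULT",
    "map_chirality",
    "chiral_abp_trajectory",
    "sample_kgamma",
    "sample_meanfield",
    "polygons_with_ar",
]

#: Angular drift at |χ_cell| = 1, rad per unit time.  With D_R_DEFAULT the
#: effective persistence time spans roughly a decade between the racemic
#: (χ_cell = 0) and enantiopure (|χ_cell| = 1) limits.
OMEGA_MAX = 1.0
#: Rotational diffusivity (1/time); τ_p ≈ 1/D_r ≈ 20 time units at ω = 0.
D_R_DEFAULT = 0.05


@dataclass(frozen=True)
class ChiralCellParams:
    """Single-cell motility parameters of the coarse-grained mimic."""

    v0: float = 1.0
    omega: float = 0.0
    D_r: float = D_R_DEFAULT
    D_t: float = 0.0
    chi_cell: float | None = None

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.D_r < 0 or self.D_t < 0:
            raise ParameterDomainError("v0, D_r, D_t must be >= 0")
        if self.chi_cell is not None and abs(self.chi_cell) > 1:
            raise ParameterDomainError("|chi_cell| must be <= 1")


@dataclass(frozen=True)
class EnsembleChirality:
    """Handedness bookkeeping of a generated ensemble."""

    n_cw: int
    n_ccw: int

    @property
    def chi_sys(self) -> float:
        total = self.n_cw + self.n_ccw
        return abs(self.n_cw - self.n_ccw) / total if total else 0.0


def map_chirality(
    chi_cell: float,
    omega_max: float = OMEGA_MAX,
    D_r: float = D_R_DEFAULT,
) -> tuple[float, float]:
    """Map interior chirality to (ω, D_r): ω = ω_max·χ_cell, D_r fixed.

    The velocity autocorrelation of the resulting motion is
    v0²·e^(−D_r t)·cos(ωt), so effective persistence decreases
    monotonically with |χ_cell| while the sign of χ_cell sets handedness.
    """
    if abs(chi_cell) > 1:
        raise ParameterDomainError(f"|chi_cell| must be <= 1, got {chi_cell}")
    return omega_max * chi_cell, D_r


def chiral_abp_trajectory(
    params: ChiralCellParams,
    n_cells: int,
    n_frames: int,
    dt: float,
    box: Box,
    seed: int,
    chi_sys: float = 0.0,
) -> tuple[Trajectory, EnsembleChirality]:
    """Non-interacting chiral active Brownian particles on a periodic box.

    Euler–Maruyama per cell with an independent seed stream:
    θ ← θ + ω·dt + sqrt(2·D_r·dt)·η, r ← r + v0·(cosθ, sinθ)·dt
    (+ sqrt(2·D_t·dt)·ξ).  Handedness is split so that the ensemble
    chirality equals ``chi_sys`` (default racemic: equal CW/CCW counts,
    even n enforced).
    """
    if dt * max(abs(params.omega), params.D_r) >= 0.1:
        raise ParameterDomainError(
            "dt too large: require dt*max(|omega|, D_r) < 0.1 for stable heading integration"
        )
    if not 0.0 <= chi_sys <= 1.0:
        raise ParameterDomainError("chi_sys must be in [0, 1]")
    n_cw = int(round(0.5 * (1.0 + chi_sys) * n_cells))
    n_ccw = n_cells - n_cw
    if chi_sys == 0.0 and n_cells % 2:
        raise ParameterDomainError("chi_sys = 0 requires an even number of cells")
    hand = np.concatenate([np.ones(n_cw), -np.ones(n_ccw)])

    streams = np.random.SeedSequence(seed).spawn(n_cells + 1)
    init_rng = np.random.default_rng(streams[-1])
    if box.kind == "periodic":
        pos0 = init_rng.uniform(0.0, 1.0, size=(n_cells, 2)) * box.lengths
    else:
        r = box.R * np.sqrt(init_rng.uniform(0, 1, n_cells))
        ang = init_rng.uniform(0, 2 * math.pi, n_cells)
        pos0 = np.column_stack([r * np.cos(ang), r * np.sin(ang)])

    positions = np.empty((n_frames, n_cells, 2))
    for c in range(n_cells):
        rng = np.random.default_rng(streams[c])
        theta0 = rng.uniform(0, 2 * math.pi)
        dtheta = hand[c] * params.omega * dt + math.sqrt(2 * params.D_r * dt) * rng.standard_normal(n_frames - 1)
        theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
        vel = params.v0 * np.column_stack([np.cos(theta[:-1]), np.sin(theta[:-1])]) * dt
        if params.D_t > 0:
            vel = vel + math.sqrt(2 * params.D_t * dt) * rng.standard_normal((n_frames - 1, 2))
        path = pos0[c] + np.concatenate([np.zeros((1, 2)), np.cumsum(vel, axis=0)])
        positions[:, c, :] = path
    positions = box.wrap(positions) if box.kind == "periodic" else positions
    traj = Trajectory(positions=positions, dt=dt, box=box, phi=None)
    return traj, EnsembleChirality(n_cw=n_cw, n_ccw=n_ccw)


def sample_kgamma(k: float, n: int, seed: int) -> np.ndarray:
    """n i.i.d. draws from the unit-mean k-gamma law (shape k, scale 1/k)."""
    if k <= 0:
        raise ParameterDomainError(f"k must be > 0, got {k}")
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=k, scale=1.0 / k, size=n)


def sample_meanfield(
    alpha: float,
    n: int,
    seed: int,
    return_acceptance: bool = False,
) -> np.ndarray | tuple[np.ndarray, float]:
    """Rejection sampling of the mean-field AR law.

    Envelope: shifted gamma on y = AR − 1 with shape 2 (the target density
    vanishes linearly at AR = 1) and rate 0.9·α (strictly thinner target
    tail, so the likelihood ratio is bounded).  The bound M is found on a
    dense grid; acceptance below 1% raises with diagnostics.
    """
    if alpha <= 0:
        raise ParameterDomainError(f"alpha must be > 0, got {alpha}")
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rate = 0.9 * alpha
    shape = 2.0

    def ratio(y: np.ndarray) -> np.ndarray:
        ar = 1.0 + y
        g = rate**shape * y * np.exp(-rate * y)  # unnormalized Gamma(2, rate)
        return _meanfield_unnorm(ar, alpha) / g

    grid = np.geomspace(1e-8, 200.0 / alpha, 4096)
    m_bound = 1.1 * float(np.max(ratio(grid)))

    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    proposed = 0
    while filled < n:
        batch = max(1024, 2 * (n - filled))
        y = rng.gamma(shape=shape, scale=1.0 / rate, size=batch)
        u = rng.uniform(size=batch)
        r = ratio(np.maximum(y, 1e-300))
        if np.any(r > m_bound):
            m_bound = 1.1 * float(r.max())  # tighten and continue; draws so far remain valid
        acc = y[u * m_bound < r]
        take = min(acc.size, n - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
        proposed += batch
        if proposed > 100 * n and filled / max(proposed, 1) < 0.01:
            raise NumericalError(
                f"rejection acceptance {filled/proposed:.4f} < 1% for alpha={alpha}"
            )
    acceptance = filled / proposed
    sample = 1.0 + out
    return (sample, acceptance) if return_acceptance else sample


def polygons_with_ar(
    ar_values: np.ndarray | list[float],
    n_vertices: int = 64,
    seed: int = 0,
    mean_area: float = 1.0,
) -> PolygonEnsemble:
    """One-frame polygon ensemble with prescribed second-moment aspect ratios.

    Each cell is an n-gon sampled at uniform parametric angles of an ellipse
    with axis ratio equal to the requested AR — the affine image of a
    regular n-gon, whose covariance is isotropic, so the polygon's
    second-moment AR equals the axis ratio exactly.  Each polygon gets a
    random rotation and is placed on a grid of non-overlapping centers.
    """
    ar = np.asarray(ar_values, dtype=float)
    if np.any(ar < 1.0):
        raise ParameterDomainError("requested aspect ratios must be >= 1")
    if n_vertices < 12:
        raise ParameterDomainError("need n_vertices >= 12 for a faithful ellipse")
    rng = np.random.default_rng(seed)
    t = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    side = int(math.ceil(math.sqrt(ar.size)))
    spacing = 4.0 * math.sqrt(mean_area * ar.max())
    frame: dict[int, np.ndarray] = {}
    for i, r in enumerate(ar):
        b = math.sqrt(mean_area / (math.pi * r))
        a = r * b
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
        phi = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        center = spacing * np.array([i % side, i // side], dtype=float)
        frame[i] = pts @ rot.T + center
    return PolygonEnsemble(frames=[frame])
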