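"""Glassy-dynamics observables on cell-center trajectories.

Implements the standard toolbox used to characterise dense active and
thermal assemblies near jamming:

* mean-squared displacement (MSD) with full time-origin averaging and
  periodic unwrapping;
* persistence time τ_p from the ballistic-to-diffusive crossover of the
  MSD (local log-log slope crossing 1.5) and persistence length
  l_p = v̄·τ_p;
* the self-intermediate scattering function, isotropically averaged in 2D,
  F_s(q, t) = ⟨J₀(q·|Δr(t)|)⟩, and the structural relaxation time τ_α at
  which it decays to 1/e;
* the non-Gaussian parameter α₂(t) and the cage-rearrangement time t* at
  its peak, used to split cells into the most- and least-mobile quantiles
  (dynamical heterogeneity);
* Voronoi-based neighbor clustering of the fast/slow subsets and Voronoi
  area distributions (periodic tessellation via image copies).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import spatial, special

from .exceptions import (
    InputError,
    InvalidGeometryError,
    NoCrossoverError,
    ParameterDomainError,
)
from .shape_stats import PolygonEnsemble, aspect_ratio

__all__ = [
    "Box",
    "Trajectory",
    "DHResult",
    "RelaxationResult",
    "PersistenceResult",
    "CageTimeResult",
    "ClusterResult",
    "msd",
    "persistence_time",
    "self_intermediate_scattering",
    "relaxation_time",
    "relaxation_analysis",
    "non_gaussian_parameter",
    "four_point_susceptibility",
    "cage_time",
    "exclude_wall_cells",
    "mobility_subsets",
    "subset_shape_stats",
    "windowed_mobility_shape_stats",
    "cluster_subsets",
    "voronoi_areas",
    "voronoi_neighbors",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Simulation/observation domain: periodic rectangle or circular wall."""

    kind: str  # "periodic" | "circular"
    Lx: float = 0.0
    Ly: float = 0.0
    R: float = 0.0

    @classmethod
    def periodic(cls, Lx: float, Ly: float | None = None) -> "Box":
        return cls(kind="periodic", Lx=float(Lx), Ly=float(Lx if Ly is None else Ly))

    @classmethod
    def circular(cls, R: float) -> "Box":
        return cls(kind="circular", R=float(R))

    @property
    def lengths(self) -> np.ndarray:
        if self.kind != "periodic":
            raise ValueError("lengths only defined for periodic boxes")
        return np.array([self.Lx, self.Ly])

    @property
    def area(self) -> float:
        return self.Lx * self.Ly if self.kind == "periodic" else math.pi * self.R**2

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        if self.kind == "periodic":
            return np.mod(pos, self.lengths)
        return pos

    def min_image(self, d: np.ndarray) -> np.ndarray:
        if self.kind == "periodic":
            L = self.lengths
            return d - np.round(d / L) * L
        return d


@dataclass
class Trajectory:
    """Cell-center tracks: ``positions`` is (n_frames, n_cells, 2)."""

    positions: np.ndarray
    dt: float
    box: Box
    phi: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise InputError("positions must have shape (n_frames, n_cells, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions contain non-finite values")
        if self.dt <= 0:
            raise ParameterDomainError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def unwrapped(self) -> np.ndarray:
        """Positions with periodic jumps removed: per-step minimum-image
        displacements accumulated from frame 0.  Assumes no cell moves more
        than half a box length between frames."""
        if self.box.kind != "periodic":
            return self.positions
        steps = self.box.min_image(np.diff(self.positions, axis=0))
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        np.cumsum(steps, axis=0, out=steps)
        out[1:] = self.positions[0] + steps
        return out


@dataclass
class DHResult:
    """Fast/slow mobility subsets at the cage-rearrangement time."""

    t_star: float
    fast_ids: np.ndarray
    slow_ids: np.ndarray
    fraction: float
    displacements: np.ndarray
    degenerate: bool = False
    fast_stats: tuple[float, float] | None = None
    slow_stats: tuple[float, float] | None = None


@dataclass
class PersistenceResult:
    tau_p: float
    v: float
    l_p: float
    lags: np.ndarray
    slopes: np.ndarray


@dataclass
class RelaxationResult:
    q: float
    times: np.ndarray
    fs: np.ndarray
    tau_alpha: float | None
    censored: bool
    lower_bound: float
    tau_p: float | None = None
    l_p: float | None = None


@dataclass
class CageTimeResult:
    t_star: float
    lags: np.ndarray
    alpha2: np.ndarray
    boundary_peak: bool


@dataclass
class ClusterResult:
    fast_components: list[list[int]]
    slow_components: list[list[int]]

    @property
    def fast_sizes(self) -> np.ndarray:
        return np.array(sorted((len(c) for c in self.fast_components), reverse=True))

    @property
    def slow_sizes(self) -> np.ndarray:
        return np.array(sorted((len(c) for c in self.slow_components), reverse=True))


# ---------------------------------------------------------------------------
# displacement statistics
# ---------------------------------------------------------------------------


def _default_lags(n_frames: int, max_lag: int | None) -> np.ndarray:
    if max_lag is None:
        max_lag = n_frames - 1
    if max_lag >= n_frames or max_lag < 1:
        raise InputError(f"max_lag must be in [1, {n_frames - 1}]")
    return np.arange(1, max_lag + 1)


def msd(
    traj: Trajectory,
    max_lag: int | None = None,
    lags: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged mean-squared displacement.

    Returns ``(times, msd)`` with times in trajectory time units (lag·dt).
    """
    if traj.n_frames < 2:
        raise InputError("need at least 2 frames")
    lag_arr = np.asarray(lags, dtype=int) if lags is not None else _default_lags(traj.n_frames, max_lag)
    if lag_arr.max() >= traj.n_frames:
        raise InputError("largest lag exceeds trajectory length")
    u = traj.unwrapped()
    out = np.empty(lag_arr.size)
    for i, lag in enumerate(lag_arr):
        d = u[lag:] - u[:-lag]
        out[i] = np.mean(np.sum(d * d, axis=-1))
    return lag_arr * traj.dt, out


def _log_spaced_subset(lags: np.ndarray, per_decade: int = 16) -> np.ndarray:
    lo, hi = lags.min(), lags.max()
    n = max(int(math.log10(hi / lo) * per_decade), 8)
    pick = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return pick[np.isin(pick, lags)]


def persistence_time(times: np.ndarray, msd_values: np.ndarray) -> PersistenceResult:
    """Persistence time from the ballistic-to-diffusive MSD crossover.

    The local log-log slope is computed by centered differences on a
    log-spaced subset of lags and smoothed with a 3-point moving average;
    τ_p is the first time the smoothed slope crosses 1.5 from above (linear
    interpolation in log time).  The early-time speed v̄ is estimated from
    the first ballistic lags, and l_p = v̄·τ_p.
    """
    times = np.asarray(times, float)
    m = np.asarray(msd_values, float)
    keep = (times > 0) & (m > 0)
    times, m = times[keep], m[keep]
    if times.size < 8:
        raise InputError("MSD curve too short for crossover analysis")
    # log-spaced subset in *time*
    idx = np.unique(np.searchsorted(times, np.geomspace(times[0], times[-1], 64)))
    idx = idx[idx < times.size]
    lt, lm = np.log(times[idx]), np.log(m[idx])
    slopes = np.empty(lt.size)
    slopes[1:-1] = (lm[2:] - lm[:-2]) / (lt[2:] - lt[:-2])
    slopes[0], slopes[-1] = slopes[1], slopes[-2]
    smooth = np.convolve(slopes, np.ones(3) / 3.0, mode="same")
    smooth[0], smooth[-1] = slopes[0], slopes[-1]

    if smooth[:max(3, smooth.size // 4)].max() < 1.8:
        raise NoCrossoverError("no ballistic regime (early log-log slope < 1.8)")
    if smooth.min() > 1.2:
        raise NoCrossoverError("no diffusive regime reached (log-log slope stays > 1.2)")

    below = np.nonzero(smooth < 1.5)[0]
    # first crossing *after* the ballistic maximum
    start = int(np.argmax(smooth[:max(3, smooth.size // 4)]))
    below = below[below > start]
    if below.size == 0:
        raise NoCrossoverError("slope never crosses 1.5 after the ballistic regime")
    j = below[0]
    # interpolate crossing in log time
    s0, s1 = smooth[j - 1], smooth[j]
    f = (s0 - 1.5) / (s0 - s1) if s1 != s0 else 0.5
    log_tau = lt[j - 1] + f * (lt[j] - lt[j - 1])
    tau_p = float(np.exp(log_tau))

    nb = min(3, times.size)
    v = float(np.mean(np.sqrt(m[:nb]) / times[:nb]))
    return PersistenceResult(tau_p=tau_p, v=v, l_p=v * tau_p, lags=np.exp(lt), slopes=smooth)


def self_intermediate_scattering(
    traj: Trajectory,
    q: float,
    lags: Sequence[int] | None = None,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic 2D self-intermediate scattering function.

    F_s(q, t) = ⟨J₀(q·|Δr(t)|)⟩ over cells and time origins (stride
    ``origin_stride``); F_s(q, 0) = 1 exactly.  Returns ``(times, fs)``
    including the t = 0 point.
    """
    if q <= 0:
        raise ParameterDomainError(f"q must be > 0, got {q}")
    lag_arr = np.asarray(lags, dtype=int) if lags is not None else _default_lags(traj.n_frames, max_lag)
    u = traj.unwrapped()
    fs = np.empty(lag_arr.size)
    for i, lag in enumerate(lag_arr):
        origins = np.arange(0, traj.n_frames - lag, origin_stride)
        d = u[origins + lag] - u[origins]
        r = np.sqrt(np.sum(d * d, axis=-1))
        fs[i] = np.mean(special.j0(q * r))
    times = np.concatenate([[0.0], lag_arr * traj.dt])
    return times, np.concatenate([[1.0], fs])


def relaxation_time(times: np.ndarray, fs: np.ndarray) -> tuple[float | None, bool, float]:
    """Structural relaxation time: first crossing of F_s below 1/e.

    Returns ``(tau_alpha, censored, lower_bound)``; censored runs return
    ``tau_alpha=None`` with the maximum lag as a lower bound.
    """
    times = np.asarray(times, float)
    fs = np.asarray(fs, float)
    target = 1.0 / math.e
    below = np.nonzero(fs < target)[0]
    if below.size == 0:
        return None, True, float(times[-1])
    j = int(below[0])
    if j == 0:
        return float(times[0]), False, float(times[0])
    f0, f1 = fs[j - 1], fs[j]
    t0, t1 = times[j - 1], times[j]
    tau = t0 + (f0 - target) / (f0 - f1) * (t1 - t0)
    return float(tau), False, float(tau)


def relaxation_analysis(
    traj: Trajectory,
    q: float,
    lags: Sequence[int] | None = None,
    origin_stride: int = 1,
) -> RelaxationResult:
    """F_s(q, t), τ_α and — when the MSD spans the crossover — τ_p and l_p."""
    times, fs = self_intermediate_scattering(traj, q, lags=lags, origin_stride=origin_stride)
    tau_alpha, censored, bound = relaxation_time(times, fs)
    tau_p = l_p = None
    try:
        t_m, m = msd(traj, lags=lags)
        pres = persistence_time(t_m, m)
        tau_p, l_p = pres.tau_p, pres.l_p
    except (NoCrossoverError, InputError):
        pass
    return RelaxationResult(
        q=q, times=times, fs=fs, tau_alpha=tau_alpha, censored=censored,
        lower_bound=bound, tau_p=tau_p, l_p=l_p,
    )


# ---------------------------------------------------------------------------
# dynamical heterogeneity
# ---------------------------------------------------------------------------


def non_gaussian_parameter(
    traj: Trajectory,
    lags: Sequence[int] | None = None,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2D non-Gaussian parameter α₂(t) = ⟨Δr⁴⟩ / (2⟨Δr²⟩²) − 1."""
    lag_arr = np.asarray(lags, dtype=int) if lags is not None else _default_lags(traj.n_frames, max_lag)
    u = traj.unwrapped()
    a2 = np.empty(lag_arr.size)
    for i, lag in enumerate(lag_arr):
        d = u[lag:] - u[:-lag]
        r2 = np.sum(d * d, axis=-1)
        m2 = np.mean(r2)
        m4 = np.mean(r2 * r2)
        a2[i] = m4 / (2.0 * m2 * m2) - 1.0 if m2 > 0 else 0.0
    return lag_arr * traj.dt, a2


def four_point_susceptibility(
    traj: Trajectory,
    overlap_cutoff: float,
    lags: Sequence[int] | None = None,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Four-point susceptibility χ₄(t) of the self-overlap.

    Per time origin, ``Q(t₀, t)`` is the fraction of cells displaced less
    than ``overlap_cutoff`` over [t₀, t₀ + t]; χ₄(t) = N·Var_{t₀}[Q].
    Peaks where cooperative rearrangement is maximal — an alternative
    definition of the cage time.
    """
    if overlap_cutoff <= 0:
        raise ParameterDomainError("overlap_cutoff must be > 0")
    lag_arr = np.asarray(lags, dtype=int) if lags is not None else _default_lags(traj.n_frames, max_lag)
    u = traj.unwrapped()
    n = traj.n_cells
    chi4 = np.empty(lag_arr.size)
    for i, lag in enumerate(lag_arr):
        d = u[lag:] - u[:-lag]
        q = np.mean(np.sqrt(np.sum(d * d, axis=-1)) < overlap_cutoff, axis=1)
        chi4[i] = n * np.var(q)
    return lag_arr * traj.dt, chi4


def cage_time(
    traj: Trajectory,
    lags: Sequence[int] | None = None,
    max_lag: int | None = None,
    method: str = "alpha2",
    overlap_cutoff: float | None = None,
) -> CageTimeResult:
    """Cage-rearrangement time t*: lag of maximal dynamical heterogeneity.

    ``method="alpha2"`` (default) peaks the 2D non-Gaussian parameter;
    ``method="chi4"`` peaks the four-point susceptibility of the
    self-overlap, with ``overlap_cutoff`` defaulting to 0.3 of the mean
    cell diameter.  A peak at the first or last lag — or, for α₂, a flat
    curve that never rises above 0.05, as for Gaussian displacements —
    triggers a boundary-peak warning: the trajectory does not resolve an
    interior heterogeneity maximum.
    """
    if method == "alpha2":
        times, a2 = non_gaussian_parameter(traj, lags=lags, max_lag=max_lag)
        floor = 0.05
    elif method == "chi4":
        if overlap_cutoff is None:
            overlap_cutoff = 0.3 * math.sqrt(traj.box.area / traj.n_cells)
        times, a2 = four_point_susceptibility(traj, overlap_cutoff, lags=lags, max_lag=max_lag)
        floor = 0.0
    else:
        raise ParameterDomainError(f"unknown cage-time method {method!r}")
    j = int(np.argmax(a2))
    boundary = j in (0, a2.size - 1) or a2[j] <= floor
    if boundary:
        warnings.warn(
            "non-Gaussian parameter has no resolved interior maximum "
            "(peak at the lag-range boundary or below the 0.05 noise floor); "
            "t* is unreliable",
            stacklevel=2,
        )
    return CageTimeResult(t_star=float(times[j]), lags=times, alpha2=a2, boundary_peak=boundary)


def exclude_wall_cells(traj: Trajectory, margin_diameters: float = 1.0) -> tuple[Trajectory, np.ndarray]:
    """Drop cells that ever come within ``margin_diameters`` mean cell
    diameters of a circular wall; returns the reduced trajectory and the
    kept cell indices.  Off by default in the pipelines — wall effects are
    a robustness check, not part of the standard analysis."""
    if traj.box.kind != "circular":
        raise InputError("wall exclusion only applies to circular boxes")
    sigma = 2.0 * math.sqrt(traj.box.area / (math.pi * traj.n_cells))
    r_max = np.max(np.sqrt(np.sum(traj.positions**2, axis=-1)), axis=0)
    keep = np.nonzero(r_max <= traj.box.R - margin_diameters * sigma)[0]
    if keep.size == 0:
        raise InputError("wall exclusion removed every cell")
    return Trajectory(traj.positions[:, keep], dt=traj.dt, box=traj.box, phi=traj.phi), keep


def mobility_subsets(
    traj: Trajectory,
    t_star: float,
    fraction: float = 0.10,
) -> DHResult:
    """Most/least mobile cell subsets over the cage-rearrangement time.

    Per-cell mobility is the time-origin-averaged displacement magnitude at
    lag t*; the top and bottom ``fraction`` quantiles (ties broken by
    cell_id for determinism) form the fast and slow sets.
    """
    if not 0.0 < fraction <= 0.5:
        raise ParameterDomainError("fraction must be in (0, 0.5]")
    lag = max(1, int(round(t_star / traj.dt)))
    if lag >= traj.n_frames:
        raise InputError("t_star exceeds the trajectory length")
    u = traj.unwrapped()
    d = u[lag:] - u[:-lag]
    disp = np.mean(np.sqrt(np.sum(d * d, axis=-1)), axis=0)

    n = traj.n_cells
    n_sub = max(1, int(round(fraction * n)))
    ids = np.arange(n)
    order = np.lexsort((ids, disp))  # ascending displacement, ties by id
    slow_ids = np.sort(order[:n_sub])
    fast_ids = np.sort(order[-n_sub:])
    degenerate = bool(np.all(disp == disp[0]))
    if degenerate:
        warnings.warn("all cells have identical mobility; subsets set by tie-break", stacklevel=2)
    return DHResult(
        t_star=float(t_star), fast_ids=fast_ids, slow_ids=slow_ids,
        fraction=fraction, displacements=disp, degenerate=degenerate,
    )


def subset_shape_stats(
    dh: DHResult,
    polygons: PolygonEnsemble,
    frames: Sequence[int] | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(AR̄, SD(AR)) of the fast and slow subsets, pooled over frames.

    ``frames`` restricts the aggregation window (default: every frame of the
    ensemble).  Populates ``dh.fast_stats`` / ``dh.slow_stats``.
    """
    from .exceptions import CoverageError

    frame_ids = range(polygons.n_frames) if frames is None else frames
    stats_out = []
    for ids in (dh.fast_ids, dh.slow_ids):
        ars = []
        wanted = set(int(i) for i in ids)
        for f in frame_ids:
            frame = polygons.frames[f]
            missing = wanted - set(frame)
            if missing:
                raise CoverageError(f"frame {f} lacks polygons for cells {sorted(missing)[:5]}")
            ars.extend(aspect_ratio(frame[c]) for c in sorted(wanted))
        arr = np.asarray(ars)
        stats_out.append((float(arr.mean()), float(arr.std(ddof=0))))
    dh.fast_stats, dh.slow_stats = stats_out[0], stats_out[1]
    return stats_out[0], stats_out[1]


# ---------------------------------------------------------------------------
# Voronoi geometry
# ---------------------------------------------------------------------------


def _check_distinct(points: np.ndarray, box: Box) -> None:
    if points.shape[0] < 4:
        raise InputError("need at least 4 points for a Voronoi tessellation")
    tree = spatial.cKDTree(points, boxsize=box.lengths if box.kind == "periodic" else None)
    d, _ = tree.query(points, k=2)
    scale = math.sqrt(box.area / points.shape[0])
    if np.any(d[:, 1] < 1e-9 * scale):
        raise InvalidGeometryError("duplicate or co-located points")


def _tiled(points: np.ndarray, box: Box) -> np.ndarray:
    L = box.lengths
    offsets = [np.array([i, j]) * L for i in (-1, 0, 1) for j in (-1, 0, 1)]
    return np.concatenate([points + off for off in offsets])


def voronoi_neighbors(points: np.ndarray, box: Box) -> set[tuple[int, int]]:
    """Pairs of cells sharing a Voronoi edge (periodic via 3×3 image copies;
    circular/walled data uses the plain tessellation)."""
    points = np.asarray(points, float)
    _check_distinct(points, box)
    n = points.shape[0]
    if box.kind == "periodic":
        pts = _tiled(box.wrap(points), box)
    else:
        pts = points
    vor = spatial.Voronoi(pts)
    pairs: set[tuple[int, int]] = set()
    for a, b in vor.ridge_points:
        ia, ib = int(a) % n, int(b) % n
        if box.kind == "periodic" and not (a // n == 4 or b // n == 4):
            continue  # keep only ridges touching the central copy
        if ia != ib:
            pairs.add((min(ia, ib), max(ia, ib)))
    return pairs


def windowed_mobility_shape_stats(
    traj: Trajectory,
    polygons: PolygonEnsemble,
    t_star: float,
    fraction: float = 0.10,
) -> tuple[tuple[float, float], tuple[float, float], int]:
    """Fast/slow shape statistics with per-time-origin subset identification.

    For every window of duration t* (half-overlapping), cells are ranked by
    their displacement across the window and the top/bottom ``fraction``
    form that window's fast/slow subsets; their aspect ratios over the
    window's frames are pooled across windows.  Re-identifying subsets per
    origin keeps the fast/slow contrast even when mobility identities decay
    on the t* scale.  Returns ``(fast_stats, slow_stats, lag_frames)`` with
    each stats pair (AR̄, SD(AR)).

    Requires ``polygons`` frames aligned one-to-one with trajectory frames.
    """
    if not 0.0 < fraction <= 0.5:
        raise ParameterDomainError("fraction must be in (0, 0.5]")
    if polygons.n_frames != traj.n_frames:
        from .exceptions import CoverageError

        raise CoverageError(
            f"polygon ensemble has {polygons.n_frames} frames, trajectory {traj.n_frames}"
        )
    lag = int(np.clip(round(t_star / traj.dt), 1, traj.n_frames // 2))
    u = traj.unwrapped()
    n = traj.n_cells
    n_sub = max(1, int(round(fraction * n)))
    ids = np.arange(n)
    ar_frames = np.array([
        [aspect_ratio(polygons.frames[f][c], check_simple=False) for c in range(n)]
        for f in range(traj.n_frames)
    ])
    fast_pool: list[np.ndarray] = []
    slow_pool: list[np.ndarray] = []
    for start in range(0, traj.n_frames - lag, max(1, lag // 2)):
        d = np.sqrt(np.sum((u[start + lag] - u[start]) ** 2, axis=-1))
        order = np.lexsort((ids, d))
        window = ar_frames[start:start + lag]
        slow_pool.append(window[:, order[:n_sub]].ravel())
        fast_pool.append(window[:, order[-n_sub:]].ravel())
    fast = np.concatenate(fast_pool)
    slow = np.concatenate(slow_pool)
    return (
        (float(fast.mean()), float(fast.std(ddof=0))),
        (float(slow.mean()), float(slow.std(ddof=0))),
        lag,
    )


def cluster_subsets(dh: DHResult, points: np.ndarray, box: Box) -> ClusterResult:
    """Connected components of the fast (and slow) cells under Voronoi
    adjacency in a single frame."""
    pairs = voronoi_neighbors(points, box)

    def components(ids: np.ndarray) -> list[list[int]]:
        idset = set(int(i) for i in ids)
        parent = {i: i for i in idset}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            if a in idset and b in idset:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        groups: dict[int, list[int]] = {}
        for i in idset:
            groups.setdefault(find(i), []).append(i)
        return [sorted(g) for g in sorted(groups.values(), key=lambda g: (-len(g), g[0]))]

    return ClusterResult(
        fast_components=components(dh.fast_ids),
        slow_components=components(dh.slow_ids),
    )


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def voronoi_areas(
    points: np.ndarray,
    box: Box,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell Voronoi areas and a density-normalized histogram.

    Periodic boxes tessellate 3×3 image copies and keep the central cells,
    so the areas sum to the box area.  Circular boxes clip each region to
    the wall.  Returns ``(areas, hist, bin_edges)``.
    """
    points = np.asarray(points, float)
    _check_distinct(points, box)
    n = points.shape[0]
    if box.kind == "periodic":
        pts = _tiled(box.wrap(points), box)
        vor = spatial.Voronoi(pts)
        areas = np.empty(n)
        for i in range(n):
            region = vor.regions[vor.point_region[4 * n + i]]
            if -1 in region or len(region) < 3:
                raise InvalidGeometryError(f"open Voronoi region for cell {i}")
            areas[i] = _polygon_area(vor.vertices[region])
    else:
        from shapely.geometry import Point, Polygon

        disk = Point(0.0, 0.0).buffer(box.R, quad_segs=128)
        # reflect points across the wall so outer regions are bounded
        r = np.sqrt(np.sum(points**2, axis=1))
        mirrored = points * ((2 * box.R / np.maximum(r, 1e-12) - 1))[:, None]
        vor = spatial.Voronoi(np.concatenate([points, mirrored]))
        areas = np.empty(n)
        for i in range(n):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 3:
                raise InvalidGeometryError(f"open Voronoi region for cell {i}")
            poly = Polygon(vor.vertices[region]).intersection(disk)
            areas[i] = poly.area
    hist, edges = np.histogram(areas, bins=bins, density=True)
    return areas, hist, edges
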