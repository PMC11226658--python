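"""Thermal Vertex Model of a confluent monolayer on a periodic domain.

The tissue is a degree-3 polygonal tiling of the torus (every edge shared by
exactly two cells, V − E + F = 0).  The mechanical energy is the standard
two-term form

    E = Σ_i [ K_A (A_i − A0)² + K_P (P_i − P0)² ],

with per-cell area A_i and perimeter P_i; the target shape index
p0 = P0/√A0 interpolates between solid-like (low p0) and fluid-like tissue.
Vertices follow overdamped Langevin dynamics at temperature T
(Euler–Maruyama, friction γ), and short edges undergo T1 neighbor exchanges
so the tissue can flow.  A per-vertex mobility mask supports the
frozen-cluster protocol: freeze every cell outside a compact cluster of n
cells and let only vertices whose incident cells are *all* inside the
cluster move — for n = 1 no vertex is mobile and the single interior cell
cannot change shape at all.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import spatial

from .dynamics import Box, Trajectory
from .exceptions import InvalidGeometryError, NumericalError, ParameterDomainError
from .shape_stats import PolygonEnsemble

__all__ = [
    "VMParams",
    "VMState",
    "VMTrajectory",
    "init_tissue",
    "energy",
    "forces",
    "step_brownian",
    "t1_transition",
    "run",
    "freeze_exterior",
    "frozen_cluster_experiment",
]


@dataclass(frozen=True)
class VMParams:
    """Mechanical and integration parameters (units: A0 = K_A = γ = 1)."""

    K_A: float = 1.0
    A0: float = 1.0
    K_P: float = 1.0
    p0: float = 3.72          # target shape index; P0 = p0·√A0
    T: float = 0.0            # temperature in energy units
    gamma: float = 1.0        # vertex friction
    dt: float = 0.01
    l_t1: float | None = None  # T1 edge-length threshold; default 0.04·√A0

    @property
    def P0(self) -> float:
        return self.p0 * math.sqrt(self.A0)

    @property
    def t1_threshold(self) -> float:
        return 0.04 * math.sqrt(self.A0) if self.l_t1 is None else self.l_t1


class VMState:
    """Vertex positions + cell-to-vertex topology on a periodic rectangle."""

    def __init__(
        self,
        vertices: np.ndarray,
        cells: list[list[int]],
        box: Box,
        params: VMParams,
        mobile_mask: np.ndarray | None = None,
        mobile_cells: set[int] | None = None,
    ) -> None:
        self.vertices = np.asarray(vertices, dtype=float)
        self.cells = [list(map(int, c)) for c in cells]
        self.box = box
        self.params = params
        self.mobile_mask = (
            np.ones(len(self.vertices), dtype=bool) if mobile_mask is None else np.asarray(mobile_mask, bool)
        )
        self.mobile_cells = mobile_cells if mobile_cells is not None else set(range(len(self.cells)))
        self._flat: dict | None = None

    # -- topology caches ----------------------------------------------------

    def invalidate(self) -> None:
        self._flat = None

    def flat(self) -> dict:
        """Flattened cycle arrays for vectorized geometry/forces."""
        if self._flat is None:
            lens = np.array([len(c) for c in self.cells])
            starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
            fv = np.concatenate([np.asarray(c) for c in self.cells])
            nxt = np.arange(fv.size) + 1
            prv = np.arange(fv.size) - 1
            for s, l in zip(starts, lens):
                nxt[s + l - 1] = s
                prv[s] = s + l - 1
            cell_of = np.repeat(np.arange(len(self.cells)), lens)
            # unique undirected edges with their two incident cells
            e_a, e_b = fv, fv[nxt]
            key = np.where(e_a < e_b, e_a * len(self.vertices) + e_b, e_b * len(self.vertices) + e_a)
            order = np.argsort(key, kind="stable")
            uk = key[order]
            first = np.concatenate([[True], uk[1:] != uk[:-1]])
            idx_first = order[first]
            idx_second = order[~first] if (~first).any() else np.empty(0, int)
            self._flat = {
                "lens": lens, "starts": starts, "fv": fv, "next": nxt, "prev": prv,
                "cell_of": cell_of,
                "edge_v1": e_a[idx_first], "edge_v2": e_b[idx_first],
                "edge_cell1": cell_of[idx_first], "edge_cell2": cell_of[idx_second],
                "n_edges": idx_first.size,
            }
        return self._flat

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    # -- geometry -----------------------------------------------------------

    def _segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Minimum-image step vectors along every cell cycle and the
        unwrapped vertex coordinates per flat entry."""
        fl = self.flat()
        pos = self.vertices
        seg = self.box.min_image(pos[fl["fv"][fl["next"]]] - pos[fl["fv"]])
        # unwrap within each cell: u[j] = pos[v0] + sum of segs before j
        cs = np.concatenate([np.zeros((1, 2)), np.cumsum(seg, axis=0)[:-1]])
        base = cs[fl["starts"]]
        u = pos[fl["fv"][fl["starts"]]].repeat(fl["lens"], axis=0) + cs - base.repeat(fl["lens"], axis=0)
        return seg, u

    def areas_perimeters(self) -> tuple[np.ndarray, np.ndarray]:
        fl = self.flat()
        seg, u = self._segments()
        un = u + seg
        cross = u[:, 0] * un[:, 1] - un[:, 0] * u[:, 1]
        areas = 0.5 * np.add.reduceat(cross, fl["starts"])
        perims = np.add.reduceat(np.sqrt(np.sum(seg * seg, axis=1)), fl["starts"])
        return areas, perims

    def cell_centroids(self) -> np.ndarray:
        fl = self.flat()
        seg, u = self._segments()
        un = u + seg
        cross = u[:, 0] * un[:, 1] - un[:, 0] * u[:, 1]
        areas = 0.5 * np.add.reduceat(cross, fl["starts"])
        cx = np.add.reduceat((u[:, 0] + un[:, 0]) * cross, fl["starts"]) / (6.0 * areas)
        cy = np.add.reduceat((u[:, 1] + un[:, 1]) * cross, fl["starts"]) / (6.0 * areas)
        return self.box.wrap(np.column_stack([cx, cy]))

    def cell_polygons(self) -> dict[int, np.ndarray]:
        """Unwrapped polygon outline per cell (one frame of a PolygonEnsemble)."""
        fl = self.flat()
        _, u = self._segments()
        return {
            i: u[s:s + l].copy()
            for i, (s, l) in enumerate(zip(fl["starts"], fl["lens"]))
        }

    def edge_lengths(self) -> np.ndarray:
        fl = self.flat()
        d = self.box.min_image(self.vertices[fl["edge_v2"]] - self.vertices[fl["edge_v1"]])
        return np.sqrt(np.sum(d * d, axis=1))

    # -- invariants ---------------------------------------------------------

    def validate(self, *, check_area: bool = True) -> None:
        """Assert the torus-tiling invariants; raise InvalidGeometryError."""
        fl = self.flat()
        nv, nc = self.n_vertices, self.n_cells
        ne = fl["fv"].size / 2
        if fl["n_edges"] * 2 != fl["fv"].size:
            raise InvalidGeometryError("some edge is not shared by exactly two cells")
        deg = np.bincount(fl["fv"], minlength=nv)
        if not np.all(deg == 3):
            bad = np.nonzero(deg != 3)[0][:5]
            raise InvalidGeometryError(f"vertices {bad.tolist()} do not have degree 3")
        if nv - ne + nc != 0:
            raise InvalidGeometryError(f"Euler characteristic {nv - ne + nc} != 0 on the torus")
        if any(len(set(c)) != len(c) for c in self.cells):
            raise InvalidGeometryError("repeated vertex within a cell cycle")
        if check_area:
            areas, _ = self.areas_perimeters()
            if np.any(areas <= 0):
                raise InvalidGeometryError("non-positively-oriented or inverted cell")
            if abs(areas.sum() - self.box.area) > 1e-8 * self.box.area:
                raise InvalidGeometryError(
                    f"cell areas sum to {areas.sum():.12g}, box area {self.box.area:.12g}"
                )

    def copy(self) -> "VMState":
        return VMState(
            vertices=self.vertices.copy(),
            cells=[list(c) for c in self.cells],
            box=self.box,
            params=self.params,
            mobile_mask=self.mobile_mask.copy(),
            mobile_cells=set(self.mobile_cells),
        )


@dataclass
class VMTrajectory:
    """Snapshots of a vertex-model run at a fixed stride."""

    times: np.ndarray
    centroids: np.ndarray          # (n_snapshots, n_cells, 2), wrapped
    polygons: PolygonEnsemble      # outline per cell per snapshot
    dt_snapshot: float
    box: Box
    t1_events: list[tuple[int, int, int]] = field(default_factory=list)
    final_state: VMState | None = None

    def trajectory(self) -> Trajectory:
        return Trajectory(positions=self.centroids, dt=self.dt_snapshot, box=self.box, phi=1.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _lattice_shape(n_cells: int, box_aspect: float) -> tuple[int, int]:
    """Factor n_cells = nx·ny (ny even) with Ly/Lx = (√3/2)(ny/nx) closest to
    box_aspect."""
    best = None
    for ny in range(2, n_cells + 1, 2):
        if n_cells % ny:
            continue
        nx = n_cells // ny
        aspect = (math.sqrt(3) / 2.0) * ny / nx
        score = abs(math.log(aspect / box_aspect))
        if best is None or score < best[0]:
            best = (score, nx, ny)
    if best is None:
        raise ParameterDomainError(
            f"n_cells={n_cells} cannot tile a periodic triangular lattice (need an even factor)"
        )
    return best[1], best[2]


def _periodic_voronoi(points: np.ndarray, box: Box) -> tuple[np.ndarray, list[list[int]]]:
    """Exact periodic Voronoi topology from a 3×3-tiled Delaunay triangulation.

    Every Voronoi vertex is the circumcenter of a Delaunay triangle; on the
    torus each triangle has exactly one representative whose circumcenter
    falls in the central box.  Cells are built by collecting, per seed
    point, the kept triangles incident to any of its images and ordering
    them CCW around the seed.
    """
    n = points.shape[0]
    L = box.lengths
    offsets = [np.array([i, j]) * L for j in (-1, 0, 1) for i in (-1, 0, 1)]
    tiled = np.concatenate([points + off for off in offsets])
    tri = spatial.Delaunay(tiled)

    a = tiled[tri.simplices[:, 0]]
    b = tiled[tri.simplices[:, 1]]
    c = tiled[tri.simplices[:, 2]]
    ab, ac = b - a, c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    if np.any(np.abs(d) < 1e-12):
        raise InvalidGeometryError("degenerate (collinear) triangle in tessellation")
    ab2 = np.sum(ab * ab, axis=1)
    ac2 = np.sum(ac * ac, axis=1)
    ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
    uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    cc = a + np.column_stack([ux, uy])

    keep = (cc[:, 0] >= 0) & (cc[:, 0] < L[0]) & (cc[:, 1] >= 0) & (cc[:, 1] < L[1])
    kept_idx = np.nonzero(keep)[0]
    if kept_idx.size != 2 * n:
        raise InvalidGeometryError(
            f"periodic tessellation produced {kept_idx.size} vertices, expected {2 * n}"
        )
    vert_pos = cc[kept_idx]
    vid_of_tri = {int(t): v for v, t in enumerate(kept_idx)}

    cells: list[list[int]] = []
    incident: list[list[tuple[float, int]]] = [[] for _ in range(n)]
    for t in kept_idx:
        cct = cc[t]
        for g in tri.simplices[t]:
            p = int(g) % n
            delta = cct - tiled[g]
            incident[p].append((math.atan2(delta[1], delta[0]), vid_of_tri[int(t)]))
    for p in range(n):
        ring = sorted(incident[p])
        if len(ring) < 3:
            raise InvalidGeometryError(f"cell {p} has fewer than 3 Voronoi vertices")
        if len(set(v for _, v in ring)) != len(ring):
            raise InvalidGeometryError(f"cell {p} repeats a Voronoi vertex (degenerate)")
        cells.append([v for _, v in ring])
    return vert_pos, cells


def init_tissue(
    n_cells: int,
    box_aspect: float = 1.0,
    disorder: float = 0.3,
    seed: int = 0,
    params: VMParams | None = None,
    max_retries: int = 10,
) -> VMState:
    """Voronoi tissue from a perturbed triangular lattice on a periodic box.

    The box is sized so the mean cell area equals A0; ``disorder`` is the
    perturbation amplitude in units of the lattice spacing.  Degenerate
    tessellations (cocircular quadruples) are re-perturbed with an
    incremented seed, logged via a warning.
    """
    if n_cells < 4:
        raise ParameterDomainError("need at least 4 cells")
    if not 0.0 <= disorder <= 0.5:
        raise ParameterDomainError("disorder must be in [0, 0.5]")
    params = params or VMParams()
    nx, ny = _lattice_shape(n_cells, box_aspect)
    # spacing so that each lattice site owns area A0
    dx = math.sqrt(params.A0 / (math.sqrt(3) / 2.0))
    dy = dx * math.sqrt(3) / 2.0
    box = Box.periodic(nx * dx, ny * dy)

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
    # fixed irrational sub-lattice offset keeps circumcenters off the box
    # boundary (keeps the disorder=0 tiling exactly hexagonal)
    pts = np.column_stack([
        (ii + 0.5 * (jj % 2) + 0.26131).ravel() * dx,
        (jj + 0.5 + 0.17407).ravel() * dy,
    ])
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        if disorder > 0:
            ang = rng.uniform(0, 2 * math.pi, n_cells)
            rad = disorder * dx * np.sqrt(rng.uniform(0, 1, n_cells))
            p = box.wrap(pts + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))
        else:
            p = pts.copy()
        try:
            verts, cells = _periodic_voronoi(p, box)
            state = VMState(vertices=verts, cells=cells, box=box, params=params)
            if state.edge_lengths().min() < 1e-9:
                raise InvalidGeometryError("near-cocircular seeds: zero-length edge")
            state.validate()
            return state
        except InvalidGeometryError as exc:
            if attempt == max_retries - 1:
                raise
            warnings.warn(f"tessellation degenerate ({exc}); re-perturbing with seed {seed + attempt + 1}")
    raise NumericalError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# energy and forces
# ---------------------------------------------------------------------------


def energy(state: VMState) -> float:
    """Σ_i K_A (A_i − A0)² + K_P (P_i − P0)²; zero only at target shape."""
    p = state.params
    areas, perims = state.areas_perimeters()
    return float(np.sum(p.K_A * (areas - p.A0) ** 2 + p.K_P * (perims - p.P0) ** 2))


def forces(state: VMState) -> np.ndarray:
    """Analytic −∂E/∂r per vertex (reported for frozen vertices too)."""
    p = state.params
    fl = state.flat()
    seg, u = state._segments()
    un = u + seg                       # next vertex, unwrapped
    up = u - seg[fl["prev"]]           # previous vertex, unwrapped
    cross = u[:, 0] * un[:, 1] - un[:, 0] * u[:, 1]
    areas = 0.5 * np.add.reduceat(cross, fl["starts"])
    lens_seg = np.sqrt(np.sum(seg * seg, axis=1))
    perims = np.add.reduceat(lens_seg, fl["starts"])

    # per flat entry: dA/dr_v = 0.5·(y_next − y_prev, x_prev − x_next)
    dA = 0.5 * np.column_stack([un[:, 1] - up[:, 1], up[:, 0] - un[:, 0]])
    unit_next = seg / lens_seg[:, None]                    # (v -> next)/|.|
    unit_prev = seg[fl["prev"]] / lens_seg[fl["prev"]][:, None]  # (prev -> v)/|.|
    dP = unit_prev - unit_next

    coefA = 2.0 * p.K_A * (areas - p.A0)
    coefP = 2.0 * p.K_P * (perims - p.P0)
    grad = coefA[fl["cell_of"]][:, None] * dA + coefP[fl["cell_of"]][:, None] * dP

    out = np.zeros_like(state.vertices)
    np.add.at(out, fl["fv"], -grad)
    return out


def step_brownian(state: VMState, rng: np.random.Generator) -> None:
    """One overdamped Euler–Maruyama step at temperature T (in place).

    Only mobile vertices move.  If the deterministic drift would move any
    vertex more than 0.1·l_t1, the step is carried out in halved substeps
    (with a warning); the thermal kick is applied at the amplitude set by
    each substep.
    """
    p = state.params
    limit = 0.1 * p.t1_threshold
    remaining = p.dt
    first = True
    while remaining > 1e-15:
        f = forces(state)
        drift_max = float(np.max(np.abs(f[state.mobile_mask]))) / p.gamma if state.mobile_mask.any() else 0.0
        dt_sub = remaining
        if drift_max * dt_sub > limit:
            # halve until the drift obeys the limit, but never below dt/1024
            # (a hard floor so pathological thresholds cannot stall the run)
            dt_sub = max(limit / drift_max, p.dt / 1024.0)
            if first:
                warnings.warn(
                    f"drift {drift_max * remaining:.3g} exceeds 0.1·l_t1; substepping", stacklevel=2
                )
        noise = math.sqrt(2.0 * p.T * dt_sub / p.gamma) * rng.standard_normal(state.vertices.shape)
        move = (dt_sub / p.gamma) * f + noise
        state.vertices[state.mobile_mask] += move[state.mobile_mask]
        state.vertices = state.box.wrap(state.vertices)
        remaining -= dt_sub
        first = False


# ---------------------------------------------------------------------------
# T1 topology changes
# ---------------------------------------------------------------------------


def _third_cell(state: VMState, vertex: int, exclude: tuple[int, int]) -> int | None:
    for ci, cyc in enumerate(state.cells):
        if ci not in exclude and vertex in cyc:
            return ci
    return None


def t1_transition(state: VMState, v1: int, v2: int) -> bool:
    """Attempt a T1 edge flip on edge (v1, v2); returns True on success.

    The edge is rotated 90° about its midpoint and reconnected so the two
    cells that shared it separate and the two cells that met it only at an
    endpoint join; the new edge length is 1.02·l_t1 to avoid an immediate
    re-flip.  Rejected (returns False) when an endpoint is frozen, a losing
    cell is a triangle, the gaining cells already touch along an edge, or
    the local neighborhood is too entangled to reconnect cleanly.
    """
    if not (state.mobile_mask[v1] and state.mobile_mask[v2]):
        return False
    fl = state.flat()
    # locate the two cells sharing the edge and the orientation of traversal
    cell_a = cell_b = None
    for ci, cyc in enumerate(state.cells):
        k = len(cyc)
        for j in range(k):
            if cyc[j] == v1 and cyc[(j + 1) % k] == v2:
                cell_a = ci
            elif cyc[j] == v2 and cyc[(j + 1) % k] == v1:
                cell_b = ci
    if cell_a is None or cell_b is None:
        return False
    if len(state.cells[cell_a]) <= 3 or len(state.cells[cell_b]) <= 3:
        return False
    cell_c = _third_cell(state, v1, (cell_a, cell_b))
    cell_d = _third_cell(state, v2, (cell_a, cell_b))
    if cell_c is None or cell_d is None or cell_c == cell_d:
        return False
    if v2 in state.cells[cell_c] or v1 in state.cells[cell_d]:
        return False  # would create a doubled edge

    pos = state.vertices
    box = state.box
    dvec = box.min_image(pos[v2] - pos[v1])
    mid = pos[v1] + 0.5 * dvec
    norm = np.linalg.norm(dvec)
    if norm == 0:
        return False
    u = dvec / norm
    # cells are CCW, so the left normal of v1->v2 points into cell_a
    # (the cell traversing the edge as v1->v2); v1 keeps cell_a after the flip
    perp = np.array([-u[1], u[0]])
    half = 0.5 * 1.02 * state.params.t1_threshold

    new_v1 = box.wrap(mid + half * perp)
    new_v2 = box.wrap(mid - half * perp)

    cells = state.cells
    # a loses v2, b loses v1
    cells[cell_a] = [v for v in cells[cell_a] if v != v2]
    cells[cell_b] = [v for v in cells[cell_b] if v != v1]
    # c gains v2 inserted before v1; d gains v1 inserted before v2
    cyc_c = cells[cell_c]
    cyc_c.insert(cyc_c.index(v1), v2)
    cyc_d = cells[cell_d]
    cyc_d.insert(cyc_d.index(v2), v1)

    state.vertices[v1] = new_v1
    state.vertices[v2] = new_v2
    state.invalidate()
    return True


def t1_sweep(state: VMState, rng: np.random.Generator) -> int:
    """Attempt a T1 on every sub-threshold, fully mobile edge (random order)."""
    flips = 0
    fl = state.flat()
    lens = state.edge_lengths()
    mobile = state.mobile_mask[fl["edge_v1"]] & state.mobile_mask[fl["edge_v2"]]
    candidates = np.nonzero((lens < state.params.t1_threshold) & mobile)[0]
    if candidates.size == 0:
        return 0
    pairs = list(zip(fl["edge_v1"][candidates], fl["edge_v2"][candidates]))
    for i in rng.permutation(len(pairs)):
        v1, v2 = int(pairs[i][0]), int(pairs[i][1])
        d = state.box.min_image(state.vertices[v2] - state.vertices[v1])
        if np.linalg.norm(d) >= state.params.t1_threshold:
            continue  # a previous flip moved it out of range
        if t1_transition(state, v1, v2):
            flips += 1
    return flips


# ---------------------------------------------------------------------------
# time evolution
# ---------------------------------------------------------------------------


def run(
    state: VMState,
    n_steps: int,
    snapshot_stride: int = 50,
    seed: int = 0,
    validate_every: int = 500,
    store_final_state: bool = True,
) -> VMTrajectory:
    """Advance the tissue: Brownian step + T1 sweep per step; snapshot the
    centroids and cell outlines every ``snapshot_stride`` steps.

    Deterministic given the seed.  Topology invariants are re-asserted every
    ``validate_every`` steps and after every snapshot; a violation aborts
    with the offending state attached.
    """
    state = state.copy()
    rng = np.random.default_rng(seed)
    cents: list[np.ndarray] = [state.cell_centroids()]
    polys: list[dict[int, np.ndarray]] = [state.cell_polygons()]
    times = [0.0]
    t1_log: list[tuple[int, int, int]] = []
    for step in range(1, n_steps + 1):
        step_brownian(state, rng)
        flips = t1_sweep(state, rng)
        if flips:
            t1_log.append((step, flips, state.n_cells))
        if step % validate_every == 0 or step == n_steps:
            try:
                state.validate()
            except InvalidGeometryError as exc:
                exc.state = state  # type: ignore[attr-defined]
                raise
        if step % snapshot_stride == 0:
            cents.append(state.cell_centroids())
            polys.append(state.cell_polygons())
            times.append(step * state.params.dt)
    return VMTrajectory(
        times=np.asarray(times),
        centroids=np.asarray(cents),
        polygons=PolygonEnsemble(frames=polys),
        dt_snapshot=snapshot_stride * state.params.dt,
        box=state.box,
        t1_events=t1_log,
        final_state=state if store_final_state else None,
    )


# ---------------------------------------------------------------------------
# frozen-cluster protocol
# ---------------------------------------------------------------------------


def cell_adjacency(state: VMState) -> dict[int, set[int]]:
    fl = state.flat()
    adj: dict[int, set[int]] = {i: set() for i in range(state.n_cells)}
    for c1, c2 in zip(fl["edge_cell1"], fl["edge_cell2"]):
        adj[int(c1)].add(int(c2))
        adj[int(c2)].add(int(c1))
    return adj


def freeze_exterior(state: VMState, n: int, center: np.ndarray | None = None) -> VMState:
    """Freeze all but a compact cluster of n cells.

    The cluster grows breadth-first over cell adjacency from the cell whose
    centroid is nearest the box center (ties by cell_id).  A vertex is
    mobile iff *all* its incident cells are in the cluster, so n = 1 leaves
    zero mobile vertices and the lone interior cell cannot deform.
    """
    if not 1 <= n <= state.n_cells:
        raise ParameterDomainError(f"n must be in [1, {state.n_cells}]")
    new = state.copy()
    cents = new.cell_centroids()
    target = 0.5 * new.box.lengths if center is None else np.asarray(center, float)
    d = np.sum(new.box.min_image(cents - target) ** 2, axis=1)
    start = int(np.lexsort((np.arange(new.n_cells), d))[0])

    adj = cell_adjacency(new)
    cluster: set[int] = {start}
    frontier = [start]
    while len(cluster) < n and frontier:
        nxt: list[int] = []
        for c in frontier:
            for nb in sorted(adj[c]):
                if nb not in cluster:
                    cluster.add(nb)
                    nxt.append(nb)
                    if len(cluster) == n:
                        break
            if len(cluster) == n:
                break
        frontier = nxt
    # vertex mobile iff every incident cell is in the cluster
    incident_out = np.zeros(new.n_vertices, dtype=bool)
    for ci, cyc in enumerate(new.cells):
        if ci not in cluster:
            incident_out[cyc] = True
    new.mobile_mask = ~incident_out
    new.mobile_cells = cluster
    return new


def frozen_cluster_experiment(
    n_values: list[int],
    T_values: list[float],
    seeds: list[int],
    n_cells: int = 100,
    p0: float = 3.72,
    equil_steps: int = 4000,
    prod_steps: int = 6000,
    sample_stride: int = 50,
    disorder: float = 0.3,
    quench_steps: int = 1500,
) -> "pd.DataFrame":  # noqa: F821
    """Frozen-cluster protocol: equilibrate, freeze all but n cells, measure
    the aspect-ratio statistics of the mobile cluster over production.

    Equilibration first relaxes the disordered initial tiling to its
    inherent structure by a T = 0 gradient quench (``quench_steps``), then
    thermalizes at the target T — without the quench a low-T tissue keeps
    the elongation frozen in by the initial disorder instead of reaching
    its near-hexagonal equilibrium.

    Returns one row per (T, n).  AR̄ and SD(AR) are computed within each
    run over the mobile cells and production snapshots (so a single mobile
    cell with every vertex frozen gives SD = 0 exactly for every seed) and
    then averaged across seeds.  Equilibration is a fixed step budget (a
    cap standing in for ≥10·τ_α when relaxation is censored at low T).
    """
    import pandas as pd

    from .shape_stats import aspect_ratio

    rows = []
    for T in T_values:
        per_seed: dict[int, list[tuple[float, float, int]]] = {n: [] for n in n_values}
        for seed in seeds:
            params = VMParams(T=T, p0=p0)
            state = init_tissue(
                n_cells, seed=seed, params=VMParams(T=0.0, p0=p0), disorder=disorder
            )
            if quench_steps:
                state = run(state, quench_steps, snapshot_stride=quench_steps,
                            seed=seed * 6011 + 3).final_state
            state.params = params
            eq = run(state, equil_steps, snapshot_stride=equil_steps, seed=seed * 7919 + 1)
            base = eq.final_state
            for n in n_values:
                frozen = freeze_exterior(base, n)
                prod = run(frozen, prod_steps, snapshot_stride=sample_stride, seed=seed * 104729 + n)
                ars = np.asarray([
                    aspect_ratio(frame[c], check_simple=False)
                    for frame in prod.polygons.frames[1:]
                    for c in sorted(frozen.mobile_cells)
                ])
                # shifted-data SD: exact (0) for a constant series, better
                # conditioned in general
                per_seed[n].append(
                    (float(ars.mean()), float(np.std(ars - ars[0], ddof=0)), ars.size)
                )
        for n in n_values:
            runs = per_seed[n]
            sds = np.array([r[1] for r in runs])
            rows.append({
                "n": n, "T": T,
                "mean_ar": float(np.mean([r[0] for r in runs])),
                "sd_ar": float(sds.mean()),
                # between-seed standard error of the SD estimate
                "sd_ar_se": float(sds.std(ddof=1) / math.sqrt(len(sds))) if len(sds) > 1 else 0.0,
                "n_samples": int(sum(r[2] for r in runs)),
                "n_runs": len(runs),
            })
    return pd.DataFrame(rows)
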