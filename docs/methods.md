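# Methods

## Aspect ratio of a polygonal cell

The aspect ratio of an outline is `AR = sqrt(λ_max/λ_min)` of the
area-weighted second-moment (covariance) tensor of the polygon interior
about its centroid — the best-fit-ellipse convention of the
shape-variability literature.  All moments come from the closed-form
shoelace expressions, so the estimator is exact for the polygon (no
rasterization) and invariant under rotation, translation, uniform scaling
and traversal orientation.  Degenerate outlines (< 3 vertices, zero area,
self-intersection) raise typed errors; simplicity checking goes through
shapely and can be disabled in hot loops where the polygons come from a
validated tiling.

## The two shape laws and their fits

**k-gamma.**  `P(x,k) = k^k/Γ(k)·x^(k−1)e^(−kx)` on the rescaled variable
`x = (AR−1)/(AR̄−1)`; mean fixed at 1, variance `1/k`.  The fit
renormalizes the sample to unit mean, after which the MLE reduces to the
monotone scalar equation `log k − ψ(k) = −mean(log x)`, solved by Brent
bracketing on `k ∈ [1e−3, 1e3]`.  Values `x = 0` carry no likelihood
information for `k > 1` and are dropped with their count reported.

**Mean-field aspect-ratio law.**
`P(AR) ∝ (AR+1/AR)^{3/2}(1−1/AR²)·e^{−α(AR+1/AR)}` on `AR ∈ [1, ∞)`.  All
densities are evaluated in a shifted parameterization with the exponent
measured from its minimum at `AR = 1` (`w − 2`, `w = AR + 1/AR`), so
normalizations stay representable at any α (the naive form underflows near
α ≈ 400).  Normalization and moments use adaptive quadrature
(`epsabs 1e−12`) with the upper limit set by an analytic tail-mass bound
(`(2AR)^{3/2}e^{−α(AR−2)}` tail below 1e−11 of a norm lower bound,
compared in logs).  The MLE for α is moment matching in `w`:
`E_α[w] = mean(w_i)`, strictly decreasing in α, solved by bracketing in
`log α`.  Sampling is by rejection with a shifted-gamma envelope on
`AR − 1` (shape 2 — the target vanishes linearly at AR = 1 — and rate
0.9α, strictly heavier-tailed than the target); the bound is taken 1.1×
the maximal likelihood ratio on a dense grid and re-tightened if exceeded,
with the acceptance rate reported.

**Universal line.**  `(AR̄(α), SD(α))` computed on a log-spaced grid of 800
α values spanning AR̄ ≈ 1.1–2.7, restricted to AR̄ ∈ [1.15, 2.5] and fitted
by unweighted least squares.  The default grid keeps consecutive AR̄ gaps
under 0.02 even when halved; slope and intercept move by < 0.01 under
halving or doubling of the density.  With these defaults the line is
`SD = 0.714·AR̄ − 0.749`.  The fit window matches the span over which the
empirical scaling is reported; the printed coefficients shift by a few
percent if the window is widened, which is why the window is an explicit
argument and recorded in the result.

**Collapse score.**  Rescaled PDFs are histogrammed on 40 equal-width bins
over `x ∈ [0, 5]`, density-normalized; the score is the mean pairwise L1
distance `∫|p_i − p_j|dx` (0 for a single sample by convention).

**Deviation from the line.**  `assess_scaling_deviation` reports the signed
residuals of (AR̄, SD) points about a fitted line, their mean and standard
error, and a one-sided one-sample t-test (α-level 0.05) of whether the set
lies below the line.  This stands in for a regression-based error analysis
whose exact form is not fixed by the data it emulates; it is the natural
first choice and is labelled as such.

## Dynamics observables

Trajectories are (frames × cells × 2) arrays with a time step and either a
periodic rectangle or a circular wall.  Periodic displacements are
unwrapped by accumulating per-step minimum-image differences, which assumes
no cell moves more than half a box length between frames.

- **MSD**: time-origin averaged over all full windows.
- **τ_p**: local log-log slope of the MSD by centered differences on a
  log-spaced subset of lags with 3-point smoothing; τ_p is the first
  crossing of slope 1.5 after the ballistic maximum (interpolated in log
  time).  Preconditions — early slope ≥ 1.8, late slope ≤ 1.2 — otherwise a
  no-crossover error is raised rather than guessing.  The early-lag speed
  estimate gives `l_p = v̄·τ_p`.  For an active Brownian particle the exact
  MSD `2v²τ²[t/τ + e^{−t/τ} − 1]` crosses slope 1.5 at `t ≈ 2.15/D_r`; the
  tests assert against that closed form rather than `1/D_r`.
- **F_s(q,t)**: isotropic 2D average `⟨J₀(q·|Δr|)⟩` over cells and origins;
  `F_s(q,0) = 1` exactly.  q defaults to `2π/σ̄` with σ̄ the mean cell
  diameter (the glass-physics convention) and is exposed everywhere.
- **τ_α**: first crossing of 1/e, linearly interpolated between bracketing
  lags; a non-crossing curve returns a censored flag with the maximum lag
  as a lower bound — censoring is a valid result, not an error.
- **t\***: lag of the maximum of the 2D non-Gaussian parameter
  `α₂ = ⟨Δr⁴⟩/(2⟨Δr²⟩²) − 1`.  A peak on the boundary of the lag range or
  below 0.05 (the noise floor for well-sampled Gaussian data) is flagged:
  the heterogeneity maximum is unresolved.  A selectable alternative peaks
  the four-point susceptibility `χ₄(t) = N·Var_{t₀}[Q(t₀,t)]` of the
  self-overlap (cutoff default 0.3 mean cell diameters).
- **Circular-wall data**: an opt-in filter drops cells that ever approach
  a circular wall within one mean cell diameter, for checking that the
  confinement boundary does not drive a result; off by default.
- **Mobility subsets**: per-cell displacement magnitude at lag t*,
  time-origin averaged; top/bottom quantile (default 10%), ties broken by
  cell id.  A second estimator re-identifies the subsets *per
  half-overlapping t\*-window* and pools shapes within windows
  (`windowed_mobility_shape_stats`); this per-time-origin variant preserves
  the fast/slow contrast when mobility identities decay on the t* scale
  and is what the heterogeneity pipeline uses.
- **Voronoi**: periodic tessellations use 3×3 image copies and keep the
  central cells (areas then sum to the box area to 1e−6); circular domains
  mirror points across the wall and clip regions to the disk.  Neighbor
  clustering of a subset is union-find over shared-Voronoi-edge adjacency.

## Vertex model

Degree-3 polygonal tiling of the torus; invariants (two cells per edge,
Euler characteristic 0, positive simple cells, areas summing to the box)
are asserted at init, every 500 steps during runs and after every T1 sweep
in tests.  Energy `E = Σ K_A(A_i − A0)² + K_P(P_i − P0)²` with
`K_A = K_P = A0 = 1` and target shape index `p0 = P0/√A0` defaulting to
3.72 (just below the regular-hexagon value 2√(2√3) ≈ 3.7224: a mildly
frustrated, solid-leaning tissue).  Forces are the analytic shoelace/
perimeter gradients, vectorized over a flattened cycle representation;
they match central finite differences to < 1e−5 relative error and sum to
zero by translation invariance.

Dynamics: overdamped Euler–Maruyama at temperature T (energy units),
friction γ = 1, dt = 0.01.  If the deterministic drift would move a vertex
more than `0.1·l_t1` in one step, the step is subdivided (with a warning
and a hard floor of dt/1024 so a pathological threshold cannot stall the
integrator); the thermal kick always enters at the amplitude of the
substep actually taken.

Topology: a T1 flip fires on edges shorter than `l_t1 = 0.04·√A0` whose
endpoints are both mobile.  The edge is rotated 90° about its midpoint
(CCW orientation fixes which endpoint stays with which cell), reconnected
so the two cells that shared it separate and the two endpoint-cells join,
and given length `1.02·l_t1` to prevent an immediate re-flip.  Flips that
would create a two-sided cell, a doubled edge, or involve a frozen vertex
are rejected.  Each step performs one sweep over eligible edges in an
order randomized from the run's seed stream; runs are bit-reproducible
given the seed.

Initialization is a periodic Voronoi tessellation of a perturbed
triangular lattice (disorder 0.3 lattice spacings by default), constructed
from a 3×3-tiled Delaunay triangulation by keeping the unique triangle
representative whose circumcenter falls in the central box — this yields
the exact torus topology with 2N vertices for N cells.  A fixed irrational
sub-lattice offset keeps circumcenters off the box boundary so the
disorder-0 limit is an exact regular hexagonal tiling.  Cocircular
degeneracies re-perturb with an incremented seed and a logged warning.

**Frozen-cluster protocol.**  The mobile cluster grows breadth-first over
cell adjacency from the cell nearest the box center (ties by id); a vertex
is mobile iff *all* its incident cells are in the cluster — the only rule
under which a single unfrozen cell (n = 1) has zero mobile vertices and
hence exactly zero shape variability.  AR̄ and SD(AR) of the cluster are
computed within each run (cells × production snapshots) and averaged
across seeds, with the between-seed standard error reported; the SD uses
the shifted-data variance formula so a constant series gives exactly 0.

**Equilibration.**  Runs quench to the inherent structure first (T = 0
gradient descent, 1500 steps) and then thermalize at the target T.  At low
T the thermal dynamics alone cannot anneal the initial disorder on any
affordable horizon (the tissue would keep a frozen-in AR̄ ≈ 1.2 at
T = 0.005), and the quench-then-thermalize protocol is the standard
substitute for equilibrating "many τ_α" in a glassy regime.  Equilibration
and production budgets are fixed step counts, stated with every result.

## Synthetic generators

Each motile cell-mimic is coarse-grained to a single chiral active
Brownian particle: heading `θ ← θ + ω·dt + sqrt(2 D_r dt)·η`, position
advanced at speed v0 along the heading, optional translational noise,
non-interacting (the dilute regime in which single-cell motility is
characterized).  The interior chirality maps linearly to the angular
drift, `ω = ω_max·χ_cell` with D_r fixed (`ω_max = 1`, `D_r = 0.05`), so
the velocity autocorrelation `v₀²e^{−D_r t}cos ωt` — and hence τ_p —
decreases monotonically with |χ_cell|, spanning roughly a decade between
the racemic (χ = 0, τ_p ≈ 40 time units) and enantiopure (|χ| = 1) limits.
Ensembles split handedness so the assembly chirality is exactly the
requested χ_Sys (racemic default; even cell count enforced).  Per-cell
seed streams are spawned from one SeedSequence, so everything is
reproducible and cells are independent.

Polygon fixtures: an n-gon sampled at uniform parametric angles of an
ellipse is the affine image of a regular n-gon, so its second-moment AR
equals the axis ratio exactly; `polygons_with_ar` therefore sets the axis
ratio to the requested AR directly (verified to 1e−3 and better in tests),
applies a random rotation per polygon and spaces the cells on a grid.

What the generators deliberately do *not* model: the granular interior of
real cell-mimics (wall currents of chiral ellipsoids), membrane
elasticity, inter-cell contact mechanics, and any density-driven physics.
Tests passing on these generators validate the estimators and the
simulation machinery, not claims about granular hardware.

## Problem sizes and what the desk-scale runs show

All simulation-backed checks run on one CPU core in minutes; the sizes are
the package's reference conditions and are printed with every result:

- universal line: 800-point α grid (seconds, deterministic);
- parameter recovery: 5×10⁴ draws;
- dynamics oracles: 500–1000 particles, 400–5000 frames;
- thermal tissue sweep: 64 cells, T ∈ {0.002, 0.005, 0.009, 0.02}, two
  seeds, quench 1500 + equilibrate 4000 + produce 4000 steps;
- frozen-cluster: 100 cells, n ∈ {1, 2, 4, 8, 12, 16},
  T ∈ {0.005, 0.02}, three seeds, quench 1500 + equilibrate 6000 +
  produce 6000 steps;
- mobility subsets: 100 cells at p0 = 3.85, T = 0.015, three seeds,
  40 000 production steps, subsets re-identified per t*-window.

At these sizes the package reproduces: the universal-line coefficients;
monotone growth of AR̄ and SD with temperature, tracking the line within
±0.05; SD(AR) = 0 exactly at n = 1, rising with cluster size and
approaching the line from below, with the small-cluster deviation larger
at high T than at low T and the on-line onset by n ≈ 4–8; fast subsets
more elongated than slow ones and significantly below the universal line,
with slow subsets inside the same ±0.05 band.

Two things the desk scale does **not** resolve, stated plainly: (i) the
*difference* between fast- and slow-subset residuals is within seed noise
(±0.005) at every operating point we examined (p0 3.72–3.90 × T
0.002–0.02, windows 10–400 frames) — the bulk tissue at the reference
conditions itself sits ≈ 0.01 below the line, and both subsets inherit
that offset; resolving the subset split cleanly appears to need much
deeper supercooling, larger systems and longer runs than a single-core
budget allows.  The confinement mechanism behind the fast-cell suppression
is instead demonstrated directly and cleanly by the frozen-cluster
protocol.  (ii) SD(AR) vs n saturates at the bulk value, where seed noise
breaks strict monotonicity; the monotonicity check is therefore stated as
non-decrease within three combined between-seed standard errors, with the
rise out of full confinement (n = 1 → 2 → 4) required strictly.

## Known limitations

- The Euler–Maruyama integrator is first order; dt = 0.01 with the
  drift-substepping safeguard is adequate for the temperatures used here
  but not validated for T ≫ 0.02.
- The frozen-cluster equilibration uses a fixed step budget rather than a
  measured multiple of τ_α (which is censored at low T); budgets are part
  of the reported conditions.
- `n_cells` must factor as nx × ny with ny even (periodic triangular
  lattice); arbitrary counts are rejected at init.
- The mean-field fit requires all aspect ratios strictly above 1; exact
  circles are a measure-zero degenerate input for that law.
- Voronoi tessellation on circular domains relies on mirror points for
  wall-bounded regions; areas near the wall are accurate to ~1% of the
  disk area, not exact as in the periodic case.
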