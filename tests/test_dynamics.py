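"""Glassy-dynamics observables: MSD, crossover, F_s, relaxation/cage times,
mobility subsets and Voronoi geometry."""

import math
import warnings

import numpy as np
import pytest

from shapejam import dynamics as dy
from shapejam import synthetic as sy
from shapejam.dynamics import Box, Trajectory
from shapejam.exceptions import (
    CoverageError,
    InputError,
    InvalidGeometryError,
    NoCrossoverError,
    ParameterDomainError,
)
from shapejam.shape_stats import PolygonEnsemble


def brownian_traj(D=0.25, n=500, frames=400, dt=0.05, L=50.0, seed=11):
    p = sy.ChiralCellParams(v0=0.0, omega=0.0, D_r=0.0, D_t=D)
    traj, _ = sy.chiral_abp_trajectory(p, n, frames, dt, Box.periodic(L), seed=seed)
    return traj


def rotate_traj(traj: Trajectory, angle: float, shift=(3.0, -7.0)) -> Trajectory:
    rot = np.array([[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]])
    pos = traj.unwrapped() @ rot.T + np.asarray(shift)
    big = Box.periodic(10 * (np.abs(pos).max() + 1))
    return Trajectory(big.wrap(pos), dt=traj.dt, box=big)


class TestMSD:
    def test_uniform_translation_is_exactly_ballistic(self):
        t = np.arange(50)[:, None, None]
        pos = np.tile(np.array([[1.0, 2.0]]), (50, 10, 1)) + 0.3 * t * np.array([1.0, 0.0])
        traj = Trajectory(pos, dt=0.5, box=Box.periodic(1e6))
        times, m = dy.msd(traj, max_lag=30)
        assert np.allclose(m, (0.3 / 0.5) ** 2 * times**2)

    def test_frozen_particles_have_zero_msd(self):
        pos = np.tile(np.random.default_rng(0).uniform(0, 10, (1, 20, 2)), (40, 1, 1))
        traj = Trajectory(pos, dt=1.0, box=Box.periodic(10.0))
        _, m = dy.msd(traj, max_lag=20)
        assert np.all(m == 0.0)

    def test_brownian_msd_matches_4dt(self):
        D = 0.25
        traj = brownian_traj(D=D)
        t, m = dy.msd(traj, max_lag=150)
        assert np.all(np.abs(m / (4 * D * t) - 1) < 0.05)

    def test_periodic_unwrapping_crosses_boundaries(self):
        # steady drift across a small periodic box: unwrapped MSD stays ballistic
        t = np.arange(200)[:, None, None]
        pos = np.mod(0.4 * t * np.array([1.0, 1.0]) + 2.0, 5.0) * np.ones((1, 3, 1))
        traj = Trajectory(pos, dt=1.0, box=Box.periodic(5.0))
        times, m = dy.msd(traj, max_lag=50)
        assert np.allclose(m, 2 * (0.4 * times) ** 2)

    def test_invariant_under_rigid_motion(self):
        traj = brownian_traj(n=50, frames=100)
        t1, m1 = dy.msd(traj, max_lag=40)
        t2, m2 = dy.msd(rotate_traj(traj, 0.7), max_lag=40)
        assert np.allclose(m1, m2, rtol=1e-9)

    def test_bad_lag_rejected(self):
        traj = brownian_traj(n=6, frames=20)
        with pytest.raises(InputError):
            dy.msd(traj, max_lag=25)


class TestPersistenceTime:
    def test_matches_abp_crossover_oracle(self):
        # exact slope-1.5 crossing of MSD = 2 v^2 tau^2 [t/tau + e^{-t/tau} - 1]
        # happens at t = x*/D_r with x* solving x(1-e^{-x})/(x+e^{-x}-1) = 3/2
        from scipy import optimize

        x_star = optimize.brentq(
            lambda x: x * (1 - math.exp(-x)) / (x + math.exp(-x) - 1) - 1.5, 0.1, 10
        )
        d_r = 0.05
        p = sy.ChiralCellParams(v0=1.0, omega=0.0, D_r=d_r)
        traj, _ = sy.chiral_abp_trajectory(p, 200, 6000, 0.08, Box.periodic(300.0), seed=5)
        t, m = dy.msd(traj, lags=np.unique(np.geomspace(1, 4000, 80).astype(int)))
        res = dy.persistence_time(t, m)
        assert res.tau_p == pytest.approx(x_star / d_r, rel=0.3)
        assert res.v == pytest.approx(1.0, rel=0.1)
        assert res.l_p == pytest.approx(res.v * res.tau_p)

    def test_purely_ballistic_input_has_no_crossover(self):
        t = np.geomspace(0.1, 100, 60)
        with pytest.raises(NoCrossoverError):
            dy.persistence_time(t, (2.0 * t) ** 2)

    def test_purely_diffusive_input_has_no_crossover(self):
        t = np.geomspace(0.1, 100, 60)
        with pytest.raises(NoCrossoverError):
            dy.persistence_time(t, 4 * 0.5 * t)

    def test_tau_p_decreases_with_angular_drift(self):
        taus = []
        for om in (0.0, 0.15, 0.4, 0.8, 1.2):
            p = sy.ChiralCellParams(v0=1.0, omega=om, D_r=0.05)
            traj, _ = sy.chiral_abp_trajectory(p, 150, 5000, 0.08, Box.periodic(300.0), seed=6)
            t, m = dy.msd(traj, lags=np.unique(np.geomspace(1, 3500, 70).astype(int)))
            taus.append(dy.persistence_time(t, m).tau_p)
        assert all(a > b for a, b in zip(taus, taus[1:]))


class TestSelfIntermediateScattering:
    def test_frozen_particles_stay_at_unity(self):
        pos = np.tile(np.random.default_rng(1).uniform(0, 10, (1, 30, 2)), (50, 1, 1))
        traj = Trajectory(pos, dt=1.0, box=Box.periodic(10.0))
        times, fs = dy.self_intermediate_scattering(traj, q=2.0, max_lag=30)
        assert np.all(fs == 1.0)

    def test_zero_lag_is_exactly_one_and_bounds_hold(self):
        traj = brownian_traj(n=100, frames=200)
        _, fs = dy.self_intermediate_scattering(traj, q=3.0, max_lag=100)
        assert fs[0] == 1.0
        assert np.all(fs <= 1.0) and np.all(fs >= -0.4028)

    def test_brownian_gaussian_closed_form(self):
        D, q = 0.25, 1.0
        traj = brownian_traj(D=D)
        times, fs = dy.self_intermediate_scattering(traj, q, max_lag=200)
        assert np.max(np.abs(fs - np.exp(-q * q * D * times))) < 0.02

    def test_invalid_q_rejected(self):
        traj = brownian_traj(n=6, frames=10)
        with pytest.raises(ParameterDomainError):
            dy.self_intermediate_scattering(traj, q=0.0, max_lag=5)


class TestRelaxationTime:
    def test_exponential_curve_recovers_tau(self):
        t = np.linspace(0, 10, 100)
        tau, censored, _ = dy.relaxation_time(t, np.exp(-t / 2.5))
        assert not censored
        assert tau == pytest.approx(2.5, rel=0.01)

    def test_non_crossing_curve_is_censored_with_bound(self):
        t = np.linspace(0, 5, 50)
        tau, censored, bound = dy.relaxation_time(t, 1.0 - 0.05 * t / 5)
        assert censored and tau is None and bound == 5.0

    def test_brownian_tau_alpha_closed_form(self):
        D, q = 0.25, 1.0
        traj = brownian_traj(D=D)
        times, fs = dy.self_intermediate_scattering(traj, q, max_lag=200)
        tau, censored, _ = dy.relaxation_time(times, fs)
        assert not censored
        assert tau == pytest.approx(1.0 / (q * q * D), rel=0.05)


def mixture_traj(seed=3, frames=600, n_slow=180, n_fast=20, d_slow=0.01, d_fast=0.1, dt=0.1):
    rng = np.random.default_rng(seed)
    slow = np.cumsum(np.sqrt(2 * d_slow * dt) * rng.standard_normal((frames, n_slow, 2)), axis=0)
    fast = np.cumsum(np.sqrt(2 * d_fast * dt) * rng.standard_normal((frames, n_fast, 2)), axis=0)
    pos = np.concatenate([slow, fast], axis=1) + 100.0
    return Trajectory(pos, dt=dt, box=Box.periodic(400.0))


class TestCageTimeAndSubsets:
    def test_gaussian_displacements_have_no_resolved_peak(self):
        traj = brownian_traj()  # 500 cells: alpha2 noise floor well below 0.05
        with pytest.warns(UserWarning, match="boundary|noise floor"):
            ct = dy.cage_time(traj, lags=np.arange(1, 200))
        assert ct.boundary_peak
        assert np.all(np.abs(ct.alpha2) < 0.05)

    def test_mixture_has_interior_heterogeneity_peak(self):
        traj = mixture_traj()
        ct = dy.cage_time(traj, lags=np.unique(np.geomspace(1, 500, 40).astype(int)))
        assert not ct.boundary_peak
        assert ct.alpha2.max() > 0.2

    def test_alpha2_rotation_invariant(self):
        traj = mixture_traj(frames=200)
        _, a1 = dy.non_gaussian_parameter(traj, lags=[5, 20, 50])
        _, a2 = dy.non_gaussian_parameter(rotate_traj(traj, 1.1), lags=[5, 20, 50])
        assert np.allclose(a1, a2, rtol=1e-9)

    def test_chi4_alternative_peaks_interior_on_mixture(self):
        traj = mixture_traj()
        lags = np.unique(np.geomspace(1, 500, 40).astype(int))
        ct = dy.cage_time(traj, lags=lags, method="chi4", overlap_cutoff=0.5)
        assert not ct.boundary_peak
        assert ct.alpha2.max() > 0.0
        with pytest.raises(ParameterDomainError):
            dy.cage_time(traj, lags=lags, method="bogus")

    def test_subset_sizes_and_recovery(self):
        traj = mixture_traj()
        ct = dy.cage_time(traj, lags=np.unique(np.geomspace(1, 500, 40).astype(int)))
        dh = dy.mobility_subsets(traj, ct.t_star, fraction=0.10)
        assert len(dh.fast_ids) == len(dh.slow_ids) == 20
        assert not np.intersect1d(dh.fast_ids, dh.slow_ids).size
        planted = np.arange(180, 200)
        assert np.intersect1d(dh.fast_ids, planted).size >= 16  # >= 80 %

    def test_twenty_cells_fraction_ten_percent(self):
        traj = mixture_traj(n_slow=18, n_fast=2)
        dh = dy.mobility_subsets(traj, 5.0, fraction=0.10)
        assert len(dh.fast_ids) == len(dh.slow_ids) == 2

    def test_identical_displacements_flagged_degenerate(self):
        t = np.arange(30)[:, None, None]
        pos = np.zeros((30, 10, 2)) + 0.1 * t * np.array([1.0, 0.0]) + 5.0
        traj = Trajectory(pos, dt=1.0, box=Box.periodic(1e5))
        with pytest.warns(UserWarning, match="identical"):
            dh = dy.mobility_subsets(traj, 5.0)
        assert dh.degenerate
        assert np.array_equal(dh.slow_ids, [0])  # tie-break by cell id

    def test_membership_invariant_under_uniform_scaling(self):
        traj = mixture_traj(frames=200)
        dh1 = dy.mobility_subsets(traj, 5.0)
        scaled = Trajectory(traj.positions * 3.0, dt=traj.dt, box=Box.periodic(1200.0))
        dh2 = dy.mobility_subsets(scaled, 5.0)
        assert np.array_equal(dh1.fast_ids, dh2.fast_ids)
        assert np.array_equal(dh1.slow_ids, dh2.slow_ids)

    def test_bad_fraction_rejected(self):
        traj = mixture_traj(frames=50)
        with pytest.raises(ParameterDomainError):
            dy.mobility_subsets(traj, 2.0, fraction=0.7)


class TestSubsetShapeStats:
    def _ensemble(self, ar_by_cell, frames=2):
        polys = sy.polygons_with_ar(ar_by_cell, n_vertices=24, seed=0)
        return PolygonEnsemble(frames=[polys.frames[0]] * frames)

    def test_identical_shapes_give_identical_stats(self):
        traj = mixture_traj(n_slow=18, n_fast=2, frames=50)
        dh = dy.mobility_subsets(traj, 2.0)
        polys = self._ensemble(np.full(20, 1.8))
        fast, slow = dy.subset_shape_stats(dh, polys)
        assert fast[0] == pytest.approx(slow[0], abs=1e-6)
        assert fast[1] == pytest.approx(slow[1], abs=1e-6)
        assert fast[0] == pytest.approx(1.8, abs=1e-6)

    def test_missing_cells_raise_coverage_error(self):
        traj = mixture_traj(n_slow=18, n_fast=2, frames=50)
        dh = dy.mobility_subsets(traj, 2.0)
        polys = sy.polygons_with_ar(np.full(5, 1.5), n_vertices=24, seed=0)
        with pytest.raises(CoverageError):
            dy.subset_shape_stats(dh, polys)


class TestClusterSubsets:
    def test_planted_patch_forms_one_component(self):
        rng = np.random.default_rng(2)
        grid = np.array([[i, j] for i in range(10) for j in range(10)], float) + 0.5
        pts = grid + rng.uniform(-0.05, 0.05, grid.shape)
        box = Box.periodic(10.0)
        # fast cells: a 2x5 contiguous block; slow: far corners
        fast = np.array([i * 10 + j for i in (4, 5) for j in range(3, 8)])
        slow = np.array([0, 9, 90, 99])
        dh = dy.DHResult(t_star=1.0, fast_ids=fast, slow_ids=slow, fraction=0.1,
                         displacements=np.zeros(100))
        res = dy.cluster_subsets(dh, pts, box)
        assert len(res.fast_components) == 1 and res.fast_sizes[0] == 10
        # the four corners are mutually adjacent only through the periodic wrap
        assert len(res.slow_components) == 1

    def test_distant_cells_are_singletons(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, (60, 2))
        box = Box.periodic(30.0)
        pairs = dy.voronoi_neighbors(pts, box)
        adj = {i: set() for i in range(60)}
        for a, b in pairs:
            adj[a].add(b)
            adj[b].add(a)
        # pick six pairwise non-adjacent cells
        chosen: list[int] = []
        for i in range(60):
            if all(i not in adj[c] for c in chosen):
                chosen.append(i)
            if len(chosen) == 6:
                break
        dh = dy.DHResult(t_star=1.0, fast_ids=np.array(chosen), slow_ids=np.array(chosen),
                         fraction=0.1, displacements=np.zeros(60))
        res = dy.cluster_subsets(dh, pts, box)
        assert all(len(c) == 1 for c in res.fast_components)

    def test_planted_clusters_beat_shuffled_null(self):
        rng = np.random.default_rng(4)
        grid = np.array([[i, j] for i in range(10) for j in range(10)], float) + 0.5
        pts = grid + rng.uniform(-0.05, 0.05, grid.shape)
        box = Box.periodic(10.0)
        fast = np.array([i * 10 + j for i in (2, 3) for j in range(2, 7)])
        dh = dy.DHResult(t_star=1.0, fast_ids=fast, slow_ids=fast, fraction=0.1,
                         displacements=np.zeros(100))
        observed = np.mean(dy.cluster_subsets(dh, pts, box).fast_sizes)
        null_means = []
        for _ in range(30):
            ids = rng.choice(100, size=10, replace=False)
            dh0 = dy.DHResult(t_star=1.0, fast_ids=ids, slow_ids=ids, fraction=0.1,
                              displacements=np.zeros(100))
            null_means.append(np.mean(dy.cluster_subsets(dh0, pts, box).fast_sizes))
        assert observed > np.percentile(null_means, 95)


class TestVoronoiAreas:
    def test_hexagonal_lattice_has_equal_areas(self, hexagonal_tissue):
        cents = hexagonal_tissue.cell_centroids()
        areas, _, _ = dy.voronoi_areas(cents, hexagonal_tissue.box)
        assert areas.std() < 1e-9
        assert areas.sum() == pytest.approx(hexagonal_tissue.box.area, abs=1e-6)

    def test_area_conservation_on_random_points(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 12, (80, 2))
        box = Box.periodic(12.0)
        areas, _, _ = dy.voronoi_areas(pts, box)
        assert areas.sum() == pytest.approx(box.area, abs=1e-6)

    def test_duplicate_points_rejected(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 3.0], [4.0, 2.0], [0.5, 4.0]])
        with pytest.raises(InvalidGeometryError):
            dy.voronoi_areas(pts, Box.periodic(5.0))

    def test_two_density_structure_is_bimodal(self):
        # clustered region + gas region: a two-component fit wins on BIC
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        dense = rng.uniform([0, 0], [6, 20], (150, 2))
        gas = rng.uniform([6, 0], [20, 20], (50, 2))
        pts = np.concatenate([dense, gas])
        areas, _, _ = dy.voronoi_areas(pts, Box.periodic(20.0))
        la = np.log(areas)[:, None]
        bic1 = GaussianMixture(1, random_state=0).fit(la).bic(la)
        bic2 = GaussianMixture(2, random_state=0).fit(la).bic(la)
        assert bic2 < bic1

    def test_wall_exclusion_keeps_interior_cells(self):
        rng = np.random.default_rng(9)
        r = 8.0 * np.sqrt(rng.uniform(0, 1, 100))
        ang = rng.uniform(0, 2 * math.pi, 100)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        traj = Trajectory(np.tile(pts, (5, 1, 1)), dt=1.0, box=Box.circular(8.0))
        sub, kept = dy.exclude_wall_cells(traj, margin_diameters=1.0)
        sigma = 2 * math.sqrt(traj.box.area / (math.pi * 100))
        assert np.all(np.sqrt((sub.positions**2).sum(-1)) <= 8.0 - sigma + 1e-12)
        assert 0 < kept.size < 100
        with pytest.raises(InputError):
            dy.exclude_wall_cells(brownian_traj(n=6, frames=10))

    def test_circular_wall_clipping(self):
        rng = np.random.default_rng(7)
        r = 8.0 * np.sqrt(rng.uniform(0, 1, 100))
        ang = rng.uniform(0, 2 * math.pi, 100)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        box = Box.circular(8.0)
        areas, _, _ = dy.voronoi_areas(pts, box)
        assert areas.sum() == pytest.approx(box.area, rel=0.01)


class TestWindowedSubsets:
    def test_contrast_on_planted_mixture_with_shapes(self):
        # fast planted cells carry larger AR; windowed pooling must find them
        traj = mixture_traj(frames=120)
        ar = np.concatenate([np.full(180, 1.2), np.full(20, 2.0)])
        polys = sy.polygons_with_ar(ar, n_vertices=24, seed=1)
        ens = PolygonEnsemble(frames=[polys.frames[0]] * traj.n_frames)
        fast, slow, lag = dy.windowed_mobility_shape_stats(traj, ens, t_star=3.0)
        assert fast[0] > 1.7
        assert slow[0] < 1.3

    def test_frame_mismatch_rejected(self):
        traj = mixture_traj(frames=50)
        polys = sy.polygons_with_ar(np.full(200, 1.5), n_vertices=24, seed=1)
        with pytest.raises(CoverageError):
            dy.windowed_mobility_shape_stats(traj, polys, t_star=3.0)
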