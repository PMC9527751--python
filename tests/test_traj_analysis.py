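"""Trajectory analyzers against constructed and closed-form oracles."""

import math

import numpy as np
import pytest

from wallmapper.potentials import WallParams
from wallmapper import traj_analysis as ta
from wallmapper.traj_analysis import LayerDefinition


WALL = WallParams(8.2, 0.18, "tridecane")
C = ta.AMU_PER_NM3_TO_G_PER_CM3


class TestDensityProfile:
    def test_uniform_gas_is_flat(self, make_traj):
        rng = np.random.default_rng(5)
        pos = rng.random((40, 4000, 3)) * [4.0, 4.0, 2.0]
        traj = make_traj(pos, box=(4.0, 4.0))
        prof = ta.density_profile(traj, bin_width=0.1, z_range=(0.0, 2.0))
        rho = prof.densities["S"]
        expected = 4000 * 75.07 / (4.0 * 4.0 * 2.0) * C
        assert np.allclose(rho, expected, rtol=0.1)
        assert rho.std() / rho.mean() < 0.05

    def test_mass_conservation(self, make_traj):
        rng = np.random.default_rng(6)
        pos = rng.random((10, 500, 3)) * [3.0, 3.0, 2.5]
        traj = make_traj(pos, box=(3.0, 3.0))
        prof = ta.density_profile(traj, bin_width=0.033)
        total = (
            prof.densities["S"].sum() * prof.bin_width * 3.0 * 3.0 / C
        )
        assert total == pytest.approx(500 * 75.07, rel=1e-10)

    def test_translation_and_relabel_invariance(self, make_traj):
        rng = np.random.default_rng(7)
        pos = rng.random((5, 300, 3)) * [3.0, 3.0, 2.0]
        traj = make_traj(pos, box=(3.0, 3.0))
        shifted = pos.copy()
        shifted[:, :, 0] += 1.7  # rigid lateral translation
        shifted[:, :, 0] %= 3.0
        perm = rng.permutation(300)
        traj2 = make_traj(shifted[:, perm], box=(3.0, 3.0))
        p1 = ta.density_profile(traj, bin_width=0.05, z_range=(0, 2))
        p2 = ta.density_profile(traj2, bin_width=0.05, z_range=(0, 2))
        assert np.allclose(p1.densities["S"], p2.densities["S"])

    def test_empty_species_selection_rejected(self, make_traj):
        traj = make_traj(np.zeros((2, 3, 3)) + 0.5)
        with pytest.raises(ValueError):
            ta.density_profile(traj, species=["nope"])


def flat_profile(value, z_max=3.0, h=0.02):
    centers = h / 2 + h * np.arange(int(z_max / h))
    return ta.DensityProfile(
        bin_centers=centers,
        densities={"S": np.full(len(centers), float(value))},
        bin_width=h,
    )


class TestInterfacialDensity:
    def test_uniform_profile_returns_the_constant(self):
        prof = flat_profile(0.42)
        assert ta.interfacial_density(prof, WALL, "S") == pytest.approx(0.42)

    def test_piecewise_profile_hand_average(self):
        # rho = 1 below z*, 0.25 above; zone [z0, z0+1]; hand integration
        prof = flat_profile(0.0)
        z0 = WALL.zero_crossing
        zstar = z0 + 0.4
        rho = np.where(prof.bin_centers < zstar, 1.0, 0.25)
        prof.densities["S"] = rho
        expected = 0.4 * 1.0 + 0.6 * 0.25
        assert ta.interfacial_density(prof, WALL, "S") == pytest.approx(
            expected, abs=0.02
        )

    def test_zone_start_shifts_with_sigma(self):
        prof = flat_profile(0.0)
        ramp = prof.bin_centers.copy()  # rho = z
        prof.densities["S"] = ramp
        w1 = WallParams(5.0, 0.18)
        w2 = WallParams(5.0, 0.34)
        r1 = ta.interfacial_density(prof, w1, "S")
        r2 = ta.interfacial_density(prof, w2, "S")
        # mean of a unit-slope ramp over a 1 nm zone = zone midpoint
        assert r2 - r1 == pytest.approx(0.715 * (0.34 - 0.18), abs=2e-3)

    def test_zone_outside_profile_rejected(self):
        prof = flat_profile(0.3, z_max=0.5)
        with pytest.raises(ValueError, match="zone"):
            ta.interfacial_density(prof, WallParams(5.0, 0.34), "S")


class TestBulkBoundary:
    def test_constant_beyond_z0(self):
        prof = flat_profile(0.0)
        z0 = 1.0
        rho = np.where(prof.bin_centers < z0,
                       0.8 + 0.5 * (z0 - prof.bin_centers), 0.8)
        prof.densities["S"] = rho
        layer, rho_star = ta.detect_bulk_boundary(
            prof, "S", wall=WALL, smoothing_window=5, derivative_tol=0.05
        )
        assert layer.z_hi == pytest.approx(z0, abs=0.1)

    def test_damped_oscillation_boundary_from_envelope(self):
        """Boundary lands where the decaying oscillation's derivative
        envelope falls below the tolerance."""
        h = 0.02
        prof = flat_profile(0.0, z_max=6.0, h=h)
        z = prof.bin_centers
        amp, lam, k = 0.5, 0.8, 2 * np.pi / 0.4
        rho = 0.6 + amp * np.exp(-z / lam) * np.cos(k * z)
        prof.densities["S"] = rho
        tol = 0.5
        layer, _ = ta.detect_bulk_boundary(
            prof, "S", wall=None, smoothing_window=3, derivative_tol=tol
        )
        # oracle: smoothing over w bins attenuates the cosine by a known
        # factor, so the derivative envelope is A(z) = amp*k*atten*exp(-z/lam);
        # a sustained window of w bins around a derivative node fits once
        # A(z)*sin(k*w*h/2) <= tol
        w = 3
        atten = abs(np.sin(k * w * h / 2) / (w * np.sin(k * h / 2)))
        z_pred = lam * math.log(amp * k * atten * math.sin(k * w * h / 2) / tol)
        assert layer.z_hi == pytest.approx(z_pred, abs=0.25)

    def test_fully_flat_profile_boundary_at_zone_start(self):
        prof = flat_profile(0.7)
        layer, rho_star = ta.detect_bulk_boundary(prof, "S", wall=WALL)
        assert layer.z_lo == pytest.approx(WALL.zero_crossing)
        assert layer.z_hi - layer.z_lo <= 3 * prof.bin_width
        assert rho_star == pytest.approx(0.7)

    def test_no_plateau_rejected(self):
        prof = flat_profile(0.0, z_max=2.0)
        prof.densities["S"] = prof.bin_centers ** 2  # ever-growing slope
        with pytest.raises(ValueError, match="plateau"):
            ta.detect_bulk_boundary(prof, "S", derivative_tol=1e-4)


def dumbbell_frames(directions, z_centers, n_frames=3, box=(6.0, 6.0)):
    """Build a trajectory of static dumbbells with given bond directions."""
    directions = np.asarray(directions, float)
    n = len(directions)
    pos = np.zeros((n_frames, 2 * n, 3))
    for i, (d, zc) in enumerate(zip(directions, z_centers)):
        d = d / np.linalg.norm(d)
        center = np.array([1.0 + 0.5 * i % 5.0, 2.0, zc])
        pos[:, 2 * i] = center - 0.075 * d
        pos[:, 2 * i + 1] = center + 0.075 * d
    bonds = [(2 * i, 2 * i + 1) for i in range(n)]
    mol = np.repeat(np.arange(n), 2)
    from conftest import make_trajectory

    return make_trajectory(
        pos, box=box, bonds=bonds, mol_ids=mol, species=["D"] * 2 * n
    )


class TestP2:
    def test_perpendicular_bonds_give_one(self):
        traj = dumbbell_frames([[0, 0, 1]] * 10, np.linspace(0.5, 2.0, 10))
        _, prof = ta.p2_profile(traj, bin_width=0.1)
        vals = prof[np.isfinite(prof)]
        assert np.allclose(vals, 1.0)

    def test_parallel_bonds_give_minus_half(self):
        traj = dumbbell_frames(
            [[1, 0.3, 0]] * 10, np.linspace(0.5, 2.0, 10)
        )
        _, prof = ta.p2_profile(traj, bin_width=0.1)
        vals = prof[np.isfinite(prof)]
        assert np.allclose(vals, -0.5)

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(42)
        n = 4000
        dirs = rng.standard_normal((n, 3))
        traj = dumbbell_frames(dirs, np.full(n, 1.0), n_frames=1)
        _, prof = ta.p2_profile(traj, bin_width=5.0)
        val = prof[np.isfinite(prof)][0]
        assert abs(val) < 3.0 / math.sqrt(n)

    def test_zero_length_bond_rejected(self, make_traj):
        pos = np.zeros((2, 2, 3)) + 1.0
        traj = make_traj(pos, bonds=[(0, 1)], mol_ids=[0, 0])
        with pytest.raises(ValueError, match="zero-length"):
            ta.p2_profile(traj)


class TestDefineLayers:
    @staticmethod
    def two_gaussian_profile(z0, d_min=0.41):
        h = 0.01
        prof = flat_profile(0.0, z_max=4.0, h=h)
        z = prof.bin_centers
        # symmetric peaks around the forced minimum at z0 + d_min
        m = z0 + d_min
        rho = (np.exp(-((z - (m - 0.2)) ** 2) / 0.008)
               + np.exp(-((z - (m + 0.2)) ** 2) / 0.008)) + 0.1
        prof.densities["S"] = rho
        return prof

    def test_forced_first_layer_thickness(self):
        wall = WallParams(8.2, 0.18)
        prof = self.two_gaussian_profile(wall.zero_crossing)
        first, second = ta.define_layers(prof, wall, "S")
        assert first.width == pytest.approx(0.41, abs=0.02)
        assert second.width == pytest.approx(first.width)
        assert second.z_lo == pytest.approx(first.z_hi)

    def test_symmetric_peaks_minimum_at_midpoint(self):
        wall = WallParams(8.2, 0.18)
        prof = self.two_gaussian_profile(wall.zero_crossing, d_min=0.6)
        first, _ = ta.define_layers(prof, wall, "S")
        m = wall.zero_crossing + 0.6
        assert first.z_hi == pytest.approx(m, abs=0.02)

    def test_single_peak_rejected(self):
        wall = WallParams(8.2, 0.18)
        prof = flat_profile(0.0, z_max=3.0)
        z = prof.bin_centers
        prof.densities["S"] = np.exp(-((z - 1.0) ** 2) / 0.02)
        with pytest.raises(ValueError, match="peaks"):
            ta.define_layers(prof, wall, "S")


class TestLayerMSD:
    def test_ballistic_movers_msd_is_v2t2(self, make_traj):
        v = 0.03  # nm/ps
        t = np.arange(50.0)
        pos = np.zeros((50, 5, 3))
        pos[:, :, 0] = v * t[:, None]
        pos[:, :, 2] = 1.0
        traj = make_traj(pos, box=(1e6, 1e6))
        layer = LayerDefinition(0.0, 2.0)
        res = ta.layer_msd_xy(traj, layer, max_lag=20.0)
        expected = (v * res.lags) ** 2
        assert np.allclose(res.msd_xy, expected, rtol=1e-10, atol=1e-12)

    def test_random_walk_diffusion_recovered(self, make_traj):
        """2-D random walk with known D confined to the layer: the
        Einstein slope/4 recovers D within 5%."""
        rng = np.random.default_rng(123)
        D = 0.5e-3  # nm^2/ps  (= 0.5e-9 m^2/s)
        dt, n_steps, n = 1.0, 10_000, 500
        steps = rng.standard_normal((n_steps, n, 2)) * math.sqrt(2 * D * dt)
        xy = np.cumsum(steps, axis=0)
        pos = np.zeros((n_steps, n, 3))
        pos[:, :, :2] = xy
        pos[:, :, 2] = 0.5
        traj = make_traj(pos, dt=dt, box=(1e6, 1e6))
        res = ta.layer_msd_xy(traj, LayerDefinition(0.0, 1.0), max_lag=500.0)
        res = ta.diffusion_coefficient(res)
        assert res.D == pytest.approx(0.5, rel=0.05)

    def test_exit_breaks_origin_lag_pairs(self, make_traj):
        # one molecule leaves the layer mid-trajectory: no origin-lag
        # pair spans the exit, so MSD counts drop accordingly
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = np.arange(10.0) * 0.1
        pos[:, 0, 2] = 0.5
        pos[5, 0, 2] = 5.0  # outside for one frame
        traj = make_traj(pos, box=(1e6, 1e6))
        res = ta.layer_msd_xy(traj, LayerDefinition(0.0, 1.0), max_lag=6.0)
        # runs are frames 0-4 and 6-9: lag-4 pairs come only from run 1
        assert res.counts[4] == 1
        # and no pair at all spans frames 4->6
        assert res.counts[6] == 0

    def test_unconstrained_walker_equals_plain_msd(self, make_traj):
        """With the layer spanning the whole film, the residency
        constraint is inert: MSD equals the unconstrained average."""
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.standard_normal((200, 20, 3)) * 0.05, axis=0) + 5.0
        traj = make_traj(pos, box=(1e9, 1e9))
        res = ta.layer_msd_xy(traj, LayerDefinition(-1e8, 1e8), max_lag=50.0)
        # independent plain multi-origin MSD, brute force
        lags = np.arange(51)
        xy = pos[:, :, :2]
        brute = np.zeros(51)
        for lag in lags[1:]:
            d = xy[lag:] - xy[:-lag]
            brute[lag] = np.mean(np.sum(d ** 2, axis=2))
        assert np.allclose(res.msd_xy, brute, rtol=1e-8, atol=1e-10)


class TestDiffusionCoefficient:
    def test_exact_line_recovers_D(self):
        lags = np.arange(101.0)
        D = 0.7  # 1e-9 m2/s -> nm^2/ps slope = 4 D 1e-3
        msd = ta.MSDResult(
            lags=lags, msd_xy=4 * D * 1e-3 * lags, counts=np.ones(101)
        )
        res = ta.diffusion_coefficient(msd)
        assert res.D == pytest.approx(D, rel=1e-12)
        assert res.D_se == pytest.approx(0.0, abs=1e-9)

    def test_ballistic_window_flagged_by_curvature(self):
        lags = np.arange(101.0)
        msd = ta.MSDResult(lags=lags, msd_xy=1e-4 * lags ** 2, counts=np.ones(101))
        res = ta.diffusion_coefficient(msd)
        assert res.curvature_flag

    def test_too_few_points_rejected(self):
        msd = ta.MSDResult(
            lags=np.arange(5.0), msd_xy=np.arange(5.0), counts=np.ones(5)
        )
        with pytest.raises(ValueError):
            ta.diffusion_coefficient(msd, fit_window=(0.0, 1.0))


class TestResidence:
    def test_fixed_particle_single_censored_visit(self, make_traj):
        pos = np.zeros((100, 1, 3)) + 0.5
        traj = make_traj(pos)
        dist = ta.residence_times(traj, LayerDefinition(0.0, 1.0))
        assert len(dist.residence_times) == 1
        assert dist.censored[0]
        assert dist.residence_times[0] == pytest.approx(100 * 1.0 * 1e-3)

    def test_oscillator_visits_half_period(self, make_traj):
        dt, period = 1.0, 40.0
        t = dt * np.arange(400)
        z = 1.0 + 0.8 * np.sin(2 * np.pi * t / period)
        pos = np.zeros((400, 1, 3))
        pos[:, 0, 2] = z
        traj = make_traj(pos, dt=dt)
        dist = ta.residence_times(traj, LayerDefinition(1.0, 3.0))
        interior = dist.residence_times[~dist.censored]
        assert np.allclose(interior, period / 2 * 1e-3, atol=2 * dt * 1e-3)

    def test_telegraph_process_mean_is_inverse_rate(self, make_traj):
        """Two-state telegraph occupancy with exit rate k: visit
        durations are exponential with mean 1/k (within 10%, seeded)."""
        rng = np.random.default_rng(77)
        k = 0.02  # 1/ps
        dt, n_frames, n = 1.0, 20_000, 50
        p_exit = 1.0 - math.exp(-k * dt)
        p_enter = 1.0 - math.exp(-k * dt)  # symmetric telegraph
        state = rng.random(n) < 0.5
        zs = np.empty((n_frames, n))
        for f in range(n_frames):
            zs[f] = np.where(state, 0.5, 5.0)
            flip = rng.random(n) < np.where(state, p_exit, p_enter)
            state ^= flip
        pos = np.zeros((n_frames, n, 3))
        pos[:, :, 2] = zs
        traj = make_traj(pos, dt=dt)
        dist = ta.residence_times(traj, LayerDefinition(0.0, 1.0))
        mean_ns = dist.mean(include_censored=False)
        # discrete-time geometric dwell: mean = dt / p_exit
        expected = dt / p_exit * 1e-3
        assert mean_ns == pytest.approx(expected, rel=0.10)

    def test_occupancy_conservation(self, make_traj):
        rng = np.random.default_rng(8)
        pos = rng.random((500, 30, 3)) * [2.0, 2.0, 2.0]
        traj = make_traj(pos, dt=2.0)
        layer = LayerDefinition(0.3, 0.9)
        dist = ta.residence_times(traj, layer)
        inside = (pos[:, :, 2] >= 0.3) & (pos[:, :, 2] < 0.9)
        total_ns = inside.sum() * 2.0 * 1e-3
        assert dist.residence_times.sum() == pytest.approx(total_ns, rel=1e-12)


class TestBondACF:
    def test_frozen_orientations_acf_stays_one(self):
        traj = dumbbell_frames(
            [[1, 1, 1]] * 5, np.full(5, 1.0), n_frames=50
        )
        res = ta.bond_acf(traj, None, max_lag=30.0)
        assert np.allclose(res.acf, 1.0)
        assert res.decay_time is None

    def test_acf_at_lag_zero_is_exactly_one(self):
        rng = np.random.default_rng(3)
        traj = dumbbell_frames(rng.standard_normal((8, 3)), np.full(8, 1.0),
                               n_frames=20)
        res = ta.bond_acf(traj, None, max_lag=10.0)
        assert res.acf[0] == pytest.approx(1.0, abs=1e-12)

    def test_rotational_diffusion_decay_time(self, make_traj):
        """Free rotational diffusion: ACF of the bond unit vector decays
        as exp(-2 D_r t); the 1/e time is 1/(2 D_r) within 10%."""
        rng = np.random.default_rng(21)
        D_r = 2e-3  # 1/ps (= 2/ns)
        dt, n_frames, n = 0.5, 4000, 300
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = np.zeros((n_frames, 2 * n, 3))
        scale = math.sqrt(2 * D_r * dt)
        centers = np.zeros((n, 3)) + [2.0, 2.0, 1.0]
        for f in range(n_frames):
            pos[f, 0::2] = centers - 0.075 * u
            pos[f, 1::2] = centers + 0.075 * u
            xi = rng.standard_normal((n, 3)) * scale
            xi -= np.sum(xi * u, axis=1, keepdims=True) * u
            u = u + xi
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        bonds = [(2 * i, 2 * i + 1) for i in range(n)]
        traj = make_traj(pos, dt=dt, box=(1e6, 1e6),
                         bonds=bonds, mol_ids=np.repeat(np.arange(n), 2),
                         species=["D"] * 2 * n)
        res = ta.bond_acf(traj, None, max_lag=600.0)
        expected_ns = 1.0 / (2 * D_r) * 1e-3
        assert res.decay_time == pytest.approx(expected_ns, rel=0.10)


class TestExtrapolation:
    def test_constant_films_give_flat_line(self):
        res = ta.extrapolate_infinite_thickness([(3.0, 0.6), (6.0, 0.6), (12.0, 0.6)])
        assert res.intercept == pytest.approx(0.6)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_in_inverse_thickness(self):
        a, b = 0.81, -0.9  # intercept, slope in 1/L
        films = [(L, a + b / L) for L in (3.1, 5.0, 9.0, 13.9)]
        res = ta.extrapolate_infinite_thickness(films)
        assert res.intercept == pytest.approx(a, rel=1e-10)
        assert res.slope == pytest.approx(b, rel=1e-10)

    def test_negative_slope_intercept_exceeds_all_films(self):
        films = [(L, 0.9 - 0.8 / L) for L in (3.0, 6.0, 9.0, 12.0)]
        res = ta.extrapolate_infinite_thickness(films)
        assert res.slope < 0
        assert res.intercept > max(r for _, r in films)

    def test_duplicate_thicknesses_rejected(self):
        with pytest.raises(ValueError):
            ta.extrapolate_infinite_thickness([(3.0, 0.5), (3.0, 0.6)])
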