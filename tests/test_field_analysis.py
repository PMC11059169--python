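"""Director grids, defects, misalignment, interfaces, and correlations."""
import numpy as np
import pandas as pd
import pytest

from nemalign.analysis import (
    DefectSet,
    DirectorGrid,
    cells_to_grid,
    correlation_length,
    defect_interface_colocalization,
    find_defects,
    interface_domains,
    misalignment,
    misalignment_histogram,
    orientation_correlation,
    plaquette_winding,
    principal_stress_axis,
    refine_grid,
    stress_vs_misalignment,
    velocity_correlation,
)
from nemalign.qtensor import nematic_distance
from nemalign.synth import smooth_nematic_field


class TestCellsToGrid:
    def test_four_cells_two_by_two(self):
        x = np.array([1.0, 6.0, 1.0, 6.0])
        y = np.array([1.0, 1.0, 6.0, 6.0])
        ang = np.array([0.1, 0.2, 0.3, 0.4])
        g = cells_to_grid(x, y, ang, np.ones(4), L=8.0)
        assert g.shape == (2, 2)
        assert g.dl == pytest.approx(4.0)
        np.testing.assert_allclose(
            g.angle, [[0.1, 0.2], [0.3, 0.4]], atol=1e-12
        )

    def test_lattice_constant_formula(self, rng):
        x = rng.uniform(0, 10, 100)
        y = rng.uniform(0, 10, 100)
        g = cells_to_grid(x, y, rng.uniform(0, np.pi, 100), np.ones(100), L=10.0)
        assert g.shape == (10, 10)
        assert g.dl == pytest.approx(1.0)

    def test_collision_closest_wins_then_input_order(self):
        # both cells map to the single site of a 1-cell-per-side grid;
        # use 4 cells so N >= 4, with two contenders for site (0, 0)
        x = np.array([0.4, 0.6, 3.0, 3.0])
        y = np.array([0.5, 0.5, 0.5, 3.0])
        ang = np.array([0.7, 0.2, 0.3, 0.4])
        g = cells_to_grid(x, y, ang, np.ones(4), L=4.0)
        # site centre (1,1): cell 1 at distance 0.64 beats cell 0 at 0.78
        assert g.angle[0, 0] == pytest.approx(0.2)
        # tie: equidistant cells resolved by input order
        x2 = np.array([0.5, 1.5, 3.0, 0.5])
        y2 = np.array([1.0, 1.0, 3.0, 3.0])
        g2 = cells_to_grid(x2, y2, np.array([0.9, 0.1, 0.2, 0.3]), np.ones(4), L=4.0)
        assert g2.angle[0, 0] == pytest.approx(0.9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cells_to_grid(np.array([1.0]), np.array([1.0]), np.array([0.0]),
                          np.array([1.0]), L=4.0)


class TestRefineGrid:
    def test_uniform_field_unchanged(self):
        g = DirectorGrid(np.full((5, 5), 0.8), np.ones((5, 5)), dl=2.0)
        r = refine_grid(g, 3)
        np.testing.assert_allclose(r.angle, 0.8, atol=1e-12)
        assert r.dl == pytest.approx(2.0 / 3.0)

    def test_nematic_midpoint_crosses_zero(self):
        # interpolating between 10 deg and 170 deg must pass near 0, not 90
        ang = np.radians(np.array([[10.0, 170.0]] * 2))
        g = DirectorGrid(ang, np.ones((2, 2)))
        r = refine_grid(g, 4)
        mids = np.degrees(r.angle)
        dist_to_0 = np.minimum(mids, 180 - mids)
        assert dist_to_0.max() < 11.0  # never near 90 deg
        # passes close to 0 near the middle (finest samples straddle the
        # exact midpoint, so the minimum is small but nonzero)
        assert dist_to_0.min() < 3.0

    def test_factor_one_identity(self, rng):
        g = DirectorGrid(rng.uniform(0, np.pi, (4, 4)), rng.uniform(0, 1, (4, 4)))
        r = refine_grid(g, 1)
        np.testing.assert_array_equal(r.angle, g.angle)
        assert r.angle is not g.angle


class TestDefects:
    def test_imprinted_plus_half(self):
        yy, xx = np.mgrid[0:41, 0:41]
        psi = 0.5 * np.arctan2(yy - 20.2, xx - 20.2)
        ds = find_defects(psi, periodic=False)
        assert len(ds) == 1
        assert ds.charge[0] == 0.5
        assert abs(ds.x[0] - 20.2) <= 1.0 and abs(ds.y[0] - 20.2) <= 1.0

    def test_imprinted_minus_half(self):
        yy, xx = np.mgrid[0:41, 0:41]
        psi = -0.5 * np.arctan2(yy - 20.2, xx - 20.2)
        ds = find_defects(psi, periodic=False)
        assert len(ds) == 1 and ds.charge[0] == -0.5

    def test_uniform_field_no_defects(self):
        assert len(find_defects(np.full((16, 16), 0.3))) == 0

    def test_periodic_charge_neutrality(self):
        # topological constraint: windings sum to zero on a torus
        for seed in range(5):
            psi = smooth_nematic_field(64, 6.0, seed=seed, n=64)
            w = plaquette_winding(psi, periodic=True)
            assert abs(w.sum()) < 1e-10
            ds = find_defects(psi, periodic=True)
            assert set(np.unique(ds.charge)).issubset({-0.5, 0.5})

    def test_refine_then_find_recovers_imprint(self):
        """Charge exact and position within one coarse lattice unit after
        interpolation onto a finer mesh."""
        yy, xx = np.mgrid[0:21, 0:21]
        psi = 0.5 * np.arctan2(yy - 10.4, xx - 10.4)
        g = DirectorGrid(psi, np.ones((21, 21)), dl=1.0)
        fine = refine_grid(g, 4)
        ds = find_defects(fine, periodic=False)
        plus = ds.charge == 0.5
        assert plus.sum() == 1
        # positions are in fine-lattice units; convert to coarse
        x_c = ds.x[plus][0] / 4.0
        y_c = ds.y[plus][0] / 4.0
        assert abs(x_c - 10.4) <= 1.0 and abs(y_c - 10.4) <= 1.0

    def test_orientation_rotates_with_texture(self):
        yy, xx = np.mgrid[0:41, 0:41]
        phi = np.arctan2(yy - 20.2, xx - 20.2)
        base = find_defects(0.5 * phi, periodic=False)
        alpha = 0.5  # rotate the whole texture
        rot = find_defects(0.5 * phi + alpha, periodic=False)
        # +1/2 defect: texture rotation by alpha turns the axis by 2 alpha...
        # the convention must be equivariant: orientation shifts linearly
        d = (rot.orientation[0] - base.orientation[0]) % (2 * np.pi)
        assert d == pytest.approx(2 * alpha, abs=0.05)

    def test_nematic_gauge_invariance(self, rng):
        """Adding pi to any subset of director angles changes nothing."""
        psi = smooth_nematic_field(32, 4.0, seed=9, n=32)
        flip = rng.random((32, 32)) < 0.5
        ds1 = find_defects(psi)
        ds2 = find_defects(np.where(flip, psi + np.pi, psi))
        assert len(ds1) == len(ds2)
        np.testing.assert_allclose(np.sort(ds1.x), np.sort(ds2.x), atol=1e-9)


class TestPrincipalStress:
    def test_diagonal_tensor(self):
        ang, mag, iso = principal_stress_axis(2.0, 0.0, 1.0)
        assert ang == pytest.approx(0.0)
        assert mag == pytest.approx(0.5)
        assert not iso

    def test_pure_shear(self):
        ang, mag, _ = principal_stress_axis(0.0, 1.0, 0.0)
        assert np.degrees(ang) == pytest.approx(45.0)
        assert mag == pytest.approx(1.0)

    def test_isotropic_flagged(self):
        ang, mag, iso = principal_stress_axis(3.0, 0.0, 3.0)
        assert iso and mag == 0.0 and ang == 0.0

    def test_rotation_equivariance(self, rng):
        sxx, sxy, syy = 2.0, 0.7, -1.0
        a0, m0, _ = principal_stress_axis(sxx, sxy, syy)
        for alpha in rng.uniform(0, np.pi, 5):
            c, s = np.cos(alpha), np.sin(alpha)
            R = np.array([[c, -s], [s, c]])
            S = R @ np.array([[sxx, sxy], [sxy, syy]]) @ R.T
            a, m, _ = principal_stress_axis(S[0, 0], S[0, 1], S[1, 1])
            assert m == pytest.approx(m0)
            assert nematic_distance(a, a0 + alpha) < 1e-10

    def test_round_trip_with_inverse(self, rng):
        """Rebuilding sigma from (angle, magnitude, trace) and re-analysing
        is the identity on angle and magnitude."""
        for _ in range(20):
            ang0 = rng.uniform(0, np.pi)
            mag0 = rng.uniform(0.1, 3.0)
            p = rng.normal()
            sxx = p + mag0 * np.cos(2 * ang0)
            sxy = mag0 * np.sin(2 * ang0)
            syy = p - mag0 * np.cos(2 * ang0)
            ang, mag, _ = principal_stress_axis(sxx, sxy, syy)
            assert mag == pytest.approx(mag0)
            assert nematic_distance(ang, ang0) < 1e-12


class TestMisalignment:
    def test_perpendicular_directors(self):
        n = DirectorGrid(np.zeros((3, 3)), np.ones((3, 3)))
        m = DirectorGrid(np.full((3, 3), np.pi / 2), np.ones((3, 3)))
        mm = misalignment(n, m)
        np.testing.assert_allclose(mm.theta_deg, 90.0)
        assert mm.extensile_fraction() == 1.0

    def test_nematic_wrap(self):
        n = DirectorGrid(np.full((2, 2), np.radians(10)), np.ones((2, 2)))
        m = DirectorGrid(np.full((2, 2), np.radians(170)), np.ones((2, 2)))
        np.testing.assert_allclose(misalignment(n, m).theta_deg, 20.0)

    def test_independent_random_fields(self, rng):
        a = rng.uniform(0, np.pi, (200, 200))
        b = rng.uniform(0, np.pi, (200, 200))
        mm = misalignment(DirectorGrid(a, np.ones_like(a)),
                          DirectorGrid(b, np.ones_like(b)))
        assert mm.theta_deg.mean() == pytest.approx(45.0, abs=0.5)
        assert mm.extensile_fraction() == pytest.approx(0.5, abs=0.01)

    def test_isotropic_sites_excluded(self):
        n = DirectorGrid(np.zeros((2, 2)), np.ones((2, 2)),
                         isotropic=np.array([[True, False], [False, False]]))
        m = DirectorGrid(np.full((2, 2), 1.0), np.ones((2, 2)))
        mm = misalignment(n, m)
        assert mm.valid.sum() == 3

    def test_exact_45_is_contractile(self):
        n = DirectorGrid(np.zeros((2, 2)), np.ones((2, 2)))
        m = DirectorGrid(np.full((2, 2), np.pi / 4), np.ones((2, 2)))
        assert misalignment(n, m).extensile_fraction() == 0.0


class TestInterfaceDomains:
    def test_half_plane_band(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, 10:] = True
        interface, fr = interface_domains(mask, r_max=1.0)
        cols = np.unique(np.nonzero(interface)[1])
        np.testing.assert_array_equal(cols, [9, 10])
        assert fr["interface"] == pytest.approx(0.1)
        assert fr["interface"] + fr["extensile"] + fr["contractile"] == pytest.approx(1.0)

    def test_uniform_mask_no_interface(self):
        interface, fr = interface_domains(np.ones((8, 8), dtype=bool), r_max=2.0)
        assert not interface.any()
        assert fr["interface"] == 0.0 and fr["extensile"] == 1.0

    def test_periodic_wraparound(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, :2] = True
        mask[:, -2:] = True  # one band through the periodic seam
        interface, _ = interface_domains(mask, r_max=1.0, periodic=True)
        # boundaries at cols 1/2 and 13/14 only; the seam is interior
        assert not interface[:, 15].any() and not interface[:, 0].any()

    def test_colocalization(self):
        interface = np.zeros((10, 10), dtype=bool)
        interface[4:6, :] = True
        inside = DefectSet(np.array([3.5]), np.array([5.0]),
                           np.array([0.5]), np.array([0.0]))
        assert defect_interface_colocalization(inside, interface) == 1.0
        outside = DefectSet(np.array([3.5]), np.array([1.0]),
                            np.array([-0.5]), np.array([0.0]))
        assert defect_interface_colocalization(outside, interface) == 0.0
        empty = DefectSet(np.array([]), np.array([]), np.array([]), np.array([]))
        assert defect_interface_colocalization(empty, interface) is None


class TestCorrelations:
    def test_constant_field(self):
        r, C = orientation_correlation(np.full((32, 32), 0.7))
        np.testing.assert_allclose(C, 1.0, atol=1e-12)
        assert r[0] == 0.0

    def test_independent_angles_decorrelate(self, rng):
        psi = rng.uniform(0, np.pi, (64, 64))
        r, C = orientation_correlation(psi)
        assert C[0] == pytest.approx(1.0)
        assert np.abs(C[2:]).max() < 3 / np.sqrt(64 * 64 / 8)

    def test_generator_round_trip(self):
        psi = smooth_nematic_field(256, 64.0, seed=12, n=256)
        r, C = orientation_correlation(psi)
        ell = correlation_length(r, C)
        assert ell == pytest.approx(64.0, rel=0.2)

    def test_global_rotation_invariance(self, rng):
        psi = smooth_nematic_field(64, 8.0, seed=2, n=64)
        r1, C1 = orientation_correlation(psi)
        r2, C2 = orientation_correlation(psi + 0.9)
        np.testing.assert_allclose(C1, C2, atol=1e-10)

    def test_temporal_mode(self, rng):
        # AR(1)-mixed components decorrelate monotonically in lag
        frames = [np.full((16, 16), 0.3), np.full((16, 16), 0.3 + 0.4),
                  np.full((16, 16), 0.3 + 0.8)]
        t, C = orientation_correlation(np.stack(frames), mode="temporal", dt=2.0)
        np.testing.assert_allclose(t, [0.0, 2.0, 4.0])
        assert C[0] == pytest.approx(1.0)
        assert C[1] == pytest.approx(np.cos(0.8))
        assert C[2] == pytest.approx(np.cos(1.6))

    def test_masked_pair_mode_matches_fft_on_full_grid(self):
        psi = smooth_nematic_field(48, 6.0, seed=4, n=48)
        r1, C1 = orientation_correlation(psi, max_r=10)
        r2, C2 = orientation_correlation(
            psi, mask=np.ones((48, 48), dtype=bool), max_r=10
        )
        # pair mode is non-periodic; agreement at short range
        np.testing.assert_allclose(C1[:8], C2[:8], atol=0.05)

    def test_velocity_uniform(self):
        u = np.full((32, 32), 0.2)
        r, C = velocity_correlation(u, u)
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    def test_velocity_white_noise(self, rng):
        ux = rng.normal(size=(64, 64))
        uy = rng.normal(size=(64, 64))
        r, C = velocity_correlation(ux, uy)
        assert np.abs(C[2:]).max() < 0.05

    def test_velocity_vortex_sign_change(self):
        n = 64
        y, x = np.mgrid[0:n, 0:n] * 2 * np.pi / n
        ux = np.sin(x) * np.cos(y)
        uy = -np.cos(x) * np.sin(y)
        r, C = velocity_correlation(ux, uy)
        assert C.min() < -0.2  # anti-correlation at the vortex scale

    def test_zero_velocity_flagged(self):
        with pytest.raises(ValueError):
            velocity_correlation(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_correlation_length_no_crossing(self):
        assert np.isnan(correlation_length(np.arange(5.0), np.ones(5)))


class TestBinnedStatistics:
    def test_flat_when_independent(self, rng):
        mag = rng.uniform(1, 2, 5000)
        theta = rng.uniform(0, 90, 5000)
        df = stress_vs_misalignment([(mag, theta)], n_bins=6)
        assert df["mean"].max() - df["mean"].min() < 0.05

    def test_cosine_decline_recovered(self, rng):
        theta = rng.uniform(0, 90, 4000)
        mag = np.cos(np.radians(theta)) + 1e-6
        df = stress_vs_misalignment([(mag, theta)], n_bins=9)
        assert (np.diff(df["mean"]) < 0).all()

    def test_rescaling_invariance(self, rng):
        theta = rng.uniform(0, 90, 1000)
        mag = rng.uniform(0.5, 1.5, 1000)
        d1 = stress_vs_misalignment([(mag, theta)], n_bins=5)
        d2 = stress_vs_misalignment([(37.0 * mag, theta)], n_bins=5)
        np.testing.assert_allclose(d1["mean"], d2["mean"], atol=1e-12)

    def test_histogram_point_mass(self):
        centres, density, frac = misalignment_histogram(np.zeros(100), n_bins=9)
        assert frac == 0.0
        assert density[0] > 0 and (density[1:] == 0).all()

    def test_histogram_uniform(self, rng):
        theta = rng.uniform(0, 90, 50_000)
        centres, density, frac = misalignment_histogram(theta, n_bins=9)
        np.testing.assert_allclose(density, 1 / 90, rtol=0.1)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_histogram_range_check(self):
        with pytest.raises(ValueError):
            misalignment_histogram(np.array([95.0]))
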