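"""Kinematic estimators: MSD/MSAD, octant correction, normals, covariance."""

import numpy as np
import pytest

from memprobe.estimators import (
    LagStatistic,
    OrientationTrajectory,
    PositionTrajectory,
    compute_angle_covariance,
    compute_msad_raw,
    compute_msd,
    compute_theta_msd,
    estimate_normals,
    get_octant_map,
    in_plane_angles,
    log_lag_grid,
    out_of_plane_angles,
    raw_to_physical_msad,
    theta_msd_from_covariance,
    unfold_octant,
)
from memprobe.synthetic import SimConfig, simulate_prone_rotor


def _flat_traj(n=100, dt=1e-3, v=(0.0, 0.0)):
    t = np.arange(n) * dt
    return PositionTrajectory(t=t, x=v[0] * t, y=v[1] * t, z=np.zeros(n))


class TestComputeMsd:
    def test_constant_position_is_zero(self):
        msd = compute_msd(_flat_traj(), lags=[1e-3, 5e-3])
        np.testing.assert_array_equal(msd.values, 0.0)

    def test_ballistic_motion_exact(self):
        v = 3.0e-6
        msd = compute_msd(_flat_traj(v=(v, 0.0)), lags=[1e-3, 2e-3, 1e-2])
        np.testing.assert_allclose(msd.values, (v * msd.lags) ** 2, rtol=1e-12)

    def test_lag_beyond_span_warns_and_omits(self):
        with pytest.warns(UserWarning, match="omitted"):
            msd = compute_msd(_flat_traj(n=50), lags=[1e-3, 10.0])
        assert msd.lags.size == 1

    def test_empty_lags_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(_flat_traj(), lags=[])

    def test_rigid_motion_invariance(self, rng):
        # time translation and rigid rotation leave the MSD unchanged
        n = 400
        t = np.arange(n) * 1e-3
        xyz = rng.normal(size=(n, 3)).cumsum(axis=0) * 1e-8
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        xyz2 = xyz @ rot.T + np.array([5e-6, -2e-6, 1e-6])
        lags = [1e-3, 7e-3, 3e-2]
        a = compute_msd(
            PositionTrajectory(t=t, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2]), lags
        )
        b = compute_msd(
            PositionTrajectory(t=t + 17.0, x=xyz2[:, 0], y=xyz2[:, 1], z=xyz2[:, 2]),
            lags,
        )
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)


class TestMsadRaw:
    def test_constant_orientation_zero(self):
        n = 50
        u = np.tile([1.0, 0.0, 0.0], (n, 1))
        traj = OrientationTrajectory(t=np.arange(n) * 1e-3, u=u)
        msad = compute_msad_raw(traj, [1e-3])
        assert msad.values[0] == 0.0

    def test_alternating_antipodal_is_four(self):
        n = 60
        u = np.tile([1.0, 0.0, 0.0], (n, 1))
        u[1::2] *= -1
        traj = OrientationTrajectory(t=np.arange(n) * 1e-3, u=u)
        msad = compute_msad_raw(traj, [1e-3])
        assert msad.values[0] == pytest.approx(4.0)

    def test_octant_saturation_of_random_orientations(self, rng):
        # folded iid unit vectors: E|u - u'|^2 = 2 - 2*3*E[|ux|]^2 = 1/2
        n = 40_000
        u = rng.normal(size=(n, 3))
        u = np.abs(u / np.linalg.norm(u, axis=1, keepdims=True))
        traj = OrientationTrajectory(t=np.arange(n) * 1e-3, u=u, octant=True)
        msad = compute_msad_raw(traj, [1e-3, 1.0])
        assert msad.values[-1] == pytest.approx(0.5, rel=0.02)

    def test_unit_norm_enforced(self):
        with pytest.raises(ValueError, match="unit norm"):
            OrientationTrajectory(t=np.array([0.0, 1.0]),
                                  u=np.array([[1, 0, 0], [0.9, 0, 0.0]]))


class TestOctantMap:
    def test_zero_maps_to_zero(self):
        omap = get_octant_map("planar_rotor")
        assert omap.invert(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_saturation_matches_closed_form(self):
        # phase-averaged quadrant folding saturates at 2 - 16/pi^2
        omap = get_octant_map("planar_rotor")
        assert omap.saturation == pytest.approx(2 - 16 / np.pi**2, rel=1e-3)

    def test_small_displacement_regime_near_identity(self):
        # folding only loses the sqrt(m)-wide phase band near the fold
        # boundaries, so raw -> physical as the displacement shrinks
        omap = get_octant_map("planar_rotor")
        ratios = np.array(
            [omap.forward(m) / m for m in (0.0025, 0.01, 0.04)]
        )
        assert np.all(ratios > 0.8) and np.all(ratios < 1.0)
        assert np.all(np.diff(ratios) < 0)  # closer to identity at smaller m

    def test_roundtrip_identity(self):
        omap = get_octant_map("planar_rotor")
        phys = np.linspace(0.01, 1.5, 25)
        np.testing.assert_allclose(omap.invert(omap.forward(phys)), phys, rtol=0.01)

    def test_forward_simulation_consistency(self, rng):
        # fold a simulated planar rotor and compare its raw MSAD with the
        # tabulated forward map at the known physical MSAD
        omap = get_octant_map("planar_rotor")
        cfg = SimConfig(seed=17, n_steps=60_000, Dr=27.7)
        traj = simulate_prone_rotor(cfg, octant=True, noise=False)
        lags = np.array([1, 2, 5, 10, 20, 50]) * cfg.dt
        raw = compute_msad_raw(traj, lags)
        np.testing.assert_allclose(
            raw.values, omap.forward(4 * 27.7 * raw.lags), rtol=0.05
        )

    def test_saturated_values_flagged(self):
        omap = get_octant_map("planar_rotor")
        assert np.isnan(omap.invert(omap.saturation + 0.01))
        stat = LagStatistic(
            lags=np.array([0.1, 1.0]),
            values=np.array([0.05, omap.saturation + 0.05]),
            stderr=np.array([1e-3, 1e-3]),
            n_pairs=np.array([100, 100]),
            kind="msad_raw",
        )
        with pytest.warns(UserWarning, match="unmappable"):
            phys = raw_to_physical_msad(stat)
        assert phys.lags.size == 1 and phys.meta["n_unmappable"] == 1


class TestEstimateNormals:
    def test_exact_planar_orientations(self, rng):
        n0 = np.array([1.0, 2.0, -0.5])
        n0 /= np.linalg.norm(n0)
        e1 = np.cross(n0, [0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)
        phi = rng.uniform(0, 2 * np.pi, size=60)
        u = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        traj = OrientationTrajectory(t=np.arange(60.0), u=u)
        ns = estimate_normals(traj, window=20)
        assert np.all(ns.valid)
        for n_hat in ns.n:
            assert abs(abs(n_hat @ n0) - 1) < 1e-9

    def test_collinear_window_flagged(self):
        u = np.tile([0.0, 0.0, 1.0], (30, 1))
        traj = OrientationTrajectory(t=np.arange(30.0), u=u)
        ns = estimate_normals(traj, window=10)
        assert not ns.valid.any()

    def test_octant_input_recovers_plane_up_to_fold_ambiguity(self, rng):
        # folded data fix the plane normal only up to component signs;
        # recovery is asserted modulo that intrinsic ambiguity
        n0 = np.array([0.2, 0.3, 1.0])
        n0 /= np.linalg.norm(n0)
        e1 = np.cross(n0, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)
        phi = np.cumsum(rng.normal(scale=0.15, size=200))
        u = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        traj = OrientationTrajectory(t=np.arange(200.0), u=np.abs(u), octant=True)
        ns = estimate_normals(traj, window=25)
        dots = np.abs(np.abs(ns.n[ns.valid]) @ np.abs(n0))
        assert np.median(np.degrees(np.arccos(np.clip(dots, -1, 1)))) < 3.0

    def test_octant_input_with_radial_anchor_resolves_branch(self, rng):
        # with vesicle geometry the outward anchor picks the physical branch
        R = 7e-6
        n0 = np.array([0.2, 0.3, 1.0])
        n0 /= np.linalg.norm(n0)
        e1 = np.cross(n0, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)
        phi = np.cumsum(rng.normal(scale=0.15, size=200))
        u = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        traj = OrientationTrajectory(t=np.arange(200.0) * 1e-3, u=np.abs(u),
                                     octant=True)
        c = R * n0  # rod sits where the radial direction equals n0
        pos = PositionTrajectory(
            t=traj.t, x=np.full(200, c[0]), y=np.full(200, c[1]),
            z=np.full(200, c[2]), R=R,
        )
        ns = estimate_normals(traj, window=25, positions=pos)
        dots = ns.n[ns.valid] @ n0  # signed: branch must be the outward one
        assert np.median(np.degrees(np.arccos(np.clip(dots, -1, 1)))) < 3.0

    def test_window_too_small_rejected(self):
        u = np.tile([0.0, 0.0, 1.0], (30, 1))
        traj = OrientationTrajectory(t=np.arange(30.0), u=u)
        with pytest.raises(ValueError):
            estimate_normals(traj, window=2)

    def test_unfold_octant_slow_rotation(self):
        phi = np.linspace(0, 4 * np.pi, 500)
        u = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        rec = unfold_octant(np.abs(u))
        # reconstruction matches u or -u globally up to sign conventions
        err = np.minimum(
            np.linalg.norm(rec - u, axis=1), np.linalg.norm(rec + u, axis=1)
        )
        assert np.median(err) < 1e-9


class TestOutOfPlaneAngles:
    def _series(self, n_vec, t=None):
        from memprobe.estimators import NormalSeries

        n = np.asarray(n_vec, dtype=float)
        return NormalSeries(
            t=np.arange(len(n), dtype=float) if t is None else t,
            n=n, valid=np.ones(len(n), bool),
            meta={"window": 1, "stride": 1},
        )

    def test_radial_normal_gives_zero(self):
        t = np.arange(5.0)
        pos = PositionTrajectory(t=t, x=np.zeros(5), y=np.zeros(5),
                                 z=np.full(5, 7e-6), R=7e-6)
        ns = self._series(np.tile([0, 0, 1.0], (5, 1)))
        out = out_of_plane_angles(ns, "sphere_radial", positions=pos)
        np.testing.assert_allclose(out.theta, 0.0, atol=1e-9)

    def test_perpendicular_normal_gives_right_angle(self):
        t = np.arange(5.0)
        pos = PositionTrajectory(t=t, x=np.zeros(5), y=np.zeros(5),
                                 z=np.full(5, 7e-6), R=7e-6)
        ns = self._series(np.tile([1.0, 0, 0], (5, 1)))
        out = out_of_plane_angles(ns, "sphere_radial", positions=pos)
        np.testing.assert_allclose(out.theta, np.pi / 2, atol=1e-9)

    def test_mean_plane_reference(self, rng):
        base = np.array([0.0, 0.0, 1.0])
        tilt = rng.normal(scale=0.05, size=(500, 2))
        n = np.column_stack([tilt[:, 0], tilt[:, 1], np.ones(500)])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        out = out_of_plane_angles(self._series(n), "mean_plane")
        assert np.nanmean(out.theta**2) == pytest.approx(2 * 0.05**2, rel=0.15)

    def test_missing_geometry_raises(self):
        ns = self._series(np.tile([0, 0, 1.0], (5, 1)))
        with pytest.raises(ValueError):
            out_of_plane_angles(ns, "sphere_radial")

    def test_in_plane_angles_unwrap(self):
        phi_true = np.linspace(0, 6 * np.pi, 400)
        u = np.column_stack(
            [np.cos(phi_true), np.sin(phi_true), np.zeros_like(phi_true)]
        )
        traj = OrientationTrajectory(t=np.arange(400.0), u=u)
        phi = in_plane_angles(traj, np.array([0.0, 0.0, 1.0]))
        spans = phi[-1] - phi[0]
        assert abs(abs(spans) - 6 * np.pi) < 1e-6


class TestThetaStatistics:
    def test_constant_series_zero(self):
        out = compute_theta_msd(np.full(100, 0.3), [1.0, 5.0], dt=1.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_white_noise_msd_is_twice_variance(self, rng):
        v = 0.04
        th = rng.normal(scale=np.sqrt(v), size=20_000)
        out = compute_theta_msd(th, [1.0, 10.0, 100.0], dt=1.0)
        z = (out.values - 2 * v) / out.stderr
        assert np.all(np.abs(z) < 3)

    def test_ou_msd_matches_closed_form(self, rng):
        # OU: <dtheta^2(tau)> = 2 v (1 - exp(-omega tau))
        omega, v, dt, n = 2.0, 0.01, 0.05, 60_000
        a = np.exp(-omega * dt)
        th = np.empty(n)
        th[0] = rng.normal(scale=np.sqrt(v))
        g = rng.normal(scale=np.sqrt(v * (1 - a**2)), size=n - 1)
        for i in range(1, n):
            th[i] = th[i - 1] * a + g[i - 1]
        lags = np.array([1, 2, 5, 10, 20, 50]) * dt
        out = compute_theta_msd(th, lags, dt=dt)
        model = 2 * v * (1 - np.exp(-omega * out.lags))
        z = (out.values - model) / out.stderr
        assert np.all(np.abs(z) < 3)

    def test_covariance_white_noise(self, rng):
        v = 0.09
        th = rng.normal(scale=np.sqrt(v), size=30_000)
        cov = compute_angle_covariance(th, [1.0, 5.0], dt=1.0)
        assert cov.meta["variance"] == pytest.approx(v, rel=0.05)
        assert np.all(np.abs(cov.values / cov.stderr) < 3)

    def test_covariance_ou_ratio(self, rng):
        omega, v, dt, n = 3.0, 0.02, 0.02, 50_000
        a = np.exp(-omega * dt)
        th = np.empty(n)
        th[0] = rng.normal(scale=np.sqrt(v))
        g = rng.normal(scale=np.sqrt(v * (1 - a**2)), size=n - 1)
        for i in range(1, n):
            th[i] = th[i - 1] * a + g[i - 1]
        lags = np.array([1, 3, 10]) * dt
        cov = compute_angle_covariance(th, lags, dt=dt)
        model = cov.meta["variance"] * np.exp(-omega * cov.lags)
        z = (cov.values - model) / cov.stderr
        assert np.all(np.abs(z) < 3)

    def test_msd_covariance_identity_exact(self, rng):
        th = rng.normal(size=5000).cumsum() * 0.01
        lags = np.array([1, 4, 16, 64], dtype=float)
        cov = compute_angle_covariance(th, lags, dt=1.0, subtract_mean=True)
        msd = compute_theta_msd(th - th.mean(), lags, dt=1.0)
        np.testing.assert_allclose(
            theta_msd_from_covariance(cov), msd.values, rtol=1e-12
        )


class TestPositionTrajectory:
    def test_z_reconstruction_satisfies_sphere_equation(self, rng):
        R = 7e-6
        ang = rng.uniform(0, 2 * np.pi, 100)
        lat = rng.uniform(0.1, np.pi / 2, 100)
        x = R * np.sin(lat) * np.cos(ang)
        y = R * np.sin(lat) * np.sin(ang)
        traj = PositionTrajectory(t=np.arange(100.0), x=x, y=y, R=R)
        np.testing.assert_allclose(x**2 + y**2 + traj.z**2, R**2, rtol=1e-12)

    def test_point_outside_sphere_rejected(self):
        with pytest.raises(ValueError):
            PositionTrajectory(
                t=np.array([0.0, 1.0]), x=np.array([0.0, 8e-6]),
                y=np.zeros(2), R=7e-6,
            )

    def test_log_lag_grid_monotone_multiples(self):
        lags = log_lag_grid(2e-4, 20.0)
        assert np.all(np.diff(lags) > 0)
        steps = lags / 2e-4
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
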