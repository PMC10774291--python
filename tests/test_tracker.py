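"""Advection, diffusion, gating, beaching and conservation."""

import numpy as np
import pandas as pd
import pytest

import kelpflux as kf
from kelpflux.tracker import ParticleState


def analytic(u_fn):
    """Wrap u_fn(x, y, t) -> (u, v) arrays for rk4_step."""
    def sample(px, py, t):
        return u_fn(np.asarray(px, float), np.asarray(py, float), t)
    return sample


def open_water(u=0.0, v=0.0, depth_fn=None, nx=40, ny=8, dx=3000.0,
               n_days=20, land_coast=False):
    """Uniform-velocity forcing on a simple wet grid."""
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    if depth_fn is None:
        depth = np.full((ny, nx), 100.0)
    else:
        depth = np.tile(depth_fn(x), (ny, 1))
    land = np.zeros((ny, nx), bool)
    if land_coast:
        land[:, 0] = True
        depth[:, 0] = 0.0
    b = kf.BathymetryGrid(x=x, y=y, depth=depth, land=land)
    time = (np.datetime64("2017-01-01", "s")
            + np.timedelta64(3 * 3600, "s") * np.arange(n_days * 8 + 1))
    shape = (time.size, ny, nx)
    f = kf.FieldSeries(grid=b, time=time, u=np.full(shape, u),
                       v=np.full(shape, v),
                       rho_bottom=np.full(shape, 1025.0),
                       wind_speed=np.zeros(shape), wind_dir=np.zeros(shape))
    return b, f


def single_release(x0, y0, date="2017-01-01"):
    dates = pd.DatetimeIndex([date])
    return kf.ReleaseSchedule(dates=dates, counts=np.array([1]),
                              positions=[np.array([[x0, y0]])], total=1,
                              seed=0)


class TestRK4:
    def test_constant_field_step_is_exact(self):
        sample = analytic(lambda x, y, t: (np.full_like(x, 0.1),
                                           np.zeros_like(y)))
        nx, ny = kf.rk4_step(sample, 0.0, 0.0, 0.0, 600.0)
        assert nx == pytest.approx(60.0, abs=1e-12)
        assert ny == pytest.approx(0.0, abs=1e-12)

    def test_solid_body_rotation_closes_orbit(self):
        omega, r0 = 1e-4, 1000.0
        sample = analytic(lambda x, y, t: (-omega * y, omega * x))
        period = 2 * np.pi / omega
        dt = 60.0
        n = int(round(period / dt))
        px, py = np.array([r0]), np.array([0.0])
        for i in range(n):
            px, py = kf.rk4_step(sample, px, py, i * dt, dt)
        # analytic orbit: radius r0, back near the start after one period
        assert abs(np.hypot(px[0], py[0]) - r0) < 1e-3

    def test_rotation_error_shrinks_fourth_order(self):
        period, r0 = 3200.0, 1000.0
        omega = 2 * np.pi / period
        sample = analytic(lambda x, y, t: (-omega * y, omega * x))

        def orbit_error(dt):
            """End-position error after exactly one period (global error,
            dominated by the 4th-order phase drift)."""
            n = int(round(period / dt))
            px, py = np.array([r0]), np.array([0.0])
            for i in range(n):
                px, py = kf.rk4_step(sample, px, py, i * dt, dt)
            return float(np.hypot(px[0] - r0, py[0]))

        ratio = orbit_error(40.0) / orbit_error(20.0)
        assert 10.0 < ratio < 25.0  # ~16x per halving

    def test_linear_shear_matches_analytic_solution(self):
        a = 1e-5
        sample = analytic(lambda x, y, t: (a * y, np.zeros_like(y)))
        px, py = np.array([100.0]), np.array([2000.0])
        t = 0.0
        for _ in range(50):
            px, py = kf.rk4_step(sample, px, py, t, 300.0)
            t += 300.0
        # y constant, x = x0 + a y t
        assert py[0] == pytest.approx(2000.0, abs=1e-12)
        assert px[0] == pytest.approx(100.0 + a * 2000.0 * t, rel=1e-14)


class TestBrownian:
    def test_zero_diffusivity_means_no_displacement(self):
        disp = kf.brownian_step(np.random.default_rng(0), 0.0, 900.0, n=10)
        assert np.all(disp == 0.0)

    def test_per_axis_standard_deviation(self):
        # sqrt(2 * 10 * 180) = 60 m
        disp = kf.brownian_step(np.random.default_rng(3), 10.0, 180.0,
                                n=100_000)
        assert disp[:, 0].std() == pytest.approx(60.0, rel=0.01)
        assert disp[:, 1].std() == pytest.approx(60.0, rel=0.01)

    def test_einstein_relation_for_accumulated_walk(self):
        rng = np.random.default_rng(4)
        K_h, dt, n_steps = 10.0, 900.0, 40
        pos = np.zeros((20_000, 2))
        for _ in range(n_steps):
            pos += kf.brownian_step(rng, K_h, dt, n=pos.shape[0])
        msd = (pos ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * K_h * dt * n_steps, rel=0.03)


class TestLogProfile:
    def test_identity_at_mid_layer_height(self):
        v = kf.log_profile_correction(np.array([0.2, -0.1]), 10.0, 5.0, 1e-3)
        np.testing.assert_allclose(v, [0.2, -0.1])

    def test_known_factor(self):
        # ln(1 / 1e-3) / ln(5 / 1e-3) = ln(1000)/ln(5000) ~ 0.8110
        v = kf.log_profile_correction(1.0, 10.0, 1.0, 1e-3)
        assert v == pytest.approx(np.log(1000) / np.log(5000), rel=1e-12)

    def test_factor_below_one_under_mid_layer(self):
        for target in (0.5, 1.0, 2.0):
            assert kf.log_profile_correction(1.0, 10.0, target, 1e-3) < 1.0

    def test_invalid_heights_rejected(self):
        with pytest.raises(ValueError):
            kf.log_profile_correction(1.0, 10.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            kf.log_profile_correction(1.0, 10.0, 1e-4, 1e-3)


class TestAdvect:
    def test_still_water_keeps_particles_at_release(self):
        b, f = open_water(u=0.0, v=0.0)
        opts = kf.TrackerOptions(dt=3600.0, K_h=0.0, record_hours=6.0)
        trajs = kf.advect(single_release(30e3, 9e3), f, b, opts)
        final = trajs.xy[0][~np.isnan(trajs.xy[0, :, 0])][-1]
        np.testing.assert_allclose(final, [30e3, 9e3], atol=1e-9)

    def test_uniform_offshore_flow_crossing_time(self):
        # depth rises linearly to 200 m at 86.4 km; 0.1 m/s covers that
        # in exactly 10 days
        b, f = open_water(u=0.1, nx=60, dx=2400.0,
                          depth_fn=lambda x: 1.0 + 199.0 * x / 86_400.0,
                          n_days=14)
        opts = kf.TrackerOptions(dt=3600.0, K_h=0.0, record_hours=1.0,
                                 min_depth=0.0)
        trajs = kf.advect(single_release(0.0, 9e3), f, b, opts)
        ages, _ = kf.crossing_ages(trajs, 200.0)
        assert ages[0] == pytest.approx(10.0, abs=0.05)

    def test_threshold_velocity_freezes_slow_flow(self):
        b, f = open_water(u=0.03, v=0.0)
        opts = kf.TrackerOptions(dt=3600.0, K_h=10.0, v_crit=0.045,
                                 record_hours=6.0)
        trajs = kf.advect(single_release(30e3, 9e3), f, b, opts)
        valid = ~np.isnan(trajs.xy[0, :, 0])
        np.testing.assert_allclose(trajs.xy[0, valid, 0], 30e3, atol=1e-6)

    def test_onshore_flow_beaches_at_coast(self):
        b, f = open_water(u=-0.05, land_coast=True, n_days=30)
        opts = kf.TrackerOptions(dt=3600.0, K_h=0.0, record_hours=6.0)
        trajs = kf.advect(single_release(30e3, 9e3), f, b, opts)
        assert trajs.state[0] == ParticleState.BEACHED
        # frozen at its last wet position near the waterline
        last = trajs.xy[0][~np.isnan(trajs.xy[0, :, 0])][-1]
        assert last[0] < 10e3

    def test_particle_count_conservation(self, default_config):
        cfg = default_config
        scn = kf.make_scenario(cfg)
        sched = kf.build_schedule(scn.kelp_prob, scn.bathymetry, total=300,
                                  seed=1, year=2017)
        opts = kf.TrackerOptions(dt=7200.0, K_h=10.0, record_hours=24.0,
                                 periodic_y=True)
        trajs = kf.advect(sched, scn.fields, scn.bathymetry, opts)
        counts = trajs.state_counts()
        assert sum(counts.values()) == trajs.n_particles == 300

    def test_deterministic_given_seed(self):
        b, f = open_water(u=0.02, v=0.01)
        sched = single_release(30e3, 9e3)
        opts = kf.TrackerOptions(dt=3600.0, K_h=10.0, record_hours=6.0, seed=5)
        t1 = kf.advect(sched, f, b, opts)
        t2 = kf.advect(sched, f, b, opts)
        np.testing.assert_array_equal(t1.xy, t2.xy)

    def test_zero_diffusion_is_seed_independent(self):
        b, f = open_water(u=0.02, v=0.01)
        sched = single_release(30e3, 9e3)
        t1 = kf.advect(sched, f, b,
                       kf.TrackerOptions(dt=3600.0, K_h=0.0, seed=1))
        t2 = kf.advect(sched, f, b,
                       kf.TrackerOptions(dt=3600.0, K_h=0.0, seed=99))
        np.testing.assert_array_equal(t1.xy, t2.xy)

    def test_schedule_outside_field_span_rejected(self):
        b, f = open_water(n_days=5)
        with pytest.raises(ValueError):
            kf.advect(single_release(30e3, 9e3, date="2018-06-01"), f, b,
                      kf.TrackerOptions(dt=3600.0))

    def test_trajectory_round_trip(self, tmp_path):
        b, f = open_water(u=0.02)
        trajs = kf.advect(single_release(30e3, 9e3), f, b,
                          kf.TrackerOptions(dt=3600.0, seed=2))
        path = tmp_path / "trajs.nc"
        trajs.save(path)
        back = kf.TrajectorySet.load(path)
        np.testing.assert_array_equal(back.xy, trajs.xy)
        np.testing.assert_array_equal(back.state, trajs.state)
        np.testing.assert_array_equal(back.record_times, trajs.record_times)
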