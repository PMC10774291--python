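"""Crossing detection, decay weighting, attribution and correlation."""

import numpy as np
import pytest

import kelpflux as kf
from conftest import make_trajectories


def flat_bathy(slope=200.0 / 80_000.0, nx=60, ny=5, dx=2000.0):
    """Depth rising linearly offshore: 200 m reached at 80 km."""
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    depth = np.tile(1.0 + slope * x, (ny, 1))
    return kf.BathymetryGrid(x=x, y=y, depth=depth,
                             land=np.zeros((ny, nx), bool))


def offshore_walkers(bathy, speeds_m_per_day, release_days, n_records=60,
                     y0=4000.0):
    """Hand-built trajectories moving offshore at constant speed from x=0,
    starting at their release day."""
    t0 = np.datetime64("2017-05-01", "s")
    day = np.timedelta64(86400, "s")
    record_times = t0 + day * np.arange(n_records)
    n = len(speeds_m_per_day)
    xy = np.full((n, n_records, 2), np.nan, dtype=np.float32)
    dep = np.full((n, n_records), np.nan, dtype=np.float32)
    for i, (v, d0) in enumerate(zip(speeds_m_per_day, release_days)):
        for r in range(d0, n_records):
            x = min(v * (r - d0), float(bathy.x[-1]))
            xy[i, r] = (x, y0)
            dep[i, r] = bathy.depth_at(x, y0)
    release_times = (t0 + day * np.asarray(release_days)).astype("datetime64[s]")
    release_xy = np.column_stack([np.zeros(n), np.full(n, y0)])
    return make_trajectories(record_times, release_times, release_xy, xy, dep)


class TestFirstCrossing:
    def test_shallow_trajectory_never_crosses(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [100.0], [0])  # 100 m/day: stays shallow
        t0 = trajs.record_times
        out = kf.first_crossing(t0, trajs.xy[0], b, 200.0)
        assert out is None

    def test_monotone_offshore_crossing_matches_kinematics(self):
        b = flat_bathy()
        v = 8000.0  # m/day; 200 m contour at 80 km -> crossing at day 10
        trajs = offshore_walkers(b, [v], [0])
        ages, times = kf.crossing_ages(trajs, 200.0)
        assert ages[0] == pytest.approx(10.0, abs=1e-9)
        t, pos = kf.first_crossing(trajs.record_times, trajs.xy[0], b, 200.0)
        assert t == times[0]
        assert pos[0] == pytest.approx(80_000.0, abs=1.0)

    def test_oscillating_trajectory_takes_first_crossing(self):
        b = flat_bathy()
        t0 = np.datetime64("2017-05-01", "s")
        day = np.timedelta64(86400, "s")
        rec = t0 + day * np.arange(5)
        xs = np.array([70e3, 85e3, 70e3, 90e3, 70e3], dtype=np.float32)
        xy = np.stack([xs, np.full(5, 4000.0, dtype=np.float32)], axis=-1)[None]
        dep = np.array([[b.depth_at(float(x), 4000.0) for x in xs]])
        trajs = make_trajectories(rec, [t0], [[70e3, 4000.0]], xy, dep)
        t, pos = kf.first_crossing(rec, trajs.xy[0], b, 200.0)
        assert t == rec[1]
        assert pos[0] == pytest.approx(85e3)

    def test_non_positive_level_rejected(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0], [0])
        with pytest.raises(ValueError):
            kf.crossing_ages(trajs, 0.0)


class TestExportFractionVsAge:
    def test_step_curve_when_all_cross_together(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0] * 4, [0, 0, 0, 0])
        curves = kf.export_fraction_vs_age(trajs, [200.0], max_age_days=20)
        c = curves[200.0]
        assert c.loc[9.0] == 0.0
        assert c.loc[10.0] == 1.0

    def test_staggered_releases_reproduce_kinematic_ages(self):
        b = flat_bathy()
        # same speed, staggered releases: identical crossing *ages*
        trajs = offshore_walkers(b, [8000.0] * 3, [0, 5, 9])
        ages, _ = kf.crossing_ages(trajs, 200.0)
        np.testing.assert_allclose(ages, 10.0)

    def test_deeper_level_curve_is_contained(self):
        b = flat_bathy(slope=600.0 / 100_000.0)
        trajs = offshore_walkers(b, [6000.0, 9000.0, 2000.0], [0, 2, 4])
        curves = kf.export_fraction_vs_age(trajs, [200.0, 500.0],
                                           max_age_days=40)
        assert np.all(curves[500.0] <= curves[200.0] + 1e-12)


class TestDecay:
    def test_zero_age_keeps_full_mass(self):
        assert kf.decay_weight(0.0) == 1.0

    def test_half_life_near_nine_point_two_days(self):
        model = kf.DecayModel(k=0.075)
        assert model.half_life_days == pytest.approx(np.log(2) / 0.075)
        assert 0.49 <= kf.decay_weight(9.2, model) <= 0.51

    def test_exponential_semigroup(self):
        model = kf.DecayModel(k=0.075)
        t_half = model.half_life_days
        assert kf.decay_weight(2 * t_half, model) == pytest.approx(
            kf.decay_weight(t_half, model) ** 2, rel=1e-12)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            kf.decay_weight(-1.0)


class TestDecayedExport:
    def test_crossing_at_half_life_halves_export(self):
        b = flat_bathy()
        model = kf.DecayModel(k=np.log(2) / 10.0)  # half-life exactly 10 d
        trajs = offshore_walkers(b, [8000.0] * 4, [0, 0, 0, 0])  # cross at 10 d
        frac, band = kf.decayed_export(trajs, model, 200.0)
        assert frac == pytest.approx(0.5, rel=1e-9)
        assert band[0] < frac < band[1]

    def test_vanishing_decay_recovers_undecayed_fraction(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0, 100.0], [0, 0])
        model = kf.DecayModel(k=1e-12)
        frac, _ = kf.decayed_export(trajs, model, 200.0)
        assert frac == pytest.approx(0.5, rel=1e-9)  # 1 of 2 crosses

    def test_mixed_ages_match_hand_summed_weights(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0, 16000.0, 4000.0], [0, 3, 1])
        model = kf.DecayModel(k=0.075)
        ages, _ = kf.crossing_ages(trajs, 200.0)
        expected = np.exp(-0.075 * ages[~np.isnan(ages)]).sum() / 3
        frac, _ = kf.decayed_export(trajs, model, 200.0)
        assert frac == pytest.approx(expected, rel=1e-12)


class TestMonthlyExport:
    def test_single_month_concentration(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0] * 3, [0, 1, 2])  # cross May 11-13
        monthly = kf.monthly_export(trajs)
        assert monthly[5] == pytest.approx(monthly.sum())
        assert monthly.drop(5).sum() == 0.0

    def test_months_sum_to_annual_decayed_export(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0, 3000.0, 2500.0, 100.0],
                                 [0, 5, 10, 0])
        model = kf.DecayModel()
        monthly = kf.monthly_export(trajs, model)
        annual, _ = kf.decayed_export(trajs, model)
        assert monthly.sum() == pytest.approx(100 * annual, rel=1e-12)

    def test_two_month_split_matches_hand_tally(self):
        b = flat_bathy()
        # 8000 m/day from day 0 crosses day 10 (May 11); 3200 m/day from
        # day 8 crosses at age 25 -> day 33 (June 3)
        trajs = offshore_walkers(b, [8000.0, 3200.0], [0, 8])
        model = kf.DecayModel(k=0.075)
        monthly = kf.monthly_export(trajs, model)
        assert monthly[5] == pytest.approx(100 * np.exp(-0.075 * 10) / 2)
        assert monthly[6] == pytest.approx(100 * np.exp(-0.075 * 25) / 2)


class TestPixelContribution:
    def test_single_pixel_holds_total(self):
        b = flat_bathy()
        trajs = offshore_walkers(b, [8000.0] * 3, [0, 0, 0])
        raster, _, _ = kf.pixel_contribution(trajs, b)
        frac, _ = kf.decayed_export(trajs)
        assert raster.sum() == pytest.approx(1000 * frac, rel=1e-9)
        assert (raster > 0).sum() == 1

    def test_non_exporting_pixel_contributes_zero(self):
        b = flat_bathy()
        t0 = np.datetime64("2017-05-01", "s")
        day = np.timedelta64(86400, "s")
        rec = t0 + day * np.arange(15)
        # particle 0 (from y=2000) crosses; particle 1 (y=8000) stays put
        xy = np.full((2, 15, 2), np.nan, dtype=np.float32)
        dep = np.full((2, 15), np.nan, dtype=np.float32)
        for r in range(15):
            xy[0, r] = (min(8000.0 * r, b.x[-1]), 2000.0)
            xy[1, r] = (1000.0, 8000.0)
            dep[0, r] = b.depth_at(float(xy[0, r, 0]), 2000.0)
            dep[1, r] = b.depth_at(1000.0, 8000.0)
        trajs = make_trajectories(rec, [t0, t0], [[0.0, 2000.0], [1000.0, 8000.0]],
                                  xy, dep)
        raster, x_edges, y_edges = kf.pixel_contribution(trajs, b)
        iy1 = np.searchsorted(y_edges, 8000.0) - 1
        ix1 = np.searchsorted(x_edges, 1000.0) - 1
        assert raster[iy1, ix1] == 0.0
        frac, _ = kf.decayed_export(trajs)
        assert raster.sum() == pytest.approx(1000 * frac, rel=1e-9)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(12, dtype=float)
        r, p = kf.export_suitability_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        r, _ = kf.export_suitability_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = rng.random(12)
        y = 0.5 * x + rng.normal(0, 0.1, 12)
        r, _ = kf.export_suitability_correlation(x, y)
        oracle = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_signals(self):
        with pytest.raises(ValueError):
            kf.export_suitability_correlation(np.ones(12), np.arange(12.0))
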