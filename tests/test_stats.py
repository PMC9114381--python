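"""Analysis layer: weighted spread, group tests, distributions, severity."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from _oracles import ks_d_oracle, percentile_type7_oracle, welch_oracle
from firegrowth.io_formats import SeverityRaster
from firegrowth.spread import FireDaySummary
from firegrowth.stats import (ba_weighted_mean_ros, compare_groups,
                              fire_level_severity, ros_distribution,
                              sample_severity, severity_pixels,
                              severity_vs_ros, top_decile_ba_share)


class TestBaWeightedMeanRos:
    def test_hand_computation(self):
        assert ba_weighted_mean_ros([1, 3], [2, 4]) == pytest.approx(3.5)

    def test_constant_ros_unaffected_by_weights(self, rng):
        ba = rng.uniform(0.1, 50, 20)
        assert ba_weighted_mean_ros(ba, np.full(20, 3.3)) == pytest.approx(3.3)

    def test_zero_weight_day_ignored(self):
        assert ba_weighted_mean_ros([0, 5], [100, 1]) == pytest.approx(1.0)

    def test_random_fixtures_match_direct_formula(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            ba = rng.uniform(0, 10, n)
            ros = rng.lognormal(0, 1, n)
            if ba.sum() == 0:
                ba[0] = 1.0
            expected = float((ba * ros).sum() / ba.sum())
            assert ba_weighted_mean_ros(ba, ros) == pytest.approx(expected,
                                                                  rel=1e-12)
            assert ros.min() - 1e-12 <= expected <= ros.max() + 1e-12

    def test_all_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="burned area"):
            ba_weighted_mean_ros([0.0, 0.0], [1.0, 2.0])


class TestCompareGroups:
    def test_identical_samples(self):
        r = compare_groups([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.ks_statistic == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_d_one(self):
        r = compare_groups([1.0, 2.0], [10.0, 20.0])
        assert r.ks_statistic == pytest.approx(1.0)

    def test_welch_and_ks_match_textbook_oracles(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 60)), int(rng.integers(2, 60))
            x = rng.normal(0, 1 + rng.random(), n1)
            y = rng.normal(rng.random(), 1, n2)
            r = compare_groups(x, y)
            t, df = welch_oracle(x, y)
            assert r.t_statistic == pytest.approx(t, rel=1e-10)
            assert r.df == pytest.approx(df, rel=1e-10)
            assert r.ks_statistic == pytest.approx(ks_d_oracle(x, y), abs=1e-12)

    def test_log_transform_epsilon_for_zeros(self):
        x = [0.0, 1.0, 2.0, 4.0]
        y = [0.5, 1.0, 3.0, 8.0]
        r = compare_groups(x, y, log_transform=True)
        assert r.log_epsilon == pytest.approx(0.25)  # half the smallest positive
        t, _ = welch_oracle(np.log(np.array(x) + 0.25),
                            np.log(np.array(y) + 0.25))
        assert r.t_statistic == pytest.approx(t, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([2.0, 2.0], [2.0, 2.0])


def _days(ros_area_pairs):
    return [FireDaySummary("F", i + 2, ros_p95=r, ros_mean=r,
                           expansion_area_km2=a, cumulative_area_km2=0.0,
                           mean_frp=1.0, n_line_detections=1)
            for i, (r, a) in enumerate(ros_area_pairs)]


class TestRosDistribution:
    def test_single_bin_is_100_percent(self):
        h = ros_distribution(_days([(0.3, 1.0)] * 10), by="fire_day",
                             bins=[0, 0.5, 1.0])
        assert h.percent.iloc[0] == pytest.approx(100.0)

    def test_burned_area_weighting(self):
        h = ros_distribution(_days([(0.3, 1.0), (6.0, 99.0)]),
                             by="burned_area", bins=[0, 1, 10])
        assert h.percent.iloc[1] == pytest.approx(99.0)

    def test_both_modes_sum_to_100(self, rng):
        days = _days([(float(r), float(a)) for r, a in
                      zip(rng.lognormal(0, 1, 200), rng.uniform(0, 5, 200))])
        for by in ("fire_day", "burned_area"):
            h = ros_distribution(days, by=by, bins=np.arange(0, 50, 0.5))
            assert h.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_gives_empty_histogram(self):
        assert ros_distribution([], by="fire_day").empty


class TestTopDecileBaShare:
    def test_uniform_days(self):
        days = _days([(1.0, 2.0)] * 10)
        # all ROS tied: every day sits at the cutoff, so the "decile" is all
        assert top_decile_ba_share(days) == pytest.approx(100.0)

    def test_one_dominant_day(self):
        days = _days([(1.0, 1.0)] * 9 + [(10.0, 90.0)])
        assert top_decile_ba_share(days) == pytest.approx(90.0 / 99.0 * 100)

    def test_skew_increases_concentration(self, rng):
        shares = []
        for sigma in (0.2, 0.7, 1.3):
            ros = rng.lognormal(0, sigma, 600)
            days = _days([(float(r), float(r**2)) for r in ros])
            shares.append(top_decile_ba_share(days))
        assert shares == sorted(shares)
        assert shares[-1] > 30.0


def _raster(values, cellsize=30.0):
    return SeverityRaster("dNBR", np.asarray(values, float), xll=0.0, yll=0.0,
                          cellsize=cellsize)


class TestSampleSeverity:
    def test_constant_raster(self):
        r = _raster(np.full((10, 10), 300.0))
        poly = Polygon([(30, 30), (270, 30), (270, 270), (30, 270)])
        s = sample_severity(r, poly)
        assert s.mean == s.p95 == 300.0

    def test_four_pixel_polygon(self):
        r = _raster([[0.0, 100.0], [200.0, 300.0]])
        poly = Polygon([(0, 0), (60, 0), (60, 60), (0, 60)])
        s = sample_severity(r, poly)
        assert s.n_pixels == 4
        assert s.mean == pytest.approx(150.0)
        assert s.p95 == pytest.approx(
            percentile_type7_oracle([0, 100, 200, 300], 95))

    def test_pixel_center_rule(self):
        r = _raster([[1.0, 2.0]])
        # polygon covers the first pixel's center only
        poly = Polygon([(0, 0), (29, 0), (29, 29), (0, 29)])
        s = sample_severity(r, poly)
        assert s.n_pixels == 1 and s.mean == 1.0

    def test_all_nodata_returns_none(self):
        r = _raster(np.full((4, 4), -9999.0))
        poly = Polygon([(0, 0), (120, 0), (120, 120), (0, 120)])
        assert sample_severity(r, poly) is None


class TestSeverityVsRos:
    def test_exact_line(self):
        x = np.linspace(0, 5, 20)
        fit = severity_vs_ros(x, 2 * x + 1)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_null_permutation_r2_near_zero(self, rng):
        x = rng.lognormal(0, 1, 200)
        y = rng.permutation(2 * x)
        fit = severity_vs_ros(x, y)
        assert fit.r_squared < 0.05

    def test_noisy_recovery_positive_slope(self, rng):
        x = rng.uniform(0, 5, 300)
        y = 15 + 16.5 * x + rng.normal(0, 5, 300)
        fit = severity_vs_ros(x, y)
        assert fit.slope == pytest.approx(16.5, rel=0.1)
        assert fit.p_value < 1e-6
        assert fit.f_statistic > 0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            severity_vs_ros([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_running_mean_tracks_monotone_signal(self, rng):
        x = rng.uniform(0, 5, 400)
        y = x**2 + rng.normal(0, 0.5, 400)
        fit = severity_vs_ros(x, y)
        rm = fit.running_mean.response_mean.to_numpy()
        assert rm[-1] > rm[0]  # running mean rises with ROS


class TestFireLevelSeverity:
    def _daily(self, means, npix):
        from firegrowth.stats import SeveritySummary
        return [SeveritySummary("F", i + 1, "dNBR", m, m, n)
                for i, (m, n) in enumerate(zip(means, npix))]

    def test_single_day_equals_day_value(self):
        assert fire_level_severity(self._daily([250.0], [10])) == 250.0

    def test_pixel_weighted_mean(self):
        got = fire_level_severity(self._daily([100.0, 300.0], [20, 20]))
        assert got == pytest.approx(200.0)
        got = fire_level_severity(self._daily([100.0, 300.0], [30, 10]))
        assert got == pytest.approx(150.0)

    def test_maximum_mode_matches_brute_force(self, rng):
        vals = rng.uniform(0, 500, (20, 20))
        r = _raster(vals)
        poly = Polygon([(0, 0), (600, 0), (600, 600), (0, 600)])
        got = fire_level_severity([], mode="maximum", raster=r,
                                  burned_polygon=poly)
        assert got == pytest.approx(
            percentile_type7_oracle(severity_pixels(r, poly), 95))
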