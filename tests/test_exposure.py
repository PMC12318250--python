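"""Temporal interpolation schemes and exposure summaries."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from heatpath import exposure, hexgrid, trajectory
from heatpath.exposure import (
    airtemp_at,
    bracket_scenes,
    diurnal_weights,
    interval_means,
    lst_at,
    maximum_of_intervals,
    weighted_mean,
)
from heatpath.geo import RasterSeries
from tests.conftest import TZ, constant_scene, make_path


def single_series(values_by_date, crs):
    scenes = {d: constant_scene(v, day=d, crs=crs) for d, v in values_by_date.items()}
    return RasterSeries(kind="single_valued", scenes=scenes)


def pair_series(maxmin_by_date, crs):
    scenes = {
        d: (constant_scene(mx, day=d, crs=crs), constant_scene(mn, day=d, crs=crs))
        for d, (mx, mn) in maxmin_by_date.items()
    }
    return RasterSeries(kind="max_min_pair", scenes=scenes)


def fixed_sunrise(hour=6, minute=30):
    def provider(d):
        return datetime(d.year, d.month, d.day, hour, minute, tzinfo=TZ)

    return provider


class TestSceneBracketing:
    def test_worked_example_weights(self, crs):
        """Scenes Mar 9 / Mar 25, index Mar 15: weights 16/6 and 16/10."""
        s = single_series({date(2015, 3, 9): 30.0, date(2015, 3, 25): 32.0}, crs)
        pair = bracket_scenes(date(2015, 3, 15), s)
        assert pair.wt_earlier == pytest.approx(16.0 / 6.0)
        assert pair.wt_later == pytest.approx(16.0 / 10.0)
        assert lst_at(0.0, 0.0, date(2015, 3, 15), s) == pytest.approx(30.75)

    def test_index_on_scene_date_full_weight(self, crs):
        s = single_series({date(2015, 3, 9): 30.0, date(2015, 3, 25): 32.0}, crs)
        assert lst_at(0.0, 0.0, date(2015, 3, 9), s) == 30.0
        assert lst_at(0.0, 0.0, date(2015, 3, 25), s) == 32.0

    def test_midway_index_simple_average(self, crs):
        s = single_series({date(2015, 3, 9): 30.0, date(2015, 3, 25): 32.0}, crs)
        assert lst_at(0.0, 0.0, date(2015, 3, 17), s) == pytest.approx(31.0)

    def test_outside_span_nearest_scene(self, crs):
        s = single_series({date(2015, 3, 9): 30.0, date(2015, 3, 25): 32.0}, crs)
        assert lst_at(0.0, 0.0, date(2015, 3, 1), s) == 30.0
        assert lst_at(0.0, 0.0, date(2015, 4, 5), s) == 32.0

    def test_equal_scene_values_any_date(self, crs):
        s = single_series({date(2015, 3, 9): 28.0, date(2015, 3, 25): 28.0}, crs)
        for day in range(9, 26):
            assert lst_at(0.0, 0.0, date(2015, 3, day), s) == pytest.approx(28.0)

    def test_monotone_approach_to_later_scene(self, crs):
        s = single_series({date(2015, 3, 9): 30.0, date(2015, 3, 25): 32.0}, crs)
        vals = [lst_at(0.0, 0.0, date(2015, 3, 9) + timedelta(days=k), s)
                for k in range(17)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(30.0 <= v <= 32.0 for v in vals)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            bracket_scenes(date(2015, 1, 1),
                           RasterSeries(kind="single_valued", scenes={}))


class TestDiurnalWeights:
    def test_at_3pm_full_weight_on_maximum(self, crs):
        sun = fixed_sunrise()
        t = datetime(2015, 7, 1, 15, 0, tzinfo=TZ)
        s = pair_series({date(2015, 7, 1): (30.0, 10.0)}, crs)
        assert airtemp_at(0.0, 0.0, t, s, sun) == 30.0

    def test_at_sunrise_full_weight_on_minimum(self, crs):
        sun = fixed_sunrise(6, 30)
        t = datetime(2015, 7, 1, 6, 30, tzinfo=TZ)
        s = pair_series({date(2015, 7, 1): (30.0, 10.0)}, crs)
        assert airtemp_at(0.0, 0.0, t, s, sun) == 10.0

    def test_midpoint_equal_weights(self, crs):
        sun = fixed_sunrise(7, 0)
        # midpoint between 07:00 sunrise and 15:00 is 11:00
        t = datetime(2015, 7, 1, 11, 0, tzinfo=TZ)
        s = pair_series({date(2015, 7, 1): (30.0, 10.0)}, crs)
        assert airtemp_at(0.0, 0.0, t, s, sun) == pytest.approx(20.0)
        w = diurnal_weights(t, sun(date(2015, 7, 1)))
        assert w.wt_max == pytest.approx(w.wt_min)

    def test_weight_ratio_is_inverse_distance_ratio(self):
        sun_t = datetime(2015, 7, 1, 6, 0, tzinfo=TZ)
        t = datetime(2015, 7, 1, 9, 0, tzinfo=TZ)
        w = diurnal_weights(t, sun_t)
        a = 6.0  # hours to 15:00
        b = 3.0  # hours since sunrise
        assert w.wt_max / w.wt_min == pytest.approx(b / a)

    def test_equal_max_min_any_time(self, crs):
        sun = fixed_sunrise()
        s = pair_series({date(2015, 7, 1): (22.0, 22.0)}, crs)
        for hr in range(24):
            t = datetime(2015, 7, 1, hr, 17, tzinfo=TZ)
            assert airtemp_at(0.0, 0.0, t, s, sun) == pytest.approx(22.0)

    def test_result_bounded_by_extremes_random_times(self, crs):
        rng = np.random.default_rng(9)
        sun = fixed_sunrise(6, 13)
        s = pair_series({date(2015, 7, 1): (31.5, 12.25)}, crs)
        for _ in range(1000):
            t = datetime(2015, 7, 1, tzinfo=TZ) + timedelta(
                seconds=int(rng.integers(0, 86400))
            )
            v = airtemp_at(0.0, 0.0, t, s, sun)
            assert 12.25 <= v <= 31.5

    def test_missing_date_signalled(self, crs):
        sun = fixed_sunrise()
        s = pair_series({date(2015, 7, 1): (30.0, 10.0)}, crs)
        with pytest.raises(exposure.MissingValueError):
            airtemp_at(0.0, 0.0, datetime(2015, 7, 5, 9, 0, tzinfo=TZ), s, sun)


class TestWeightedMean:
    def test_constant_values(self):
        assert weighted_mean([5.0, 5.0, 5.0], [1.0, 10.0, 3.0]) == 5.0

    def test_hand_computed_example(self):
        # 30 degC for 3 h and 34 degC for 1 h -> 31
        assert weighted_mean([30.0, 34.0], [3.0, 1.0]) == pytest.approx(31.0)

    def test_equal_durations_reduce_to_simple_mean(self):
        rng = np.random.default_rng(0)
        v = rng.normal(20, 5, 50)
        assert weighted_mean(v, np.full(50, 60.0)) == pytest.approx(
            float(v.mean()), abs=1e-12
        )

    def test_nan_values_dropped_with_durations(self):
        v = [10.0, np.nan, 30.0]
        d = [60.0, 1e6, 60.0]
        assert weighted_mean(v, d) == pytest.approx(20.0)

    def test_zero_total_duration_signalled(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])


class TestIntervalMeans:
    def test_constant_exposure(self, crs):
        t = pd.date_range("2015-07-01 08:00", periods=60, freq="min", tz=TZ)
        means = interval_means(t, np.full(60, 25.0))
        assert np.allclose(means, 25.0)
        assert maximum_of_intervals(t, np.full(60, 25.0)) == 25.0

    def test_single_hot_bin_sets_maximum(self, crs):
        t = pd.date_range("2015-07-01 08:00", periods=200, freq="min", tz=TZ)
        v = np.full(200, 20.0)
        v[100] = 30.0
        v[105] = 40.0  # same 10-min bin as index 100
        assert maximum_of_intervals(t, v) == pytest.approx(
            (30.0 + 40.0 + 8 * 20.0) / 10.0
        )

    def test_translation_by_whole_bins_invariant(self):
        rng = np.random.default_rng(1)
        v = rng.normal(20, 3, 120)
        t = pd.date_range("2015-07-01 08:00", periods=120, freq="min", tz=TZ)
        m1 = maximum_of_intervals(t, v)
        m2 = maximum_of_intervals(t + pd.Timedelta(minutes=30), v)
        assert m1 == m2

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 80))
            offs = np.sort(rng.choice(np.arange(0, 300), size=n, replace=False))
            t = pd.Timestamp("2015-07-01 08:00", tz=TZ) + pd.to_timedelta(
                offs, unit="min"
            )
            v = rng.normal(20, 5, n)
            got = interval_means(pd.Series(t), v)
            bins = {}
            for o, val in zip(offs, v):
                bins.setdefault((o - offs[0]) // 10, []).append(val)
            want = [np.mean(bins[k]) for k in sorted(bins)]
            assert np.allclose(got, want)


class TestSummaries:
    def _stay_at_home(self, crs, grid):
        cx, cy = grid.centroid(hexgrid.assign_hex(grid, 123.0, -456.0))
        path = make_path("p", range(300), np.full(300, cx), np.full(300, cy), crs)
        # pin coordinates exactly at the centroid
        path.frame["x"] = cx
        path.frame["y"] = cy
        return path, hexgrid.infer_home(path, grid)

    def test_stay_at_home_constant_surface(self, crs):
        grid = hexgrid.hex_grid((-6000, -6000, 6000, 6000), 62.0)
        path, home = self._stay_at_home(crs, grid)
        s = single_series({date(2015, 10, 1): 27.0, date(2015, 10, 16): 27.0}, crs)
        mob = exposure.mobility_summary(path, s, "lst")
        res = exposure.residence_summary(path, home, s, "lst")
        for summ in (mob, res):
            assert summ.mean_incl_nonwear == pytest.approx(27.0)
            assert summ.maximum == pytest.approx(27.0)
        assert mob.mean_incl_nonwear == res.mean_incl_nonwear
        assert mob.maximum == res.maximum

    def test_stay_at_home_identity_on_heterogeneous_surface(self, crs):
        grid = hexgrid.hex_grid((-6000, -6000, 6000, 6000), 62.0)
        path, home = self._stay_at_home(crs, grid)
        rng = np.random.default_rng(5)
        sc1 = constant_scene(0.0, day=date(2015, 10, 1), crs=crs)
        sc1.values = rng.normal(30, 8, sc1.values.shape)
        sc2 = constant_scene(0.0, day=date(2015, 10, 16), crs=crs)
        sc2.values = rng.normal(30, 8, sc2.values.shape)
        s = RasterSeries(kind="single_valued",
                         scenes={sc1.scene_date: sc1, sc2.scene_date: sc2})
        mob = exposure.mobility_summary(path, s, "lst")
        res = exposure.residence_summary(path, home, s, "lst")
        assert mob.mean_incl_nonwear == res.mean_incl_nonwear
        assert mob.mean_excl_nonwear == res.mean_excl_nonwear
        # maxima follow different aggregation rules (day-level vs 10-min
        # bins) that coincide mathematically for a stay-at-home path
        assert mob.maximum == pytest.approx(res.maximum, abs=1e-9)

    def test_nonwear_exclusion_changes_only_excl_mean(self, crs):
        # day at 30 degC zone, overnight gap at 20 degC home
        minutes = list(range(60)) + [60 + 8 * 60] + list(range(60 + 8 * 60 + 1,
                                                                60 + 8 * 60 + 30))
        n = len(minutes)
        x = np.concatenate([np.full(60, 3000.0), np.full(n - 60, -3000.0)])
        path = make_path("p", minutes, x, np.zeros(n), crs)
        sc = constant_scene(0.0, crs=crs)
        sc.values[:, sc.values.shape[1] // 2:] = 30.0
        sc.values[:, : sc.values.shape[1] // 2] = 20.0
        s = RasterSeries(kind="single_valued", scenes={sc.scene_date: sc})
        summ = exposure.mobility_summary(path, s, "lst")
        r = path.retained()
        dur = r["dt_s"].to_numpy()
        vals = np.where(r["x"].to_numpy() > 0, 30.0, 20.0)
        want_incl = np.sum(vals * dur) / dur.sum()
        wear = r["wear"].to_numpy()
        want_excl = np.sum(vals[wear] * dur[wear]) / dur[wear].sum()
        assert summ.mean_incl_nonwear == pytest.approx(want_incl)
        assert summ.mean_excl_nonwear == pytest.approx(want_excl)
        assert want_incl != pytest.approx(want_excl)

    def test_residence_lst_maximum_is_day_level_scan(self, crs):
        grid = hexgrid.hex_grid((-6000, -6000, 6000, 6000), 62.0)
        rng = np.random.default_rng(6)
        days = [date(2015, 10, 1) + timedelta(days=15 * k) for k in range(3)]
        scenes = {}
        for d in days:
            sc = constant_scene(0.0, day=d, crs=crs)
            sc.values = rng.normal(30, 8, sc.values.shape)
            scenes[d] = sc
        s = RasterSeries(kind="single_valued", scenes=scenes)
        # pings spanning 5 calendar dates at a fixed non-home-cell location
        minutes = np.arange(0, 5 * 1440, 13)
        path = make_path("p", minutes, np.full(len(minutes), 70.0),
                         np.full(len(minutes), 70.0), crs)
        home = hexgrid.infer_home(path, grid)
        res = exposure.residence_summary(path, home, s, "lst")
        follow_dates = sorted(set(path.retained()["t"].dt.date))
        brute = max(lst_at(home.x, home.y, d, s) for d in follow_dates)
        assert res.maximum == pytest.approx(brute, abs=1e-12)

    def test_residence_airtemp_maximum_over_home_bins(self, crs):
        grid = hexgrid.hex_grid((-6000, -6000, 6000, 6000), 62.0)
        sun = fixed_sunrise(6, 45)
        days = [date(2015, 10, 1) + timedelta(days=k) for k in range(3)]
        s = pair_series(
            {days[0]: (28.0, 12.0), days[1]: (35.0, 14.0), days[2]: (30.0, 13.0)},
            crs,
        )
        minutes = np.arange(0, 3 * 1440, 10)
        path = make_path("p", minutes, np.full(len(minutes), 50.0),
                         np.full(len(minutes), 50.0), crs,
                         start=datetime(2015, 10, 1, 0, 0, tzinfo=TZ))
        home = hexgrid.infer_home(path, grid)
        res = exposure.residence_summary(path, home, s, "airtemp", sun)
        r = path.retained()
        vals = np.array(
            [
                airtemp_at(home.x, home.y, ts.to_pydatetime(), s, sun)
                for ts in r["t"]
            ]
        )
        brute = maximum_of_intervals(r["t"], vals)
        assert res.maximum == pytest.approx(brute, abs=1e-12)
        # hottest day's near-3pm bin dominates
        assert 30.0 < res.maximum <= 35.0

    def test_nodata_scene_falls_back_to_other(self, crs):
        sc1 = constant_scene(30.0, day=date(2015, 10, 1), crs=crs)
        sc1.values[:] = np.nan
        sc2 = constant_scene(32.0, day=date(2015, 10, 16), crs=crs)
        s = RasterSeries(kind="single_valued",
                         scenes={sc1.scene_date: sc1, sc2.scene_date: sc2})
        assert lst_at(0.0, 0.0, date(2015, 10, 8), s) == 32.0
        sc2.values[:] = np.nan
        with pytest.raises(exposure.MissingValueError):
            lst_at(0.0, 0.0, date(2015, 10, 8), s)
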