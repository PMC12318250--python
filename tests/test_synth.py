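"""Synthetic world generator: determinism, emulation targets, closed forms."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from heatpath import synth, trajectory
from tests.conftest import TZ


class TestHeatSurface:
    def test_same_seed_bit_identical(self, small_world):
        lst1, at1 = synth.simulate_heat_surface(small_world)
        lst2, at2 = synth.simulate_heat_surface(small_world)
        assert lst1.dates == lst2.dates
        for d in lst1.dates:
            assert np.array_equal(lst1.scenes[d].values, lst2.scenes[d].values)
        for d in at1.dates:
            assert np.array_equal(at1.scenes[d][0].values, at2.scenes[d][0].values)
            assert np.array_equal(at1.scenes[d][1].values, at2.scenes[d][1].values)

    def test_zero_spatial_sd_gives_constant_scenes(self, small_world):
        cfg = synth.WorldConfig(
            domain_km=small_world.domain_km, n_days=4, seed=1,
            lst=synth.LstLikeConfig(cell_size_m=200.0, spatial_sd=0.0),
            at=synth.AtLikeConfig(cell_size_m=3000.0, spatial_sd_max=0.0,
                                  spatial_sd_min=0.0),
        )
        lst, at = synth.simulate_heat_surface(cfg)
        for sc in lst.scenes.values():
            assert np.ptp(sc.values) == 0.0
        for mx, mn in at.scenes.values():
            assert np.ptp(mx.values) == 0.0
            assert np.ptp(mn.values) == 0.0

    def test_within_scene_sd_matches_configured(self, small_world):
        lst, _ = synth.simulate_heat_surface(small_world)
        sds = [sc.values.std() for sc in lst.scenes.values()]
        assert np.mean(sds) == pytest.approx(small_world.lst.spatial_sd, rel=0.15)

    def test_at_max_at_least_min_everywhere(self, small_world):
        _, at = synth.simulate_heat_surface(small_world)
        for mx, mn in at.scenes.values():
            assert np.all(mx.values >= mn.values)

    def test_scene_schedule_and_endpoints_kept(self, small_world):
        cfg = synth.WorldConfig(
            domain_km=(12.0, 12.0), n_days=4, seed=2, margin_days=30,
            lst=synth.LstLikeConfig(cell_size_m=300.0, scene_drop_prob=0.8),
            at=synth.AtLikeConfig(cell_size_m=3000.0),
        )
        lst, _ = synth.simulate_heat_surface(cfg)
        first = cfg.start - timedelta(days=30)
        assert first in lst.scenes
        offsets = [(d - first).days for d in lst.dates]
        assert all(o % cfg.lst.cadence_days == 0 for o in offsets)
        assert min(lst.dates) <= cfg.start
        assert max(lst.dates) >= cfg.start + timedelta(days=cfg.n_days)

    def test_hot_zone_raises_values_inside_only(self):
        hz = synth.HotZone(x=2000.0, y=2000.0, radius_m=800.0, excess_c=5.0)
        cfg = synth.WorldConfig(
            domain_km=(12.0, 12.0), n_days=2, seed=3, hot_zone=hz,
            lst=synth.LstLikeConfig(cell_size_m=200.0, spatial_sd=0.0),
            at=synth.AtLikeConfig(cell_size_m=3000.0, spatial_sd_max=0.0,
                                  spatial_sd_min=0.0),
        )
        lst, _ = synth.simulate_heat_surface(cfg)
        sc = lst.scenes[min(lst.dates)]
        inside = sc.sample(np.asarray(2000.0), np.asarray(2000.0))
        outside = sc.sample(np.asarray(-4000.0), np.asarray(-4000.0))
        assert float(inside) - float(outside) == pytest.approx(5.0)

    def test_domain_smaller_than_cell_rejected(self):
        cfg = synth.WorldConfig(domain_km=(2.0, 2.0),
                                at=synth.AtLikeConfig(cell_size_m=4000.0))
        with pytest.raises(ValueError):
            synth.simulate_heat_surface(cfg)


class TestCohort:
    def test_same_seed_identical_cohort(self, small_world):
        cfg = synth.CohortConfig(n_participants=3, followup_days=3,
                                 mean_daily_km=10.0, home_margin_km=4.0, seed=7)
        p1, t1, c1 = synth.simulate_cohort(cfg, small_world)
        p2, t2, c2 = synth.simulate_cohort(cfg, small_world)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(c1, c2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.daily_km, b.daily_km)

    def test_adding_participant_preserves_existing(self, small_world):
        kw = dict(followup_days=2, mean_daily_km=10.0, home_margin_km=4.0, seed=7)
        p3, _, _ = synth.simulate_cohort(synth.CohortConfig(n_participants=3, **kw),
                                         small_world)
        p4, _, _ = synth.simulate_cohort(synth.CohortConfig(n_participants=4, **kw),
                                         small_world)
        pd.testing.assert_frame_equal(
            p3, p4[p4.participant_id.isin(p3.participant_id.unique())]
            .reset_index(drop=True)
        )

    def test_zero_trips_all_pings_at_home(self, small_world, crs):
        cfg = synth.CohortConfig(n_participants=2, followup_days=3,
                                 trips_per_day=0, home_margin_km=4.0, seed=1)
        pings, truths, _ = synth.simulate_cohort(cfg, small_world)
        for tr in truths:
            sub = pings[pings.participant_id == tr.participant_id]
            x, y = crs.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
            d = np.hypot(x - tr.home_x, y - tr.home_y)
            assert np.all(d < 1.0)  # projection round-trip noise only
            path = trajectory.build_paths(sub, crs)[tr.participant_id]
            frac = trajectory.fraction_time_near(path, (tr.home_x, tr.home_y))
            assert frac == 1.0
            assert np.all(tr.daily_km == 0.0)

    def test_cohort_emulates_study_mobility_targets(self):
        """n=100 with defaults: ~59 km/day and ~74% time at home."""
        world = synth.WorldConfig(seed=3)
        cfg = synth.CohortConfig(n_participants=100, seed=3)
        pings, truths, _ = synth.simulate_cohort(cfg, world)
        crs = world.crs
        km = []
        frac = []
        for tr in truths[:30]:  # distance recomputed from emitted pings
            sub = pings[pings.participant_id == tr.participant_id]
            path = trajectory.build_paths(sub, crs)[tr.participant_id]
            km.append(trajectory.daily_distance(path).mean())
            frac.append(
                trajectory.fraction_time_near(path, (tr.home_x, tr.home_y))
            )
        # pings reproduce the generator's own bookkeeping
        truth_km = np.mean([t.daily_km.mean() for t in truths[:30]])
        assert np.mean(km) == pytest.approx(truth_km, rel=0.01)
        # and the full-cohort truth hits the configured targets
        all_km = np.mean([t.daily_km.mean() for t in truths])
        assert all_km == pytest.approx(cfg.mean_daily_km, rel=0.10)
        assert np.mean(frac) == pytest.approx(cfg.fraction_time_home, rel=0.15)

    def test_wear_window_and_overnight_gap(self, small_world, crs):
        cfg = synth.CohortConfig(n_participants=1, followup_days=3,
                                 mean_daily_km=10.0, home_margin_km=4.0, seed=5)
        pings, truths, _ = synth.simulate_cohort(cfg, small_world)
        path = trajectory.build_paths(pings, crs)["P0000"]
        r = path.retained()
        wear_h = r.loc[r["wear"], "dt_s"].groupby(r["t"].dt.date).sum() / 3600.0
        # each full day's wear is near the configured 13.3 h
        assert np.all(np.abs(wear_h.iloc[:-1] - 13.3) < 0.6)
        gaps = r.loc[~r["wear"] & (r["dt_s"] > 0), "dt_s"] / 3600.0
        assert len(gaps) == 2  # one overnight gap between consecutive days
        assert np.all((gaps > 9.0) & (gaps < 12.5))
        # gap is bracketed at home
        for i in r.index[~r["wear"] & (r["dt_s"] > 0)]:
            d = np.hypot(r.loc[i, "x"] - truths[0].home_x,
                         r.loc[i, "y"] - truths[0].home_y)
            assert d < 1.0

    def test_covariate_labels_follow_frequencies(self, small_world):
        cfg = synth.CohortConfig(n_participants=300, followup_days=1,
                                 trips_per_day=0, home_margin_km=4.0, seed=9)
        _, _, cov = synth.simulate_cohort(cfg, small_world)
        freq = cov["sex"].value_counts(normalize=True)
        assert freq["female"] == pytest.approx(0.559, abs=0.08)
        assert set(cov.columns) == {"participant_id", "age_group", "sex",
                                    "income", "race_ethnicity"}

    def test_infeasible_config_rejected(self, small_world):
        cfg = synth.CohortConfig(n_participants=1, mean_daily_km=200.0,
                                 speed_kmh=10.0, home_margin_km=4.0, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            synth.simulate_cohort(cfg, small_world)


class TestAnalyticTruth:
    def test_always_home_constant_surface(self):
        blocks = [synth.SiteBlock(0.0, 0.0, 100)]
        mob, res = synth.analytic_exposure_truth(blocks, (0.0, 0.0), 25.0, None)
        assert mob == 25.0
        assert res == 25.0

    def test_fraction_in_zone_hand_bookkeeping(self):
        hz = synth.HotZone(x=3000.0, y=0.0, radius_m=500.0, excess_c=4.0)
        # 60 weighted minutes at home, 40 at the zone centre, last ping home
        blocks = [
            synth.SiteBlock(0.0, 0.0, 30),
            synth.SiteBlock(3000.0, 0.0, 40),
            synth.SiteBlock(0.0, 0.0, 31),
        ]
        mob, res = synth.analytic_exposure_truth(blocks, (0.0, 0.0), 20.0, hz)
        assert mob == pytest.approx(20.0 + 0.4 * 4.0)
        assert res == 20.0

    def test_zero_excess_equalises_methods(self):
        hz = synth.HotZone(x=3000.0, y=0.0, radius_m=500.0, excess_c=0.0)
        blocks = [synth.SiteBlock(0.0, 0.0, 50), synth.SiteBlock(3000.0, 0.0, 51)]
        mob, res = synth.analytic_exposure_truth(blocks, (0.0, 0.0), 20.0, hz)
        assert mob == res == 20.0

    def test_schedule_pings_are_minute_spaced(self, crs):
        blocks = [synth.SiteBlock(0.0, 0.0, 5), synth.SiteBlock(100.0, 0.0, 5)]
        start = datetime(2015, 10, 2, 9, 0, tzinfo=TZ)
        df = synth.deterministic_schedule_pings("p", blocks, start, crs)
        assert len(df) == 10
        dt = df["t"].diff().dropna().dt.total_seconds()
        assert (dt == 60.0).all()
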