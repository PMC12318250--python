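"""End-to-end pipeline: simulate -> assess -> compare.

``simulate`` writes a synthetic world (pings CSV, per-scene GeoTIFFs,
truth and covariate tables, resolved config).  ``assess`` cleans the GPS
record, infers homes, and computes the four exposure summaries per
participant and indicator.  ``compare`` produces the overall and
stratified method-comparison tables and histogram counts.  All stages are
deterministic functions of their config and seeds, so identical runs
produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import compare as cmp
from . import exposure, geo, hexgrid, synth, trajectory
from .solar import SunriseTable

__all__ = [
    "ProcessingConfig",
    "StudyConfig",
    "run_simulate",
    "run_assess",
    "run_compare",
    "load_config",
    "save_config",
]

INDICATORS = ("lst", "airtemp")


@dataclass
class ProcessingConfig:
    vmax_mph: float = 100.0
    valid_day_hours: float = 10.0
    hex_side_m: float = 62.0
    home_radius_m: float = 200.0
    minute_rule: str = "first"
    interval_width_min: float = 10.0
    hist_bin_width_means: float = 0.25
    hist_bin_width_maximums: float = 0.5
    strata: tuple = ("daily_distance_tertile", "age_group", "sex",
                     "income", "race_ethnicity")


@dataclass
class StudyConfig:
    world: synth.WorldConfig = field(default_factory=synth.WorldConfig)
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    w = dict(raw.get("world", {}))
    if "lst" in w:
        w["lst"] = synth.LstLikeConfig(**w["lst"])
    if "at" in w:
        w["at"] = synth.AtLikeConfig(**w["at"])
    if w.get("hot_zone") is not None:
        w["hot_zone"] = synth.HotZone(**w["hot_zone"])
    if "start" in w:
        w["start"] = date.fromisoformat(w["start"])
    if "domain_km" in w:
        w["domain_km"] = tuple(w["domain_km"])
    if "center_lonlat" in w:
        w["center_lonlat"] = tuple(w["center_lonlat"])
    c = dict(raw.get("cohort", {}))
    p = dict(raw.get("processing", {}))
    if "strata" in p:
        p["strata"] = tuple(p["strata"])
    return StudyConfig(
        world=synth.WorldConfig(**w),
        cohort=synth.CohortConfig(**c),
        processing=ProcessingConfig(**p),
    )


def run_simulate(cfg: StudyConfig, outdir) -> dict:
    """Generate and write the synthetic world; returns in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lst, at = synth.simulate_heat_surface(cfg.world)
    pings, truths, covariates = synth.simulate_cohort(cfg.cohort, cfg.world)
    geo.write_pings(pings, outdir / "pings.csv")
    geo.write_series(lst, outdir / "rasters" / "lst")
    geo.write_series(at, outdir / "rasters" / "airtemp")
    covariates.to_csv(outdir / "covariates.csv", index=False)
    truth_df = pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "home_x": t.home_x,
                "home_y": t.home_y,
                "mean_daily_km": float(np.mean(t.daily_km)),
            }
            for t in truths
        ]
    )
    truth_df.to_csv(outdir / "truth.csv", index=False)
    save_config(cfg, outdir / "config.yaml")
    return {"pings": pings, "lst": lst, "airtemp": at, "truths": truths,
            "covariates": covariates}


def study_area_polygon(world: synth.WorldConfig):
    hx, hy = world.half_extent_m
    return shapely.box(-hx, -hy, hx, hy)


def run_assess(pings: pd.DataFrame, lst: geo.RasterSeries, at: geo.RasterSeries,
               cfg: StudyConfig, outdir=None) -> dict:
    """Clean paths, infer homes, and compute all exposure summaries.

    Returns a dict with ``paths``, ``homes``, ``exposures`` (long table)
    and ``descriptives`` (per-participant mobility measures).  Optionally
    writes the cleaned-path, homes, exposures and descriptives CSVs.
    """
    world = cfg.world
    proc = cfg.processing
    crs = world.crs
    area = study_area_polygon(world)
    hx, hy = world.half_extent_m
    grid = hexgrid.hex_grid((-hx, -hy, hx, hy), proc.hex_side_m)
    sun = SunriseTable(world.center_lonlat[1], world.center_lonlat[0],
                       world.utc_offset_hours)

    paths = trajectory.build_paths(pings, crs, minute_rule=proc.minute_rule)
    homes = {}
    exp_rows = []
    desc_rows = []
    kept_paths = {}
    for pid in sorted(paths):
        path = paths[pid]
        trajectory.filter_speed(path, proc.vmax_mph)
        trajectory.clip_area(path, area)
        valid = trajectory.select_valid_days(path, proc.valid_day_hours)
        if not valid:
            continue  # participant needs at least one valid day
        kept_paths[pid] = path
        home = hexgrid.infer_home_with_crosscheck(path, grid)
        homes[pid] = home
        dist = trajectory.daily_distance(path)
        frac_home = trajectory.fraction_time_near(
            path, (home.x, home.y), proc.home_radius_m
        )
        lon_home, lat_home = crs.inverse(home.x, home.y)
        desc_rows.append(
            {
                "participant_id": pid,
                "n_valid_days": len(valid),
                "mean_daily_km": float(dist.mean()) if len(dist) else 0.0,
                "pct_time_home": 100.0 * frac_home,
                "home_x": home.x,
                "home_y": home.y,
                "home_lon": float(lon_home),
                "home_lat": float(lat_home),
                "dwell_hours": home.dwell_seconds / 3600.0,
                "overnight_relation": home.relation,
            }
        )
        for indicator, series in (("lst", lst), ("airtemp", at)):
            mob = exposure.mobility_summary(path, series, indicator, sun)
            res = exposure.residence_summary(path, home, series, indicator, sun)
            for s in (mob, res):
                exp_rows.append(
                    {
                        "participant_id": pid,
                        "indicator": indicator,
                        "method": s.method,
                        "mean_incl_nonwear": s.mean_incl_nonwear,
                        "mean_excl_nonwear": s.mean_excl_nonwear,
                        "maximum": s.maximum,
                        "n_intervals": s.n_intervals,
                    }
                )
    exposures = pd.DataFrame(exp_rows)
    descriptives = pd.DataFrame(desc_rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cleaned = []
        for pid, path in kept_paths.items():
            f = path.frame.copy()
            f.insert(0, "participant_id", pid)
            f["t"] = f["t"].map(lambda ts: ts.isoformat())
            cleaned.append(
                f[["participant_id", "t", "lon", "lat", "wear",
                   "excluded", "reason"]]
            )
        pd.concat(cleaned, ignore_index=True).to_csv(
            outdir / "cleaned_paths.csv", index=False
        )
        descriptives.to_csv(outdir / "descriptives.csv", index=False)
        exposures.to_csv(outdir / "exposures.csv", index=False)
        homes_df = descriptives[
            ["participant_id", "home_lon", "home_lat", "dwell_hours",
             "overnight_relation"]
        ]
        homes_df.to_csv(outdir / "homes.csv", index=False)
    return {"paths": kept_paths, "homes": homes, "exposures": exposures,
            "descriptives": descriptives}


def comparison_records(exposures: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long exposure table into per-participant difference records."""
    rows = []
    for (pid, indicator), grp in exposures.groupby(
        ["participant_id", "indicator"], sort=True
    ):
        by_method = {r["method"]: r for _, r in grp.iterrows()}
        mob = by_method["mobility"]
        res = by_method["residence"]
        rows.append(
            {
                "participant_id": pid,
                "indicator": indicator,
                "mean_mobility": mob["mean_incl_nonwear"],
                "mean_residence": res["mean_incl_nonwear"],
                "mean_mobility_excl_nonwear": mob["mean_excl_nonwear"],
                "mean_residence_excl_nonwear": res["mean_excl_nonwear"],
                "maximum_mobility": mob["maximum"],
                "maximum_residence": res["maximum"],
                "difference_means": mob["mean_incl_nonwear"] - res["mean_incl_nonwear"],
                "difference_means_excl_nonwear": (
                    mob["mean_excl_nonwear"] - res["mean_excl_nonwear"]
                ),
                "difference_maximums": mob["maximum"] - res["maximum"],
            }
        )
    return pd.DataFrame(rows)


def run_compare(exposures: pd.DataFrame, descriptives: pd.DataFrame,
                covariates: pd.DataFrame | None, cfg: StudyConfig,
                outdir=None) -> dict:
    """Build comparison records, stratified tables and histogram counts."""
    proc = cfg.processing
    records = comparison_records(exposures)
    records = records.merge(
        descriptives[["participant_id", "mean_daily_km"]],
        on="participant_id", how="left",
    )
    if covariates is not None:
        records = records.merge(covariates, on="participant_id", how="left")

    strata = [s for s in proc.strata if s == "daily_distance_tertile"
              or s in records.columns]
    if "daily_distance_tertile" in strata:
        if records["participant_id"].nunique() >= 3:
            per_pid = records.drop_duplicates("participant_id")
            _, _, labels = cmp.tertiles(per_pid["mean_daily_km"].to_numpy())
            lab_map = dict(zip(per_pid["participant_id"], labels))
            records["daily_distance_tertile"] = records["participant_id"].map(lab_map)
        else:
            strata = [s for s in strata if s != "daily_distance_tertile"]

    table = cmp.stratified_table(records, strata)

    hists = []
    for indicator, sub in records.groupby("indicator", sort=True):
        for fld, width in (
            ("difference_means", proc.hist_bin_width_means),
            ("difference_maximums", proc.hist_bin_width_maximums),
        ):
            h = cmp.histogram_export(sub[fld].to_numpy(), width)
            h.insert(0, "field", fld)
            h.insert(0, "indicator", indicator)
            hists.append(h)
    histograms = pd.concat(hists, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "comparison_records.csv", index=False)
        table.to_csv(outdir / "comparison_table.csv", index=False)
        histograms.to_csv(outdir / "histograms.csv", index=False)
    return {"records": records, "table": table, "histograms": histograms}
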