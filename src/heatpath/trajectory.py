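"""Activity-path construction, cleaning and descriptive mobility measures.

A participant's pings are ordered in time, aggregated to the minute level,
filtered for implausible straight-line speeds (> 100 mph) and for points
outside the study area, and classified into wear and non-wear intervals:
the interval following a ping is wear when the next ping arrives within one
minute, and non-wear otherwise (interpreted as the overnight gap between
taking the device off and putting it back on).  Each retained ping carries
an elapsed-time-to-next weight used by every downstream time-weighted
statistic; the final ping of follow-up has zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import TransverseMercator

__all__ = [
    "ActivityPath",
    "build_paths",
    "filter_speed",
    "clip_area",
    "classify_wear",
    "select_valid_days",
    "daily_distance",
    "fraction_time_near",
    "MPH_TO_MPS",
]

MPH_TO_MPS = 0.44704
WEAR_GAP_SECONDS = 60.0  # pings one minute apart are wear


@dataclass
class ActivityPath:
    """Time-ordered minute-level pings of one participant.

    ``frame`` columns: t (tz-aware), lon, lat, x, y (projected metres),
    dt_s (elapsed seconds to the next retained ping; 0 for the last),
    wear (bool, describes the interval following the ping),
    excluded (bool), reason (str, empty when retained).
    """

    participant_id: str
    frame: pd.DataFrame
    crs: TransverseMercator = field(default_factory=lambda: TransverseMercator(0.0, 0.0))

    def retained(self) -> pd.DataFrame:
        return self.frame.loc[~self.frame["excluded"]]

    def total_elapsed_seconds(self) -> float:
        return float(self.retained()["dt_s"].sum())


def _recompute_weights(path: ActivityPath) -> None:
    """Refresh dt_s and wear flags of retained pings after any exclusion."""
    frame = path.frame
    idx = frame.index[~frame["excluded"]]
    frame["dt_s"] = 0.0
    frame["wear"] = False
    if len(idx) >= 2:
        t = frame.loc[idx, "t"]
        dt = t.diff().dt.total_seconds().to_numpy()[1:]
        frame.loc[idx[:-1], "dt_s"] = dt
        frame.loc[idx[:-1], "wear"] = dt <= WEAR_GAP_SECONDS


def build_paths(pings: pd.DataFrame, crs: TransverseMercator,
                minute_rule: str = "first") -> dict:
    """Build one ActivityPath per participant from raw pings.

    Pings are sorted by time within participant and collapsed to one per
    calendar minute.  ``minute_rule`` is ``"first"`` (keep the first ping
    of each minute, the default) or ``"centroid"`` (mean position of the
    minute's pings); either way the kept ping's timestamp is the minute
    mark.  Duplicate timestamps keep the first occurrence.
    """
    if minute_rule not in ("first", "centroid"):
        raise ValueError(f"unknown minute_rule {minute_rule!r}")
    paths = {}
    for pid, grp in pings.groupby("participant_id", sort=True):
        g = grp.sort_values("t", kind="mergesort").reset_index(drop=True)
        minute = g["t"].dt.floor("min")
        if minute_rule == "first":
            g = g.loc[~minute.duplicated(keep="first")].reset_index(drop=True)
            g["t"] = g["t"].dt.floor("min")
        else:
            g = (
                g.assign(t=minute)
                .groupby("t", as_index=False)[["lon", "lat"]]
                .mean()
            )
        g = g.loc[~g["t"].duplicated(keep="first")].reset_index(drop=True)
        x, y = crs.forward(g["lon"].to_numpy(), g["lat"].to_numpy())
        frame = pd.DataFrame(
            {
                "t": g["t"],
                "lon": g["lon"].to_numpy(),
                "lat": g["lat"].to_numpy(),
                "x": x,
                "y": y,
                "dt_s": 0.0,
                "wear": False,
                "excluded": False,
                "reason": "",
            }
        )
        path = ActivityPath(participant_id=str(pid), frame=frame, crs=crs)
        _recompute_weights(path)
        paths[str(pid)] = path
    return paths


def filter_speed(path: ActivityPath, vmax_mph: float = 100.0) -> ActivityPath:
    """Exclude pings whose straight-line speed to the next ping exceeds vmax.

    A single forward pass over time-ordered retained pings: for each
    consecutive pair, if the as-the-crow-flies speed strictly exceeds the
    threshold the origin ping of the segment is excluded (reason "speed").
    Elapsed-time weights are recomputed afterwards.
    """
    vmax_mps = vmax_mph * MPH_TO_MPS
    frame = path.frame
    idx = frame.index[~frame["excluded"]].to_numpy()
    if len(idx) >= 2:
        x = frame.loc[idx, "x"].to_numpy()
        y = frame.loc[idx, "y"].to_numpy()
        dt = frame.loc[idx, "t"].diff().dt.total_seconds().to_numpy()[1:]
        dist = np.hypot(np.diff(x), np.diff(y))
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = np.where(dt > 0, dist / dt, np.inf)
        over = speed > vmax_mps
        bad = idx[:-1][over]
        frame.loc[bad, "excluded"] = True
        frame.loc[bad, "reason"] = "speed"
    _recompute_weights(path)
    return path


def clip_area(path: ActivityPath, polygon) -> ActivityPath:
    """Exclude retained pings strictly outside ``polygon`` (path CRS).

    Boundary points are kept.  Raises on a degenerate polygon.
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate study-area polygon")
    frame = path.frame
    idx = frame.index[~frame["excluded"]]
    pts = shapely.points(frame.loc[idx, "x"].to_numpy(), frame.loc[idx, "y"].to_numpy())
    inside = shapely.covers(polygon, pts)
    bad = idx[~inside]
    frame.loc[bad, "excluded"] = True
    frame.loc[bad, "reason"] = "out-of-area"
    _recompute_weights(path)
    return path


def classify_wear(path: ActivityPath) -> pd.Series:
    """Per-ping wear flag: the following interval is wear iff ≤ 1 minute.

    Weights are kept current by the cleaning steps; this recomputes and
    returns the flags of retained pings for convenience.
    """
    _recompute_weights(path)
    return path.retained()["wear"]


def select_valid_days(path: ActivityPath, min_wear_hours: float = 10.0) -> set:
    """Dates with at least ``min_wear_hours`` of wear time.

    Wear intervals are attributed to the local calendar date of their
    starting ping.  A participant is retained in the cohort when they have
    at least one valid day.
    """
    r = path.retained()
    if len(r) == 0:
        return set()
    wear_s = r["dt_s"].where(r["wear"], 0.0)
    by_date = wear_s.groupby(r["t"].dt.date).sum()
    return set(by_date.index[by_date >= min_wear_hours * 3600.0])


def daily_distance(path: ActivityPath) -> pd.Series:
    """Cumulative straight-line distance (km) between pings, per date.

    Each segment is attributed to the date of its starting ping (overnight
    segments count toward the evening's date).
    """
    r = path.retained()
    if len(r) < 2:
        return pd.Series(dtype=float)
    x = r["x"].to_numpy()
    y = r["y"].to_numpy()
    seg_km = np.hypot(np.diff(x), np.diff(y)) / 1000.0
    dates = r["t"].dt.date.to_numpy()[:-1]
    return pd.Series(seg_km).groupby(dates).sum()


def fraction_time_near(path: ActivityPath, point, radius_m: float = 200.0) -> float:
    """Fraction of total elapsed time (incl. non-wear) within ``radius_m``
    of ``point`` (projected metres)."""
    r = path.retained()
    total = r["dt_s"].sum()
    if total <= 0:
        return float("nan")
    px, py = point
    near = np.hypot(r["x"].to_numpy() - px, r["y"].to_numpy() - py) <= radius_m
    return float(r["dt_s"].to_numpy()[near].sum() / total)
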