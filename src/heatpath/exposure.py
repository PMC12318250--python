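"""Mobility-based and residence-based exposure summaries.

Two temporal-interpolation schemes bring the gridded indicators to the
minute scale of the GPS record:

* **Sparse single-valued series** (LST-like, one scene every ~15 days).
  Each ping's value is the inverse-time-distance weighted combination of
  the scene most closely preceding and the scene most closely following
  the ping's date:

      value = (v_earlier * wt_earlier + v_later * wt_later)
              / (wt_earlier + wt_later)

  with ``wt_earlier = span / (index - earlier)`` and
  ``wt_later = span / (later - index)`` where ``span`` is the number of
  days between the two scenes.  Equivalently a linear interpolation in
  time; when the index date coincides with a scene that scene receives
  full weight.

* **Daily max/min pair series** (air-temperature-like).  Within a day the
  maximum is anchored at 15:00 local and the minimum at that day's
  sunrise; a ping at clock time t gets

      value = (v_max * wt_max + v_min * wt_min) / (wt_max + wt_min)

  with ``wt_max = (a + b) / a`` and ``wt_min = (a + b) / b`` where ``a``
  is the time until/after 15:00 and ``b`` the time since/until sunrise.
  At the anchors the corresponding extreme is returned exactly.

Per participant the time-weighted mean (weights = elapsed time to the next
ping, optionally excluding non-wear intervals) and a maximum over ordered
10-minute interval averages are computed, either along the actual
trajectory (mobility-based) or holding the location fixed at the inferred
home while keeping the participant's own ping times (residence-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .geo import RasterScene, RasterSeries
from .hexgrid import HomeLocation
from .trajectory import ActivityPath

__all__ = [
    "ScenePair",
    "DiurnalWeights",
    "ExposureSummary",
    "bracket_scenes",
    "lst_at",
    "diurnal_weights",
    "airtemp_at",
    "weighted_mean",
    "interval_means",
    "maximum_of_intervals",
    "mobility_summary",
    "residence_summary",
    "MAX_TEMP_ANCHOR_HOUR",
]

MAX_TEMP_ANCHOR_HOUR = 15  # daily maximum assumed at 3 pm local


class MissingValueError(ValueError):
    """No usable indicator value at a point/time."""


@dataclass(frozen=True)
class ScenePair:
    """The two scenes bracketing an index date, with inverse-time weights.

    When the index date falls on a scene, or outside the series' span,
    ``earlier`` and ``later`` are the same scene with weights (1, 0).
    """

    earlier: RasterScene
    later: RasterScene
    index_date: date
    wt_earlier: float
    wt_later: float


def bracket_scenes(index_date: date, series: RasterSeries) -> ScenePair:
    """Nearest scene on each side of the index date plus their weights."""
    if series.kind != "single_valued":
        raise ValueError("bracket_scenes needs a single_valued series")
    dates = series.dates
    if not dates:
        raise ValueError("empty raster series")
    earlier_d = max((d for d in dates if d <= index_date), default=None)
    later_d = min((d for d in dates if d >= index_date), default=None)
    if earlier_d is None:
        earlier_d = later_d
    if later_d is None:
        later_d = earlier_d
    earlier = series.scenes[earlier_d]
    later = series.scenes[later_d]
    if earlier_d == later_d:
        return ScenePair(earlier, later, index_date, 1.0, 0.0)
    span = (later_d - earlier_d).days
    wt_earlier = span / (index_date - earlier_d).days
    wt_later = span / (later_d - index_date).days
    return ScenePair(earlier, later, index_date, wt_earlier, wt_later)


def _combine_pair(v_a, v_b, w_a: float, w_b: float):
    """Weighted combination with nodata fallback.

    If one side is NaN the other receives full weight; both NaN -> NaN.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    a_ok = ~np.isnan(v_a)
    b_ok = ~np.isnan(v_b)
    with np.errstate(invalid="ignore"):
        both = (v_a * w_a + v_b * w_b) / (w_a + w_b)
    out = np.where(
        a_ok & b_ok, both, np.where(a_ok, v_a, np.where(b_ok, v_b, np.nan))
    )
    return out


def lst_values(pair: ScenePair, x, y):
    """Interpolated single-valued indicator at points, for one index date."""
    if pair.wt_later == 0.0:
        return pair.earlier.sample(x, y)
    v_e = pair.earlier.sample(x, y)
    v_l = pair.later.sample(x, y)
    return _combine_pair(v_e, v_l, pair.wt_earlier, pair.wt_later)


def lst_at(x: float, y: float, index_date: date, series: RasterSeries) -> float:
    """Scalar convenience wrapper around :func:`lst_values`."""
    pair = bracket_scenes(index_date, series)
    v = float(np.asarray(lst_values(pair, np.asarray(x), np.asarray(y))))
    if np.isnan(v):
        raise MissingValueError(f"no value at ({x}, {y}) on {index_date}")
    return v


@dataclass(frozen=True)
class DiurnalWeights:
    index_time: datetime
    sunrise_time: datetime
    wt_max: float
    wt_min: float


def _sunrise_anchor(t: datetime, sunrise_provider) -> datetime:
    """Which sunrise anchors the 'time since/until sunrise' distance.

    Between the day's sunrise and 15:00: that day's sunrise (time since).
    After 15:00: the next day's sunrise (time until).  Before the day's
    sunrise: the previous day's sunrise (time since).  Indicator values
    are always sampled from the index date's scenes regardless.
    """
    d = t.date()
    sr = sunrise_provider(d)
    if t >= t.replace(hour=MAX_TEMP_ANCHOR_HOUR, minute=0, second=0, microsecond=0):
        return sunrise_provider(d + timedelta(days=1))
    if t < sr:
        return sunrise_provider(d - timedelta(days=1))
    return sr


def diurnal_weights(index_time: datetime, sunrise_time: datetime) -> DiurnalWeights:
    """Inverse-time-distance weights between the 3 pm and sunrise anchors.

    Exact anchor times are handled as limits: at 15:00 the weight is fully
    on the maximum, at sunrise fully on the minimum.
    """
    anchor_max = index_time.replace(
        hour=MAX_TEMP_ANCHOR_HOUR, minute=0, second=0, microsecond=0
    )
    a = abs((index_time - anchor_max).total_seconds())
    b = abs((index_time - sunrise_time).total_seconds())
    if a == 0.0:
        return DiurnalWeights(index_time, sunrise_time, np.inf, 0.0)
    if b == 0.0:
        return DiurnalWeights(index_time, sunrise_time, 0.0, np.inf)
    return DiurnalWeights(index_time, sunrise_time, (a + b) / a, (a + b) / b)


def _diurnal_fractions(t: datetime, sunrise_provider):
    """(weight fraction on max, on min) for one clock time."""
    w = diurnal_weights(t, _sunrise_anchor(t, sunrise_provider))
    if np.isinf(w.wt_max):
        return 1.0, 0.0
    if np.isinf(w.wt_min):
        return 0.0, 1.0
    s = w.wt_max + w.wt_min
    return w.wt_max / s, w.wt_min / s


def _diurnal_max_fraction_vec(t: pd.Series, day: date, sunrise_provider):
    """Vectorised weight fraction on the daily maximum for one date's pings.

    Same anchor-day convention as :func:`_sunrise_anchor`; note
    wt_max/(wt_max+wt_min) simplifies to b/(a+b) with a the distance to
    15:00 and b the distance to the anchoring sunrise.
    """
    epoch = pd.Timestamp(0, tz="UTC")
    te = (t - epoch).dt.total_seconds().to_numpy()
    tz = t.iloc[0].tzinfo
    anchor_e = datetime.combine(day, time(MAX_TEMP_ANCHOR_HOUR), tzinfo=tz).timestamp()
    sr0 = sunrise_provider(day).timestamp()
    srp = sunrise_provider(day - timedelta(days=1)).timestamp()
    srn = sunrise_provider(day + timedelta(days=1)).timestamp()
    a = te - anchor_e
    sr_anchor = np.where(a >= 0, srn, np.where(te < sr0, srp, sr0))
    abs_a = np.abs(a)
    b = np.abs(te - sr_anchor)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_max = b / (abs_a + b)
    f_max = np.where(abs_a == 0, 1.0, np.where(b == 0, 0.0, f_max))
    return f_max


def airtemp_at(x: float, y: float, t: datetime, series: RasterSeries,
               sunrise_provider) -> float:
    """Diurnally interpolated air temperature at a point and clock time."""
    if series.kind != "max_min_pair":
        raise ValueError("airtemp_at needs a max_min_pair series")
    d = t.date()
    if d not in series.scenes:
        raise MissingValueError(f"no air-temperature scenes for {d}")
    scene_max, scene_min = series.scenes[d]
    v_max = float(np.asarray(scene_max.sample(np.asarray(x), np.asarray(y))))
    v_min = float(np.asarray(scene_min.sample(np.asarray(x), np.asarray(y))))
    f_max, f_min = _diurnal_fractions(t, sunrise_provider)
    v = _combine_pair(v_max, v_min, f_max, f_min)
    v = float(np.asarray(v))
    if np.isnan(v):
        raise MissingValueError(f"no value at ({x}, {y}) on {d}")
    return v


def weighted_mean(values, durations, include=None) -> float:
    """Duration-weighted mean; NaN values drop with their durations.

    ``include`` optionally masks intervals (e.g. wear-only).  Raises when
    the included total duration is zero.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(durations, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    keep = ~np.isnan(v) & (d > 0)
    if include is not None:
        keep &= np.asarray(include, dtype=bool)
    total = d[keep].sum()
    if total <= 0:
        raise ValueError("undefined mean: zero total duration")
    return float(np.sum(v[keep] * d[keep]) / total)


def interval_means(times, values, width_minutes: float = 10.0) -> np.ndarray:
    """Unweighted per-bin means over consecutive fixed-width time bins.

    Bins are anchored at the first timestamp.  NaN values are ignored
    within a bin; bins with no usable value are omitted.
    """
    t = pd.Series(pd.to_datetime(times))
    if len(t) == 0:
        raise ValueError("empty path: no intervals to bin")
    v = np.asarray(values, dtype=float)
    offset_s = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    bins = np.floor(offset_s / (width_minutes * 60.0)).astype(np.int64)
    ok = ~np.isnan(v)
    if not ok.any():
        return np.array([])
    sums = np.bincount(bins[ok], weights=v[ok])
    counts = np.bincount(bins[ok])
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means[counts > 0]


def maximum_of_intervals(times, values, width_minutes: float = 10.0) -> float:
    means = interval_means(times, values, width_minutes)
    if means.size == 0:
        raise ValueError("no usable interval values")
    return float(means.max())


@dataclass(frozen=True)
class ExposureSummary:
    participant_id: str
    indicator: str          # "lst" | "airtemp"
    method: str             # "mobility" | "residence"
    mean_incl_nonwear: float
    mean_excl_nonwear: float
    maximum: float
    n_intervals: int


def _values_along(frame: pd.DataFrame, xs, ys, indicator: str,
                  series: RasterSeries, sunrise_provider):
    """Indicator value for every ping, at externally supplied coordinates."""
    n = len(frame)
    out = np.full(n, np.nan)
    t = frame["t"]
    dates = t.dt.date.to_numpy()
    if indicator == "lst":
        for d in pd.unique(dates):
            sel = dates == d
            pair = bracket_scenes(d, series)
            out[sel] = lst_values(pair, xs[sel], ys[sel])
    elif indicator == "airtemp":
        for d in pd.unique(dates):
            sel = dates == d
            if d not in series.scenes:
                continue
            scene_max, scene_min = series.scenes[d]
            v_max = scene_max.sample(xs[sel], ys[sel])
            v_min = scene_min.sample(xs[sel], ys[sel])
            f_max = _diurnal_max_fraction_vec(t[sel], d, sunrise_provider)
            ok_max = ~np.isnan(v_max)
            ok_min = ~np.isnan(v_min)
            with np.errstate(invalid="ignore"):
                both = v_max * f_max + v_min * (1.0 - f_max)
            out[sel] = np.where(
                ok_max & ok_min,
                both,
                np.where(ok_max, v_max, np.where(ok_min, v_min, np.nan)),
            )
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    return out


def _summarise(pid: str, indicator: str, method: str, frame: pd.DataFrame,
               values: np.ndarray, maximum: float) -> ExposureSummary:
    dur = frame["dt_s"].to_numpy(dtype=float)
    wear = frame["wear"].to_numpy(dtype=bool)
    mean_incl = weighted_mean(values, dur)
    try:
        mean_excl = weighted_mean(values, dur, include=wear)
    except ValueError:
        mean_excl = float("nan")  # no wear intervals at all
    n_bins = interval_means(frame["t"], values).size
    return ExposureSummary(
        participant_id=pid,
        indicator=indicator,
        method=method,
        mean_incl_nonwear=mean_incl,
        mean_excl_nonwear=mean_excl,
        maximum=maximum,
        n_intervals=n_bins,
    )


def mobility_summary(path: ActivityPath, series: RasterSeries, indicator: str,
                     sunrise_provider=None) -> ExposureSummary:
    """Time-weighted mean and 10-minute-interval maximum along the trajectory."""
    frame = path.retained()
    if len(frame) == 0:
        raise ValueError(f"participant {path.participant_id}: empty path")
    xs = frame["x"].to_numpy(dtype=float)
    ys = frame["y"].to_numpy(dtype=float)
    values = _values_along(frame, xs, ys, indicator, series, sunrise_provider)
    maximum = maximum_of_intervals(frame["t"], values)
    return _summarise(path.participant_id, indicator, "mobility", frame, values, maximum)


def residence_summary(path: ActivityPath, home: HomeLocation, series: RasterSeries,
                      indicator: str, sunrise_provider=None) -> ExposureSummary:
    """Same temporal machinery as mobility, all samples at the home point.

    For the sparse single-valued indicator the maximum is the maximum over
    follow-up dates of the day-level home value (scene interpolation
    depends only on the date, so the home value is constant within a day).
    For the daily max/min indicator the maximum is over 10-minute interval
    means at the home location.
    """
    frame = path.retained()
    if len(frame) == 0:
        raise ValueError(f"participant {path.participant_id}: empty path")
    xs = np.full(len(frame), home.x)
    ys = np.full(len(frame), home.y)
    values = _values_along(frame, xs, ys, indicator, series, sunrise_provider)
    if indicator == "lst":
        dates = pd.unique(frame["t"].dt.date)
        day_vals = []
        for d in dates:
            pair = bracket_scenes(d, series)
            day_vals.append(float(np.asarray(lst_values(pair, np.asarray(home.x),
                                                        np.asarray(home.y)))))
        day_vals = np.asarray(day_vals)
        if np.all(np.isnan(day_vals)):
            raise MissingValueError("home location has no usable day-level value")
        maximum = float(np.nanmax(day_vals))
    else:
        maximum = maximum_of_intervals(frame["t"], values)
    return _summarise(path.participant_id, indicator, "residence", frame, values, maximum)
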