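"""Synthetic heat surfaces and a synthetic GPS cohort.

The study's participant data are not public, so the pipeline is exercised
on a generated world built to match the study's reported statistical
structure: a sparse high-resolution single-valued indicator series
(LST-like: 30 m cells, one scene per ~15 days, about half of scheduled
scenes dropped as too cloudy, within-scene spatial SD ≈ 8.4 °C) and a
daily coarse max/min pair series (air-temperature-like: 4 km cells,
spatial SDs ≈ 3.8 / 3.0 °C); and a cohort of home-anchored participants
(default n = 599, 14 days of follow-up, ~13.3 h of device wear per day,
~59 km travelled daily, ~74 % of elapsed time at home) with one overnight
non-wear gap per day whose bracketing pings sit at the home location.

Spatial fields are low-pass-filtered white noise rescaled to the target
within-scene SD; only the SDs are constrained by the emulated data
products, so the correlation length is an explicit model choice.  A
deterministic ``SeedSequence`` sub-stream per participant means adding a
participant never perturbs the others.

For exactness tests, :func:`static_hot_zone_world` builds a temporally
constant, spatially piecewise-constant world (uniform background plus a
hot disc) and :func:`analytic_exposure_truth` computes the expected
mobility and residence means for a deterministic block schedule by direct
time-in-zone bookkeeping, independent of the exposure code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geo import RasterScene, RasterSeries, TransverseMercator

__all__ = [
    "LstLikeConfig",
    "AtLikeConfig",
    "HotZone",
    "WorldConfig",
    "CohortConfig",
    "TruthRecord",
    "simulate_heat_surface",
    "simulate_cohort",
    "static_hot_zone_world",
    "SiteBlock",
    "deterministic_schedule_pings",
    "analytic_exposure_truth",
    "DEFAULT_COVARIATE_FREQS",
]


@dataclass
class LstLikeConfig:
    cell_size_m: float = 30.0
    cadence_days: int = 15
    scene_drop_prob: float = 0.49   # ~35 of 69 scheduled scenes usable
    spatial_sd: float = 8.36        # °C, within-scene spatial SD
    seasonal_mean: float = 31.0     # °C, annual mean of scene-wide means
    seasonal_amplitude: float = 12.0
    peak_doy: int = 200             # day of year of the seasonal peak
    corr_length_m: float = 1000.0   # e-folding scale of the spatial field


@dataclass
class AtLikeConfig:
    cell_size_m: float = 4000.0
    spatial_sd_max: float = 3.75    # °C, daily-max field spatial SD
    spatial_sd_min: float = 3.02    # °C, daily-min field spatial SD
    mean_max: float = 25.0          # °C, annual mean of daily maxima
    mean_min: float = 12.0          # °C, annual mean of daily minima
    amplitude_max: float = 8.0
    amplitude_min: float = 6.0
    peak_doy: int = 200
    corr_length_m: float = 8000.0


@dataclass
class HotZone:
    x: float
    y: float
    radius_m: float
    excess_c: float


@dataclass
class WorldConfig:
    domain_km: tuple = (60.0, 60.0)
    center_lonlat: tuple = (-117.16, 32.72)
    start: date = date(2015, 10, 1)
    n_days: int = 14
    margin_days: int = 30           # raster coverage beyond the study window
    utc_offset_hours: float = -8.0
    lst: LstLikeConfig = dc_field(default_factory=LstLikeConfig)
    at: AtLikeConfig = dc_field(default_factory=AtLikeConfig)
    hot_zone: HotZone | None = None
    seed: int = 0

    @property
    def crs(self) -> TransverseMercator:
        return TransverseMercator(*self.center_lonlat)

    @property
    def half_extent_m(self) -> tuple:
        return (self.domain_km[0] * 500.0, self.domain_km[1] * 500.0)

    @property
    def tz(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset_hours))


DEFAULT_COVARIATE_FREQS = {
    "age_group": {"35-50": 0.235, "51-65": 0.449, "66-80": 0.316},
    "sex": {"female": 0.559, "male": 0.441},
    "income": {"<$30k": 0.270, "$30k-$55k": 0.227, "$55k+": 0.464, "Missing": 0.039},
    "race_ethnicity": {
        "White": 0.494,
        "Latino": 0.417,
        "Asian": 0.030,
        "Black": 0.028,
        "Native American or Pacific Islander": 0.022,
        "Missing": 0.009,
    },
}


@dataclass
class CohortConfig:
    n_participants: int = 599
    followup_days: int = 14
    wear_hours_per_day: float = 13.3
    trips_per_day: int = 2
    speed_kmh: float = 30.0
    mean_daily_km: float = 59.0
    fraction_time_home: float = 0.74
    wake_hour: float = 7.5
    home_margin_km: float = 20.0      # homes stay this far from the domain edge
    between_sd_log: float = 0.4       # lognormal sd of the per-participant
                                      # travel multiplier
    day_gamma_shape: float = 2.0      # shape of the mean-1 daily multiplier
    covariate_freqs: dict = dc_field(default_factory=lambda: DEFAULT_COVARIATE_FREQS)
    home_points: list | None = None   # explicit (x, y) homes, overrides dispersion
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if not 0.0 < self.wear_hours_per_day <= 24.0:
            raise ValueError("wear_hours_per_day must be in (0, 24]")


@dataclass
class TruthRecord:
    participant_id: str
    home_x: float
    home_y: float
    daily_km: np.ndarray
    covariates: dict


def _seasonal(day: date, mean: float, amplitude: float, peak_doy: int) -> float:
    doy = day.timetuple().tm_yday
    return mean + amplitude * math.cos(2.0 * math.pi * (doy - peak_doy) / 365.0)


def _smooth_field(rng, shape, sigma_cells: float) -> np.ndarray:
    """Unit-SD smoothed white noise (empirically standardised per scene)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _scene(cfg: WorldConfig, day: date, values: np.ndarray,
           cell_size: float) -> RasterScene:
    hx, hy = cfg.half_extent_m
    return RasterScene(
        scene_date=day, values=values, cell_size=cell_size,
        west=-hx, north=hy, crs=cfg.crs,
    )


def _grid_shape(cfg: WorldConfig, cell_size: float):
    hx, hy = cfg.half_extent_m
    ncols = int(round(2 * hx / cell_size))
    nrows = int(round(2 * hy / cell_size))
    if ncols < 1 or nrows < 1:
        raise ValueError("domain smaller than one raster cell")
    return nrows, ncols


def _hot_zone_mask(cfg: WorldConfig, cell_size: float, shape) -> np.ndarray | None:
    if cfg.hot_zone is None:
        return None
    hz = cfg.hot_zone
    nrows, ncols = shape
    hx, hy = cfg.half_extent_m
    cx = -hx + (np.arange(ncols) + 0.5) * cell_size
    cy = hy - (np.arange(nrows) + 0.5) * cell_size
    dist2 = (cx[None, :] - hz.x) ** 2 + (cy[:, None] - hz.y) ** 2
    return dist2 <= hz.radius_m**2


def simulate_heat_surface(cfg: WorldConfig):
    """Generate the LST-like and AT-like series for one world seed.

    Returns ``(lst_series, at_series)``.  The LST-like scene schedule runs
    from ``margin_days`` before the study start to ``margin_days`` past its
    end at the configured cadence; each scheduled scene is independently
    dropped with ``scene_drop_prob`` except the first and last, which are
    always kept so every study date is bracketed.
    """
    if not 0.0 <= cfg.lst.scene_drop_prob < 1.0:
        raise ValueError("scene_drop_prob must be in [0, 1)")
    rng_lst = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rng_at = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    # --- sparse single-valued (LST-like) series ---
    shape = _grid_shape(cfg, cfg.lst.cell_size_m)
    hz_mask = _hot_zone_mask(cfg, cfg.lst.cell_size_m, shape)
    sigma = cfg.lst.corr_length_m / cfg.lst.cell_size_m
    first = cfg.start - timedelta(days=cfg.margin_days)
    last = cfg.start + timedelta(days=cfg.n_days + cfg.margin_days)
    schedule = []
    d = first
    while d <= last:
        schedule.append(d)
        d += timedelta(days=cfg.lst.cadence_days)
    lst_scenes = {}
    for i, day in enumerate(schedule):
        drop = rng_lst.uniform() < cfg.lst.scene_drop_prob
        keep = (i == 0) or (i == len(schedule) - 1) or not drop
        # draw the field regardless so kept scenes don't depend on which
        # other scenes were dropped
        if cfg.lst.spatial_sd > 0:
            fld = _smooth_field(rng_lst, shape, sigma) * cfg.lst.spatial_sd
        else:
            fld = np.zeros(shape)
        if not keep:
            continue
        vals = _seasonal(day, cfg.lst.seasonal_mean, cfg.lst.seasonal_amplitude,
                         cfg.lst.peak_doy) + fld
        if hz_mask is not None:
            vals = vals + cfg.hot_zone.excess_c * hz_mask
        lst_scenes[day] = _scene(cfg, day, vals, cfg.lst.cell_size_m)

    # --- daily max/min pair (AT-like) series ---
    shape_at = _grid_shape(cfg, cfg.at.cell_size_m)
    hz_mask_at = _hot_zone_mask(cfg, cfg.at.cell_size_m, shape_at)
    sigma_at = cfg.at.corr_length_m / cfg.at.cell_size_m
    at_scenes = {}
    day = cfg.start - timedelta(days=2)
    end = cfg.start + timedelta(days=cfg.n_days + 2)
    while day <= end:
        if cfg.at.spatial_sd_max > 0:
            f1 = _smooth_field(rng_at, shape_at, sigma_at) * cfg.at.spatial_sd_max
        else:
            f1 = np.zeros(shape_at)
        if cfg.at.spatial_sd_min > 0:
            f2 = _smooth_field(rng_at, shape_at, sigma_at) * cfg.at.spatial_sd_min
        else:
            f2 = np.zeros(shape_at)
        vmax = _seasonal(day, cfg.at.mean_max, cfg.at.amplitude_max,
                         cfg.at.peak_doy) + f1
        vmin = _seasonal(day, cfg.at.mean_min, cfg.at.amplitude_min,
                         cfg.at.peak_doy) + f2
        if hz_mask_at is not None:
            vmax = vmax + cfg.hot_zone.excess_c * hz_mask_at
            vmin = vmin + cfg.hot_zone.excess_c * hz_mask_at
        vmin = np.minimum(vmin, vmax - 0.2)  # daily max strictly above min
        at_scenes[day] = (
            _scene(cfg, day, vmax, cfg.at.cell_size_m),
            _scene(cfg, day, vmin, cfg.at.cell_size_m),
        )
        day += timedelta(days=1)

    return (
        RasterSeries(kind="single_valued", scenes=lst_scenes),
        RasterSeries(kind="max_min_pair", scenes=at_scenes),
    )


def _draw_category(rng, freqs: dict) -> str:
    labels = list(freqs)
    p = np.array([freqs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return labels[rng.choice(len(labels), p=p)]


def _day_schedule(rng, cfg: CohortConfig, home, travel_mult: float,
                  half_extent, margin_m: float):
    """Waypoints (minute offsets from local midnight, x, y) for one day.

    Returns (waypoints, wear_start_min, wear_end_min, day_km).
    """
    hx, hy = half_extent
    wake_min = int(round((cfg.wake_hour + rng.uniform(-0.5, 0.5)) * 60.0))
    wear_min = int(round((cfg.wear_hours_per_day + rng.uniform(-0.5, 0.5)) * 60.0))
    wear_end = wake_min + wear_min
    if cfg.trips_per_day == 0:
        return ([(wake_min, home[0], home[1]), (wear_end, home[0], home[1])],
                wake_min, wear_end, 0.0)

    away_h = (1.0 - cfg.fraction_time_home) * 24.0
    travel_h = cfg.mean_daily_km / cfg.speed_kmh
    dwell_total_h = away_h - travel_h
    if dwell_total_h < 0:
        raise ValueError(
            "infeasible cohort config: required daily distance at the given "
            "speed exceeds the away-from-home time budget"
        )
    dwell_min_per_trip = int(round(dwell_total_h * 60.0 / cfg.trips_per_day))

    shape = cfg.day_gamma_shape
    day_mult = rng.gamma(shape, 1.0 / shape) * travel_mult
    day_km_target = cfg.mean_daily_km * day_mult
    d_oneway_m = day_km_target / (2.0 * cfg.trips_per_day) * 1000.0

    trips = []
    for _ in range(cfg.trips_per_day):
        dest = None
        for _attempt in range(100):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cand = (home[0] + d_oneway_m * math.cos(theta),
                    home[1] + d_oneway_m * math.sin(theta))
            if (abs(cand[0]) <= hx - margin_m) and (abs(cand[1]) <= hy - margin_m):
                dest = cand
                break
        if dest is None:
            dest = (float(np.clip(cand[0], -hx + margin_m, hx - margin_m)),
                    float(np.clip(cand[1], -hy + margin_m, hy - margin_m)))
        dist_m = math.hypot(dest[0] - home[0], dest[1] - home[1])
        travel_leg_min = max(1, int(round(dist_m / 1000.0 / cfg.speed_kmh * 60.0)))
        trips.append((dest, dist_m, travel_leg_min))

    away_minutes = sum(2 * t[2] + dwell_min_per_trip for t in trips)
    home_blocks = cfg.trips_per_day + 1
    home_total = wear_min - away_minutes
    if home_total < home_blocks:
        raise ValueError(
            "infeasible cohort config: trips plus dwell exceed the wear window"
        )
    block = home_total // home_blocks
    extra = home_total - block * home_blocks

    wp = [(wake_min, home[0], home[1])]
    t_min = wake_min
    day_km = 0.0
    for k, (dest, dist_m, leg_min) in enumerate(trips):
        t_min += block + (extra if k == 0 else 0)
        wp.append((t_min, home[0], home[1]))          # depart home
        t_min += leg_min
        wp.append((t_min, dest[0], dest[1]))          # arrive
        t_min += dwell_min_per_trip
        wp.append((t_min, dest[0], dest[1]))          # leave
        t_min += leg_min
        wp.append((t_min, home[0], home[1]))          # back home
        day_km += 2.0 * dist_m / 1000.0
    wp.append((wear_end, home[0], home[1]))
    return wp, wake_min, wear_end, day_km


def simulate_cohort(cfg: CohortConfig, world: WorldConfig):
    """Generate minute-spaced cohort pings plus per-participant truth.

    Returns ``(pings, truths, covariates)`` where ``pings`` is a DataFrame
    (participant_id, t, lon, lat), ``truths`` a list of TruthRecord and
    ``covariates`` a DataFrame of simulated socio-demographic labels.

    Each participant gets day-anchored round trips from a fixed home, a
    wear window of roughly the configured hours, and a single overnight
    non-wear gap bracketed by pings at home.  Deterministic given seeds:
    participant ``i`` uses ``SeedSequence([seed, 3, i])``.
    """
    hx, hy = world.half_extent_m
    margin_m = 1000.0
    home_margin_m = cfg.home_margin_km * 1000.0
    if hx - home_margin_m <= 0 or hy - home_margin_m <= 0:
        raise ValueError("home margin leaves no room in the domain")
    tz = world.tz
    crs = world.crs

    all_pid = []
    all_t = []
    all_x = []
    all_y = []
    truths = []
    cov_rows = []
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, i]))
        pid = f"P{i:04d}"
        if cfg.home_points is not None:
            home = tuple(map(float, cfg.home_points[i]))
        else:
            home = (rng.uniform(-hx + home_margin_m, hx - home_margin_m),
                    rng.uniform(-hy + home_margin_m, hy - home_margin_m))
        travel_mult = math.exp(rng.normal(-cfg.between_sd_log**2 / 2.0,
                                          cfg.between_sd_log))
        covs = {k: _draw_category(rng, v) for k, v in cfg.covariate_freqs.items()}
        daily_km = []
        for day_i in range(cfg.followup_days):
            day = world.start + timedelta(days=day_i)
            wp, wake_min, wear_end, day_km = _day_schedule(
                rng, cfg, home, travel_mult, (hx, hy), margin_m
            )
            daily_km.append(day_km)
            minutes = np.arange(wake_min, wear_end + 1)
            wt = np.array([w[0] for w in wp], dtype=float)
            wx = np.array([w[1] for w in wp], dtype=float)
            wy = np.array([w[2] for w in wp], dtype=float)
            px = np.interp(minutes, wt, wx)
            py = np.interp(minutes, wt, wy)
            midnight = datetime.combine(day, time(0, 0), tzinfo=tz)
            ts = [midnight + timedelta(minutes=int(m)) for m in minutes]
            all_pid.extend([pid] * len(ts))
            all_t.extend(ts)
            all_x.append(px)
            all_y.append(py)
        truths.append(TruthRecord(pid, home[0], home[1],
                                  np.asarray(daily_km), covs))
        cov_rows.append({"participant_id": pid, **covs})

    x = np.concatenate(all_x)
    y = np.concatenate(all_y)
    lon, lat = crs.inverse(x, y)
    pings = pd.DataFrame(
        {"participant_id": all_pid, "t": pd.to_datetime(all_t), "lon": lon, "lat": lat}
    )
    return pings, truths, pd.DataFrame(cov_rows)


# ---------------------------------------------------------------------------
# piecewise-constant worlds and closed-form expected exposures
# ---------------------------------------------------------------------------


def static_hot_zone_world(cfg: WorldConfig, background_c: float,
                          hot_zone: HotZone | None):
    """Temporally constant world: uniform background plus an optional hot disc.

    Every LST-like scene is identical and AT-like max == min everywhere,
    so both interpolation schemes return the exact piecewise-constant
    spatial value at any date/time; expected exposures then have closed
    forms.
    """
    cfg2 = WorldConfig(
        domain_km=cfg.domain_km, center_lonlat=cfg.center_lonlat,
        start=cfg.start, n_days=cfg.n_days, margin_days=cfg.margin_days,
        utc_offset_hours=cfg.utc_offset_hours, hot_zone=hot_zone, seed=cfg.seed,
    )
    shape = _grid_shape(cfg2, cfg.lst.cell_size_m)
    base = np.full(shape, background_c)
    mask = _hot_zone_mask(cfg2, cfg.lst.cell_size_m, shape)
    if mask is not None:
        base = base + hot_zone.excess_c * mask
    lst_scenes = {}
    first = cfg.start - timedelta(days=cfg.margin_days)
    last = cfg.start + timedelta(days=cfg.n_days + cfg.margin_days)
    d = first
    while d <= last:
        lst_scenes[d] = _scene(cfg2, d, base.copy(), cfg.lst.cell_size_m)
        d += timedelta(days=cfg.lst.cadence_days)

    shape_at = _grid_shape(cfg2, cfg.at.cell_size_m)
    base_at = np.full(shape_at, background_c)
    mask_at = _hot_zone_mask(cfg2, cfg.at.cell_size_m, shape_at)
    if mask_at is not None:
        base_at = base_at + hot_zone.excess_c * mask_at
    at_scenes = {}
    d = cfg.start - timedelta(days=2)
    while d <= cfg.start + timedelta(days=cfg.n_days + 2):
        at_scenes[d] = (
            _scene(cfg2, d, base_at.copy(), cfg.at.cell_size_m),
            _scene(cfg2, d, base_at.copy(), cfg.at.cell_size_m),
        )
        d += timedelta(days=1)
    return (
        RasterSeries(kind="single_valued", scenes=lst_scenes),
        RasterSeries(kind="max_min_pair", scenes=at_scenes),
    )


@dataclass(frozen=True)
class SiteBlock:
    """A deterministic schedule block: stay ``minutes`` at point (x, y)."""

    x: float
    y: float
    minutes: int


def deterministic_schedule_pings(pid: str, blocks, start_dt: datetime,
                                 crs: TransverseMercator) -> pd.DataFrame:
    """Minute-spaced pings realising a block schedule (for recovery tests)."""
    xs = []
    ys = []
    for b in blocks:
        xs.extend([b.x] * b.minutes)
        ys.extend([b.y] * b.minutes)
    n = len(xs)
    ts = [start_dt + timedelta(minutes=m) for m in range(n)]
    lon, lat = crs.inverse(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))
    return pd.DataFrame(
        {"participant_id": pid, "t": pd.to_datetime(ts), "lon": lon, "lat": lat}
    )


def _zone_value(x: float, y: float, background_c: float,
                hot_zone: HotZone | None) -> float:
    if hot_zone is not None and math.hypot(x - hot_zone.x, y - hot_zone.y) <= hot_zone.radius_m:
        return background_c + hot_zone.excess_c
    return background_c


def analytic_exposure_truth(blocks, home_xy, background_c: float,
                            hot_zone: HotZone | None):
    """Expected (mobility_mean, residence_mean) for a block schedule.

    Direct elapsed-time bookkeeping on the piecewise-constant surface:
    every minute-spaced ping carries one minute of weight except the final
    ping of follow-up, which carries none.  Independent of the exposure
    module's code path.
    """
    counts = []
    for b in blocks:
        counts.append([_zone_value(b.x, b.y, background_c, hot_zone), b.minutes])
    if not counts:
        raise ValueError("empty schedule")
    counts[-1][1] -= 1  # final ping has no elapsed time to a next ping
    total = sum(c for _, c in counts)
    if total <= 0:
        raise ValueError("schedule has no weighted time")
    mobility = sum(v * c for v, c in counts) / total
    residence = _zone_value(home_xy[0], home_xy[1], background_c, hot_zone)
    return mobility, residence
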