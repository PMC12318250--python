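"""Local sunrise times from the NOAA solar-position equations.

The diurnal air-temperature interpolation anchors the daily minimum at
sunrise, so the pipeline needs sunrise for every follow-up date at the
study centroid.  This module implements the NOAA solar-calculator chain
(Julian century, equation of time, solar declination, hour angle at the
standard 90.833° sunrise zenith) and converts to local clock time with an
explicit, caller-supplied UTC offset — offsets are never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

__all__ = ["SunriseResult", "sunrise", "SunriseTable"]

_SUNRISE_ZENITH_DEG = 90.833  # solar zenith at sunrise incl. refraction


class PolarLatitudeError(ValueError):
    """Sunrise is undefined or unsupported at polar latitudes."""


@dataclass(frozen=True)
class SunriseResult:
    day: date
    lat: float
    lon: float
    utc_offset_hours: float
    sunrise: datetime


def _julian_day(day: date, hours_utc: float) -> float:
    return day.toordinal() + 1721424.5 + hours_utc / 24.0


def sunrise(day: date, lat: float, lon: float, utc_offset_hours: float) -> SunriseResult:
    """NOAA-equation sunrise for one date and location, in local clock time.

    ``lon`` is in degrees east (San Diego ≈ −117.16).  Latitudes poleward
    of 66° are rejected (no polar day/night handling).
    """
    if abs(lat) >= 66.0:
        raise PolarLatitudeError(f"latitude {lat} not supported (|lat| must be < 66)")

    # evaluate the slowly varying solar terms at local noon
    jd = _julian_day(day, 12.0 - utc_offset_hours)
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))

    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0 = math.radians(geom_mean_long)
    eqtime_min = 229.18 * (  # 4 * degrees(...) == 229.18 * radians expression
        var_y * math.sin(2 * l0)
        - 2 * ecc * math.sin(m)
        + 4 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y * var_y * math.sin(4 * l0)
        - 1.25 * ecc * ecc * math.sin(2 * m)
    )

    phi = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(_SUNRISE_ZENITH_DEG)) / (math.cos(phi) * math.cos(decl))
        - math.tan(phi) * math.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise PolarLatitudeError(f"sun does not rise/set on {day} at latitude {lat}")
    ha_deg = math.degrees(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * lon - eqtime_min + utc_offset_hours * 60.0
    sunrise_min = solar_noon_min - 4.0 * ha_deg

    tz = timezone(timedelta(hours=utc_offset_hours))
    t0 = datetime(day.year, day.month, day.day, tzinfo=tz)
    return SunriseResult(
        day=day,
        lat=lat,
        lon=lon,
        utc_offset_hours=utc_offset_hours,
        sunrise=t0 + timedelta(minutes=sunrise_min),
    )


class SunriseTable:
    """Cached per-date sunrise for one fixed location.

    The study computes sunrise once per day for a single point (the study
    centroid), not per ping; this memoises that lookup.
    """

    def __init__(self, lat: float, lon: float, utc_offset_hours: float):
        self.lat = lat
        self.lon = lon
        self.utc_offset_hours = utc_offset_hours
        self._cache: dict[date, datetime] = {}

    def __call__(self, day: date) -> datetime:
        got = self._cache.get(day)
        if got is None:
            got = sunrise(day, self.lat, self.lon, self.utc_offset_hours).sunrise
            self._cache[day] = got
        return got

    def table(self, days) -> "list[tuple[date, datetime]]":
        return [(d, self(d)) for d in days]
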