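"""Temporal interpolation of the two gridded heat indicators.

A sparse high-resolution indicator (one scene every ~15 days) is brought
to daily resolution by inverse-time-distance weighting between the scene
preceding and the scene following an index date.  A daily max/min pair is
brought to minute resolution by weighting between the daily maximum
(anchored at 3 pm) and the daily minimum (anchored at sunrise).
"""

from datetime import date, datetime, timedelta, timezone

import numpy as np

from heatpath.exposure import airtemp_at, bracket_scenes, lst_at
from heatpath.geo import RasterScene, RasterSeries, TransverseMercator
from heatpath.solar import SunriseTable

crs = TransverseMercator(-117.16, 32.72)
tz = timezone(timedelta(hours=-8))


def scene(value, day):
    return RasterScene(day, np.full((2, 2), float(value)), 10.0, -10.0, 10.0, crs)


# --- sparse single-valued indicator (LST-like) -----------------------------
d_earlier, d_later = date(2015, 3, 9), date(2015, 3, 25)
series = RasterSeries(
    kind="single_valued",
    scenes={d_earlier: scene(30.0, d_earlier), d_later: scene(32.0, d_later)},
)
index = date(2015, 3, 15)
pair = bracket_scenes(index, series)
print(f"scenes {d_earlier} (30.0 C) and {d_later} (32.0 C), index {index}")
print(f"  wt_earlier = {pair.wt_earlier:.4f} (= 16/6), "
      f"wt_later = {pair.wt_later:.4f} (= 16/10)")
print(f"  interpolated value = {lst_at(0.0, 0.0, index, series):.2f} C "
      "(closer to the nearer scene)")

# --- daily max/min pair (air-temperature-like) -----------------------------
day = date(2015, 7, 10)
at = RasterSeries(
    kind="max_min_pair", scenes={day: (scene(30.0, day), scene(14.0, day))}
)
sun = SunriseTable(32.72, -117.16, -8.0)
print(f"\nair temperature on {day}: max 30.0 C at 3 pm, "
      f"min 14.0 C at sunrise ({sun(day).time().isoformat('minutes')})")
for hh, mm in [(6, 0), (9, 0), (12, 0), (15, 0), (21, 0)]:
    t = datetime(2015, 7, 10, hh, mm, tzinfo=tz)
    v = airtemp_at(0.0, 0.0, t, at, sun)
    print(f"  {t.time().isoformat('minutes')} -> {v:5.2f} C")
print("values slide between the sunrise minimum and the 3 pm maximum")
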