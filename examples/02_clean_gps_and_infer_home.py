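"""GPS trajectory cleaning, wear classification and home inference.

Builds one synthetic participant-day by hand: a morning at home, a round
trip, an implausible GPS jump, and an overnight non-wear gap; then runs
the cleaning rules (minute aggregation, 100 mph speed filter, wear
classification) and infers the home hexagon from dwell time.
"""

from datetime import datetime, timedelta, timezone

import numpy as np

from heatpath import hexgrid, trajectory
from heatpath.geo import TransverseMercator
import pandas as pd

crs = TransverseMercator(-117.16, 32.72)
tz = timezone(timedelta(hours=-8))
start = datetime(2015, 10, 2, 7, 0, tzinfo=tz)

# home for 2 h, drive 6 km out over 12 min, 1 h at the destination, drive
# back, one bad ping 20 km away (GPS bounce), evening at home, overnight gap
minutes, xs, ys = [], [], []
m = 0


def block(n, x, y):
    global m
    for _ in range(n):
        minutes.append(m)
        xs.append(x)
        ys.append(y)
        m += 1


block(240, 0.0, 0.0)
for k in range(1, 13):            # outbound leg, 500 m per minute
    block(1, 500.0 * k, 0.0)
block(60, 6000.0, 0.0)            # destination dwell
for k in range(11, -1, -1):       # return leg
    block(1, 500.0 * k, 0.0)
block(1, 20000.0, 15000.0)        # implausible jump (over 100 mph)
block(330, 0.0, 0.0)              # evening at home
m += 10 * 60                      # overnight: device off for 10 h
block(30, 0.0, 0.0)               # next morning

lon, lat = crs.inverse(np.array(xs), np.array(ys))
ts = [start + timedelta(minutes=k) for k in minutes]
pings = pd.DataFrame({"participant_id": "demo", "t": pd.to_datetime(ts),
                      "lon": lon, "lat": lat})

path = trajectory.build_paths(pings, crs)["demo"]
trajectory.filter_speed(path, vmax_mph=100.0)
excluded = path.frame[path.frame.excluded]
print(f"pings: {len(path.frame)}, excluded by speed filter: {len(excluded)} "
      f"(reason: {excluded.reason.iloc[0]})")

wear = path.retained()
wear_h = wear.loc[wear.wear, "dt_s"].sum() / 3600
nonwear_h = wear.loc[~wear.wear, "dt_s"].sum() / 3600
print(f"wear time {wear_h:.1f} h, non-wear (overnight gap) {nonwear_h:.1f} h")
print(f"valid days (>= 10 h wear): {sorted(trajectory.select_valid_days(path))}")
print(f"distance travelled: {trajectory.daily_distance(path).sum():.1f} km")

grid = hexgrid.hex_grid((-25000, -25000, 25000, 25000), 62.0)
home = hexgrid.infer_home_with_crosscheck(path, grid)
print(f"inferred home hexagon centroid: ({home.x:.0f} m, {home.y:.0f} m), "
      f"dwell {home.dwell_seconds / 3600:.1f} h, "
      f"overnight cross-check: {home.relation}")
frac = trajectory.fraction_time_near(path, (home.x, home.y), 200.0)
print(f"fraction of elapsed time within 200 m of home: {frac:.2f}")
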