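"""Shared fixtures: a study CRS, small worlds, and path builders."""

from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from heatpath import synth, trajectory
from heatpath.geo import RasterScene, TransverseMercator

SD_LON, SD_LAT = -117.16, 32.72
TZ = timezone(timedelta(hours=-8))


@pytest.fixture(scope="session")
def crs():
    return TransverseMercator(SD_LON, SD_LAT)


@pytest.fixture(scope="session")
def tz():
    return TZ


@pytest.fixture
def small_world():
    """A 12 km world with coarse cells, cheap enough for per-test generation."""
    return synth.WorldConfig(
        domain_km=(12.0, 12.0),
        n_days=4,
        seed=11,
        lst=synth.LstLikeConfig(cell_size_m=150.0, corr_length_m=600.0),
        at=synth.AtLikeConfig(cell_size_m=3000.0, corr_length_m=4000.0),
    )


def planar_pings(pid, minutes, x, y, crs, start=None):
    """Pings DataFrame from planar coordinates at given minute offsets."""
    start = start or datetime(2015, 10, 2, 8, 0, tzinfo=TZ)
    lon, lat = crs.inverse(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    ts = [start + timedelta(minutes=int(m)) for m in minutes]
    return pd.DataFrame(
        {"participant_id": pid, "t": pd.to_datetime(ts), "lon": lon, "lat": lat}
    )


def make_path(pid, minutes, x, y, crs, start=None):
    """ActivityPath from planar coordinates (already cleaned, no exclusions)."""
    pings = planar_pings(pid, minutes, x, y, crs, start)
    return trajectory.build_paths(pings, crs)[pid]


def constant_scene(value, day=date(2015, 10, 2), cell=100.0, half=6000.0, crs=None):
    n = int(2 * half / cell)
    return RasterScene(
        scene_date=day,
        values=np.full((n, n), float(value)),
        cell_size=cell,
        west=-half,
        north=half,
        crs=crs or TransverseMercator(SD_LON, SD_LAT),
    )
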