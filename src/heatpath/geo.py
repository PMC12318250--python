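"""Spatial primitives: projection, raster grids, point sampling, and file I/O.

Everything downstream works in a single metric projected CRS (a local
transverse Mercator centred on the study area by default) so that speeds,
buffer distances and hexagon geometry are all in metres.  Temperatures are
held in degrees Celsius internally; Kelvin grids are converted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "WGS84_A",
    "WGS84_F",
    "TransverseMercator",
    "GpsPing",
    "RasterScene",
    "RasterSeries",
    "ProjectionError",
    "OutOfBoundsError",
    "project_points",
    "sample_raster",
    "read_pings",
    "write_pings",
    "read_raster",
    "write_raster",
]

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563


class ProjectionError(ValueError):
    """A point falls outside the validity area of the projection."""


class OutOfBoundsError(ValueError):
    """A point falls outside a raster's extent."""


def _tm_series_coefficients(n: float):
    """Krüger series coefficients to fourth order in the third flattening."""
    n2, n3, n4 = n * n, n**3, n**4
    alpha = (
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440,
        61 * n3 / 240 - 103 * n4 / 140,
        49561 * n4 / 161280,
    )
    beta = (
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440,
        17 * n3 / 480 - 37 * n4 / 840,
        4397 * n4 / 161280,
    )
    delta = (
        2 * n - 2 * n2 / 3 - 2 * n3 + 116 * n4 / 45,
        7 * n2 / 3 - 8 * n3 / 5 - 227 * n4 / 45,
        56 * n3 / 15 - 136 * n4 / 35,
        4279 * n4 / 630,
    )
    return alpha, beta, delta


@dataclass(frozen=True)
class TransverseMercator:
    """Ellipsoidal transverse Mercator (Krüger series) on WGS84, scale 1.

    Centred on ``(lon0, lat0)``: the central meridian is ``lon0`` and
    northings are measured from the parallel ``lat0``, so the centre maps
    to (0, 0).  Series truncation error is far below a millimetre for any
    domain a GPS cohort study covers.
    """

    lon0: float
    lat0: float

    # widest longitude offset accepted before a point is flagged as outside
    # the projection's validity area
    max_dlon_deg: float = 30.0

    def _setup(self):
        f = WGS84_F
        n = f / (2.0 - f)
        big_a = WGS84_A / (1.0 + n) * (1.0 + n * n / 4.0 + n**4 / 64.0)
        e = 2.0 * math.sqrt(n) / (1.0 + n)
        alpha, beta, delta = _tm_series_coefficients(n)
        return big_a, e, alpha, beta, delta

    def _xi_eta(self, lon, lat, big_a, e, alpha):
        phi = np.radians(lat)
        dlam = np.radians(lon - self.lon0)
        s = np.sin(phi)
        t = np.sinh(np.arctanh(s) - e * np.arctanh(e * s))
        xi_p = np.arctan2(t, np.cos(dlam))
        eta_p = np.arcsinh(np.sin(dlam) / np.hypot(t, np.cos(dlam)))
        xi = xi_p.copy()
        eta = eta_p.copy()
        for j, a_j in enumerate(alpha, start=1):
            xi += a_j * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
            eta += a_j * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
        return xi, eta

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar x/y in metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        dlon = (lon - self.lon0 + 180.0) % 360.0 - 180.0
        bad = np.abs(dlon) > self.max_dlon_deg
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))[:10].tolist()
            raise ProjectionError(
                f"{int(np.sum(bad))} point(s) outside the projection validity "
                f"area (|dlon| > {self.max_dlon_deg} deg); first indices {idx}"
            )
        big_a, e, alpha, _, _ = self._setup()
        xi, eta = self._xi_eta(lon, lat, big_a, e, alpha)
        xi0, _ = self._xi_eta(
            np.asarray(self.lon0), np.asarray(self.lat0), big_a, e, alpha
        )
        x = big_a * eta
        y = big_a * (xi - xi0)
        return x, y

    def inverse(self, x, y):
        """Planar x/y in metres back to lon/lat in degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        big_a, e, alpha, beta, delta = self._setup()
        xi0, _ = self._xi_eta(
            np.asarray(self.lon0), np.asarray(self.lat0), big_a, e, alpha
        )
        xi = y / big_a + xi0
        eta = x / big_a
        xi_p = xi.copy()
        eta_p = eta.copy()
        for j, b_j in enumerate(beta, start=1):
            xi_p -= b_j * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
            eta_p -= b_j * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
        chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
        phi = chi.copy()
        for j, d_j in enumerate(delta, start=1):
            phi += d_j * np.sin(2 * j * chi)
        lam = np.radians(self.lon0) + np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        return np.degrees(lam), np.degrees(phi)

    def to_dict(self) -> dict:
        return {"type": "local_tmerc", "lon0": self.lon0, "lat0": self.lat0}

    @classmethod
    def from_dict(cls, d: dict) -> "TransverseMercator":
        if d.get("type") != "local_tmerc":
            raise ValueError(f"unknown CRS descriptor: {d!r}")
        return cls(lon0=float(d["lon0"]), lat0=float(d["lat0"]))


@dataclass(frozen=True)
class GpsPing:
    """One GPS observation: who, when, where (WGS84 degrees)."""

    participant_id: str
    t: datetime
    lon: float
    lat: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.t.tzinfo is None:
            raise ValueError("ping timestamp must carry an explicit UTC offset")


def project_points(pings, crs: TransverseMercator):
    """Project a collection of pings (or a pings DataFrame) to planar metres.

    Returns ``(x, y)`` arrays in ping order.
    """
    if isinstance(pings, pd.DataFrame):
        lon = pings["lon"].to_numpy(dtype=float)
        lat = pings["lat"].to_numpy(dtype=float)
    else:
        lon = np.array([p.lon for p in pings], dtype=float)
        lat = np.array([p.lat for p in pings], dtype=float)
    return crs.forward(lon, lat)


@dataclass
class RasterScene:
    """A dated rectangular grid of indicator values in °C.

    ``values[0, 0]`` is the north-west cell; ``west``/``north`` are the
    coordinates of the grid's top-left corner in the projected CRS, and
    ``cell_size`` is the square cell edge in metres.  NaN marks nodata.
    """

    scene_date: date
    values: np.ndarray
    cell_size: float
    west: float
    north: float
    crs: TransverseMercator = field(default_factory=lambda: TransverseMercator(0.0, 0.0))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("non-masked raster values must be finite")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cell_size

    def cell_of(self, x, y):
        """Row/col of the cell containing each point.

        Containment is half-open, [west, east) in x and (south, north] in y,
        so every in-bounds point maps to exactly one cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.west) / self.cell_size).astype(np.int64)
        row = np.floor((self.north - y) / self.cell_size).astype(np.int64)
        # top edge of the grid belongs to row 0
        row = np.where(y == self.north, 0, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def sample(self, x, y, out_of_bounds: str = "raise"):
        """Value of the cell containing each point (NaN where masked).

        ``out_of_bounds``: "raise" (default) or "nan".
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        row, col, inside = self.cell_of(x, y)
        if not inside.all():
            if out_of_bounds == "raise":
                n_out = int((~inside).sum())
                raise OutOfBoundsError(
                    f"{n_out} point(s) outside raster bounds "
                    f"[{self.west}, {self.east}) x ({self.south}, {self.north}]"
                )
        out = np.full(np.broadcast(x, y).shape, np.nan)
        r = np.clip(row, 0, self.nrows - 1)
        c = np.clip(col, 0, self.ncols - 1)
        vals = self.values[r, c]
        out[...] = np.where(inside, vals, np.nan)
        return out


def sample_raster(scene: RasterScene, x: float, y: float) -> float:
    """Scalar nearest-cell sample; raises on out-of-bounds, NaN on masked."""
    return float(scene.sample(np.asarray(x), np.asarray(y)))


@dataclass
class RasterSeries:
    """A dated collection of scenes.

    ``kind="single_valued"``: ``scenes`` maps date -> RasterScene (an
    LST-like sparse series).  ``kind="max_min_pair"``: ``scenes`` maps
    date -> (max_scene, min_scene) (an air-temperature-like daily series).
    """

    kind: str
    scenes: dict

    def __post_init__(self):
        if self.kind not in ("single_valued", "max_min_pair"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        dates = list(self.scenes)
        if any(d2 <= d1 for d1, d2 in zip(dates, dates[1:])):
            self.scenes = dict(sorted(self.scenes.items()))
            dates = list(self.scenes)
        if len(set(dates)) != len(dates):
            raise ValueError("scene dates must be strictly increasing")
        if self.kind == "max_min_pair":
            for d, (mx, mn) in self.scenes.items():
                both = ~(np.isnan(mx.values) | np.isnan(mn.values))
                if np.any(mx.values[both] < mn.values[both]):
                    raise ValueError(f"max < min on {d} at some non-masked cell")

    @property
    def dates(self):
        return list(self.scenes)

    def __len__(self):
        return len(self.scenes)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

PING_COLUMNS = ["participant_id", "timestamp_iso8601", "lon", "lat"]


def read_pings(path) -> pd.DataFrame:
    """Read a pings CSV into a DataFrame (participant_id, t, lon, lat).

    Timestamps must be ISO-8601 with an explicit UTC offset.  Malformed rows
    are reported by 1-based data-row number.  Rows are returned in file
    order; time-ordering is the trajectory stage's job.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in PING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pings CSV {path} missing columns {missing}")
    t = pd.to_datetime(df["timestamp_iso8601"], errors="coerce", utc=True)
    bad_rows = []
    bad_t = t.isna() & df["timestamp_iso8601"].notna() | df["timestamp_iso8601"].isna()
    bad_rows.extend((np.flatnonzero(bad_t) + 1).tolist())
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_coord = (
        lon.isna() | lat.isna() | (lon.abs() > 180.0) | (lat.abs() > 90.0)
    )
    bad_rows.extend((np.flatnonzero(bad_coord) + 1).tolist())
    if bad_rows:
        rows = sorted(set(bad_rows))
        raise ValueError(f"malformed pings CSV rows (1-based, after header): {rows}")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "t": t,
            "lon": lon.astype(float),
            "lat": lat.astype(float),
        }
    )
    return out


def write_pings(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "timestamp_iso8601": pd.Series(df["t"]).map(lambda ts: ts.isoformat()),
            "lon": df["lon"],
            "lat": df["lat"],
        }
    )
    out.to_csv(path, index=False)


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


def write_raster(path, scene: RasterScene) -> None:
    """Write a scene as a single-band GeoTIFF.

    Georeferencing goes in ModelPixelScale/ModelTiepoint tags; scene date,
    CRS descriptor and unit go in a JSON ImageDescription.  Finite grids
    round-trip losslessly (float64 band).
    """
    desc = json.dumps(
        {
            "scene_date": scene.scene_date.isoformat(),
            "crs": scene.crs.to_dict(),
            "unit": "degC",
        }
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (scene.cell_size, scene.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, scene.west, scene.north, 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        scene.values.astype(np.float64),
        description=desc,
        extratags=extratags,
    )


def read_raster(path) -> RasterScene:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible).

    A ``unit`` of ``"K"`` in the description converts values to °C via
    K − 273.15.  Raises if georeferencing or the CRS descriptor is absent.
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        desc_tag = tags.get("ImageDescription")
        if desc_tag is None:
            raise ValueError(f"{path}: missing ImageDescription (CRS descriptor)")
        meta = json.loads(desc_tag.value)
    if "crs" not in meta:
        raise ValueError(f"{path}: CRS descriptor missing from ImageDescription")
    if meta.get("unit") == "K":
        values = values - 273.15
    return RasterScene(
        scene_date=date.fromisoformat(meta["scene_date"]),
        values=values,
        cell_size=float(scale[0]),
        west=float(tie[3]),
        north=float(tie[4]),
        crs=TransverseMercator.from_dict(meta["crs"]),
    )


def raster_filename(scene_date: date, suffix: str = "") -> str:
    """Conventional per-scene filename: YYYY-MM-DD[_max|_min].tif."""
    return f"{scene_date.isoformat()}{suffix}.tif"


def write_series(series: RasterSeries, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if series.kind == "single_valued":
        for d, scene in series.scenes.items():
            write_raster(directory / raster_filename(d), scene)
    else:
        for d, (mx, mn) in series.scenes.items():
            write_raster(directory / raster_filename(d, "_max"), mx)
            write_raster(directory / raster_filename(d, "_min"), mn)


def read_series(directory, kind: str) -> RasterSeries:
    directory = Path(directory)
    scenes: dict = {}
    if kind == "single_valued":
        for p in sorted(directory.glob("*.tif")):
            scene = read_raster(p)
            scenes[scene.scene_date] = scene
    else:
        for p in sorted(directory.glob("*_max.tif")):
            mx = read_raster(p)
            mn = read_raster(p.with_name(p.name.replace("_max", "_min")))
            scenes[mx.scene_date] = (mx, mn)
    return RasterSeries(kind=kind, scenes=scenes)
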