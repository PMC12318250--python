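"""Hexagonal-grid home inference.

Home is the centroid of the grid hexagon holding the participant's maximal
elapsed dwell time, with a cross-check against the hexagon of maximal
overnight (20:00–06:00) dwell.  The grid is a flat-topped regular hexagon
tessellation; the default side of 62 m gives cells of ≈9,986 m², small
enough that a residential parcel dominates its own cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HexGrid", "HomeLocation", "hex_grid", "assign_hex", "infer_home",
           "compare_home_candidates", "overnight_overlap_seconds",
           "infer_home_with_crosscheck"]

SQRT3 = np.sqrt(3.0)

# axial-coordinate offsets of the six edge neighbours of a flat-topped hexagon
AXIAL_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

_SENTINEL = np.iinfo(np.int64).max


@dataclass(frozen=True)
class HexGrid:
    """Flat-topped regular hexagon tessellation covering a bounding box.

    Cell (q, r) has its centre at ``(1.5*s*q, sqrt(3)*s*(r + q/2))``.
    For each axial column q the grid holds a contiguous run of rows
    ``r_lo[q - q_lo] .. r_hi[q - q_lo]``; cells are identified by a dense
    integer index in (q, r) sort order, computed arithmetically.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    side_m: float
    q_lo: int
    r_lo: np.ndarray      # per-q first row
    r_hi: np.ndarray      # per-q last row (inclusive)
    offsets: np.ndarray   # per-q cumulative start index

    @property
    def n_cells(self) -> int:
        return int(self.offsets[-1])

    def index_from_qr(self, q, r):
        """Dense cell index for axial coordinates; sentinel when off-grid."""
        q = np.asarray(q, dtype=np.int64)
        r = np.asarray(r, dtype=np.int64)
        qi = q - self.q_lo
        ok_q = (qi >= 0) & (qi < len(self.r_lo))
        qi_c = np.clip(qi, 0, len(self.r_lo) - 1)
        ok = ok_q & (r >= self.r_lo[qi_c]) & (r <= self.r_hi[qi_c])
        idx = self.offsets[qi_c] + (r - self.r_lo[qi_c])
        return np.where(ok, idx, _SENTINEL)

    def qr_from_index(self, cell_index):
        idx = np.asarray(cell_index, dtype=np.int64)
        qi = np.searchsorted(self.offsets, idx, side="right") - 1
        q = qi + self.q_lo
        r = idx - self.offsets[qi] + self.r_lo[qi]
        return q, r

    def centroid(self, cell_index):
        """Centre coordinates of one or more cells."""
        q, r = self.qr_from_index(cell_index)
        x = 1.5 * self.side_m * q.astype(float)
        y = SQRT3 * self.side_m * (r.astype(float) + q.astype(float) / 2.0)
        return x, y

    def neighbours(self, cell_index: int) -> list:
        q, r = self.qr_from_index(cell_index)
        out = []
        for dq, dr in AXIAL_NEIGHBOURS:
            j = int(self.index_from_qr(int(q) + dq, int(r) + dr))
            if j != _SENTINEL:
                out.append(j)
        return out

    def vertices(self, cell_index: int) -> np.ndarray:
        """The six corner points of a cell (flat-topped orientation)."""
        cx, cy = self.centroid(cell_index)
        ang = np.radians([0, 60, 120, 180, 240, 300])
        return np.column_stack([cx + self.side_m * np.cos(ang),
                                cy + self.side_m * np.sin(ang)])


def hex_grid(bbox, side_m: float) -> HexGrid:
    """Build a hexagon grid whose cells cover ``bbox = (xmin, ymin, xmax, ymax)``.

    Centres are enumerated out to a two-side margin so every bbox point's
    true containing hexagon is on the grid.
    """
    if side_m <= 0:
        raise ValueError("hexagon side must be positive")
    xmin, ymin, xmax, ymax = (float(v) for v in bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding box")
    m = 2.0 * side_m
    q_lo = int(np.floor((xmin - m) / (1.5 * side_m))) - 1
    q_hi = int(np.ceil((xmax + m) / (1.5 * side_m))) + 1
    qs = np.arange(q_lo, q_hi + 1)
    y0 = SQRT3 * side_m * (qs / 2.0)
    r_lo = np.floor((ymin - m - y0) / (SQRT3 * side_m)).astype(np.int64) - 1
    r_hi = np.ceil((ymax + m - y0) / (SQRT3 * side_m)).astype(np.int64) + 1
    counts = r_hi - r_lo + 1
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return HexGrid(xmin, ymin, xmax, ymax, side_m, q_lo, r_lo, r_hi, offsets)


def _cube_round(qf, rf):
    """Round fractional axial coordinates to the containing hexagon."""
    xf = qf
    zf = rf
    yf = -xf - zf
    rx = np.rint(xf)
    ry = np.rint(yf)
    rz = np.rint(zf)
    dx = np.abs(rx - xf)
    dy = np.abs(ry - yf)
    dz = np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(np.int64), rz.astype(np.int64)


def assign_hex(grid: HexGrid, x, y):
    """Cell index containing each point; edge ties go to the lowest index.

    A hexagon grid is the Voronoi diagram of its centres, so containment
    is nearest-centre; the cube-rounded candidate is confirmed against its
    six neighbours and exact-distance ties break to the lowest cell index.
    Raises if any point falls outside the grid's bounding box.
    """
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    outside = (x < grid.xmin) | (x > grid.xmax) | (y < grid.ymin) | (y > grid.ymax)
    if np.any(outside):
        raise ValueError(f"{int(outside.sum())} point(s) outside the hex grid bbox")
    s = grid.side_m
    qf = (2.0 / 3.0) * x / s
    rf = -x / (3.0 * s) + (SQRT3 / 3.0) * y / s
    q0, r0 = _cube_round(qf, rf)

    n = x.shape[0]
    cand_q = np.empty((n, 7), dtype=np.int64)
    cand_r = np.empty((n, 7), dtype=np.int64)
    cand_q[:, 0] = q0
    cand_r[:, 0] = r0
    for k, (dq, dr) in enumerate(AXIAL_NEIGHBOURS, start=1):
        cand_q[:, k] = q0 + dq
        cand_r[:, k] = r0 + dr
    cx = 1.5 * s * cand_q
    cy = SQRT3 * s * (cand_r + cand_q / 2.0)
    d2 = (cx - x[:, None]) ** 2 + (cy - y[:, None]) ** 2
    best = d2.min(axis=1)
    tol = (1e-9 * s) ** 2 + 1e-12 * best
    tie = d2 <= (best + tol)[:, None]
    idx = grid.index_from_qr(cand_q, cand_r)
    idx = np.where(tie, idx, _SENTINEL)
    result = idx.min(axis=1)
    if np.any(result == _SENTINEL):
        raise ValueError("point maps to a hexagon outside the grid enumeration")
    return int(result[0]) if scalar else result


@dataclass(frozen=True)
class HomeLocation:
    participant_id: str
    cell_index: int
    x: float
    y: float
    dwell_seconds: float
    overnight_cell_index: int | None
    relation: str  # same | adjacent | disjoint


def overnight_overlap_seconds(start_s, dur_s, day0_midnight_s,
                              win_start_h: float = 20.0, win_end_h: float = 30.0):
    """Seconds of each interval falling inside nightly 20:00–06:00 windows.

    Times are seconds relative to a local midnight; windows repeat every
    24 h from ``win_start_h`` to ``win_end_h`` (hours, end may exceed 24).
    Intervals spanning window boundaries contribute only the clipped part.
    """
    start_s = np.asarray(start_s, dtype=float) - day0_midnight_s
    dur_s = np.asarray(dur_s, dtype=float)
    w0 = win_start_h * 3600.0
    wlen = (win_end_h - win_start_h) * 3600.0

    def cum(t):
        u = t - w0
        nfull = np.floor(u / 86400.0)
        rem = u - nfull * 86400.0
        return wlen * nfull + np.clip(rem, 0.0, wlen)

    return cum(start_s + dur_s) - cum(start_s)


def infer_home(path, grid: HexGrid, window: str = "all_hours") -> HomeLocation:
    """Centroid of the hexagon with maximal elapsed dwell time.

    ``path`` is an ActivityPath; dwell uses elapsed-time-to-next weights of
    retained pings, including non-wear intervals.  ``window`` is
    ``"all_hours"`` or ``"overnight"`` (20:00–06:00 local, intervals
    clipped at window boundaries).  Ties break to the earliest-visited cell.
    """
    frame = path.retained()
    if len(frame) == 0:
        raise ValueError(f"participant {path.participant_id}: empty path")
    cells = np.atleast_1d(
        assign_hex(grid, frame["x"].to_numpy(), frame["y"].to_numpy())
    )
    dur = frame["dt_s"].to_numpy(dtype=float)
    if window == "overnight":
        t = frame["t"]
        midnight = t.iloc[0].normalize()
        start_s = (t - midnight).dt.total_seconds().to_numpy()
        dur = overnight_overlap_seconds(start_s, dur, 0.0)
    elif window != "all_hours":
        raise ValueError(f"unknown window {window!r}")

    # dense dwell over the visited cells only
    uniq, inv = np.unique(cells, return_inverse=True)
    dwell = np.bincount(inv, weights=dur, minlength=len(uniq))
    first_seen = np.full(len(uniq), len(cells), dtype=np.int64)
    np.minimum.at(first_seen, inv, np.arange(len(cells)))
    max_dwell = dwell.max()
    cand = np.flatnonzero(dwell == max_dwell)
    cell = int(uniq[cand[np.argmin(first_seen[cand])]])
    cx, cy = grid.centroid(cell)
    return HomeLocation(
        participant_id=path.participant_id,
        cell_index=cell,
        x=float(cx),
        y=float(cy),
        dwell_seconds=float(max_dwell),
        overnight_cell_index=None,
        relation="",
    )


def compare_home_candidates(cell_all: int, cell_night: int, grid: HexGrid) -> str:
    """Relation between the all-hours and overnight home hexagons."""
    if cell_all == cell_night:
        return "same"
    if cell_night in grid.neighbours(cell_all):
        return "adjacent"
    return "disjoint"


def infer_home_with_crosscheck(path, grid: HexGrid) -> HomeLocation:
    """All-hours home (authoritative) plus the overnight-window cross-check."""
    home_all = infer_home(path, grid, window="all_hours")
    home_night = infer_home(path, grid, window="overnight")
    relation = compare_home_candidates(
        home_all.cell_index, home_night.cell_index, grid
    )
    return HomeLocation(
        participant_id=home_all.participant_id,
        cell_index=home_all.cell_index,
        x=home_all.x,
        y=home_all.y,
        dwell_seconds=home_all.dwell_seconds,
        overnight_cell_index=home_night.cell_index,
        relation=relation,
    )
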