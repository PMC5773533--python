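"""Shared domain model for home-cage monitoring (HCM) event-stream analysis.

Conventions used throughout the package
---------------------------------------

* **Time** is measured in seconds from Zeitgeber time 0 (ZT0, lights-on) of
  the calendar day on which a mouse-day starts.  A mouse-day (MD) runs from
  the end of the daily maintenance period (ZT8) to the start of the next one
  (ZT6 of the following day, i.e. ZT30 on this axis), giving a 22 h
  observation window ``[28800, 108000)`` seconds.
* **Intervals** are half-open ``[start, end)`` so that partitions of the
  window are unambiguous.
* **Space**: the cage floor is the rectangle ``[0, width] x [0, length]``
  in cm, origin at the corner nearest the water spout, ``x`` across the
  24 cm width and ``y`` along the 45 cm length.  The housing niche occupies
  a 10 x 10 cm square in the far corner (large ``x``, large ``y``).
* Occupancy grids partition the floor into ``rows`` cells along the length
  and ``cols`` cells across the width; a position on an interior gridline
  belongs to the higher-index cell.

The module also provides light-weight interval-set arithmetic on ``(n, 2)``
float arrays (sorted, disjoint rows), which the state-designation and
feature modules share.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_MIN = 60.0


def zt(hours: float) -> float:
    """Convert Zeitgeber hours to seconds on the package time axis."""
    return float(hours) * SECONDS_PER_HOUR


#: Default 22 h observation window: maintenance occupies ZT6-8, so a
#: mouse-day runs ZT8 -> ZT30 (= ZT6 next day).
DEFAULT_WINDOW_START = zt(8)
DEFAULT_WINDOW_END = zt(30)
WINDOW_HOURS = 22.0

#: Dark cycle ZT12-24, light cycle ZT0-12 (expressed on the MD axis the
#: light portion of the window is ZT8-12 plus ZT24-30).
DARK_CYCLE = (zt(12), zt(24))


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort file violates the CSV contract."""


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[start, end)`` in seconds from ZT0."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"Interval requires start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlap_length(self, other: "Interval") -> float:
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo < hi else None

    def as_tuple(self) -> tuple[float, float]:
        return (self.start, self.end)


DEFAULT_WINDOW = Interval(DEFAULT_WINDOW_START, DEFAULT_WINDOW_END)


# ---------------------------------------------------------------------------
# Interval-set arithmetic on (n, 2) arrays
# ---------------------------------------------------------------------------

def as_interval_array(intervals: Iterable) -> np.ndarray:
    """Coerce Intervals / pairs to a float array of shape (n, 2)."""
    rows = []
    for iv in intervals:
        if isinstance(iv, Interval):
            rows.append(iv.as_tuple())
        else:
            rows.append((float(iv[0]), float(iv[1])))
    if not rows:
        return np.empty((0, 2), dtype=float)
    arr = np.asarray(rows, dtype=float)
    return arr


def union_intervals(arr: np.ndarray) -> np.ndarray:
    """Sorted union of an interval set; touching intervals are merged.

    Zero-length rows (points) are kept if isolated, absorbed otherwise.
    """
    arr = np.asarray(arr, dtype=float).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr.copy()
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=float)


def interval_set_length(arr: np.ndarray) -> float:
    arr = np.asarray(arr, dtype=float).reshape(-1, 2)
    return float(np.sum(arr[:, 1] - arr[:, 0]))


def intersect_sets(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two disjoint sorted interval sets."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_interval_array(out)


def complement_set(arr: np.ndarray, window: Interval) -> np.ndarray:
    """Complement of a sorted disjoint set within ``window``."""
    arr = np.asarray(arr, dtype=float).reshape(-1, 2)
    out = []
    cursor = window.start
    for s, e in arr:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < window.end:
        out.append((cursor, window.end))
    return as_interval_array(out)


def covered_length_before(ivs: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Total length of a sorted disjoint interval set lying below each ``t``.

    Vectorised cumulative-coverage lookup used for clipping dwell segments
    against restriction sets.
    """
    ivs = np.asarray(ivs, dtype=float).reshape(-1, 2)
    t = np.asarray(t, dtype=float)
    if ivs.shape[0] == 0:
        return np.zeros_like(t)
    starts, ends = ivs[:, 0], ivs[:, 1]
    cum = np.concatenate([[0.0], np.cumsum(ends - starts)])
    idx = np.searchsorted(starts, t, side="right")
    covered = cum[idx]
    prev_end = np.where(idx > 0, ends[np.maximum(idx - 1, 0)], -np.inf)
    covered = covered - np.clip(prev_end - t, 0.0, None)
    return covered


def overlap_with_set(ivs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Length of overlap of each segment [lo_i, hi_i) with an interval set."""
    return covered_length_before(ivs, hi) - covered_length_before(ivs, lo)


# ---------------------------------------------------------------------------
# Cage geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CageGeometry:
    """Cage floor geometry and grid discretisations.

    The default matches a 45 x 24 cm enclosure with feeder and lickometer
    at the y = 0 end and a 10 x 10 cm housing niche in the far corner.
    The coarse home-base grid is 4 cells along the length x 2 across the
    width (11.25 x 12 cm each); exactly one coarse cell contains the whole
    niche footprint.
    """

    width_cm: float = 24.0
    length_cm: float = 45.0
    #: (x0, y0, x1, y1) footprint of the housing niche.
    niche_rect: tuple[float, float, float, float] = (14.0, 35.0, 24.0, 45.0)
    water_pos: tuple[float, float] = (4.0, 0.0)
    feeder_pos: tuple[float, float] = (20.0, 0.0)
    #: coarse home-base grid: rows along the length, cols across the width
    coarse_rows: int = 4
    coarse_cols: int = 2
    #: fine occupancy grid (288 cells by default)
    fine_rows: int = 24
    fine_cols: int = 12

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.niche_rect
        if not (0 <= x0 < x1 <= self.width_cm and 0 <= y0 < y1 <= self.length_cm):
            raise ValueError("niche_rect must lie inside the cage rectangle")
        eps = 1e-9
        corners = [(x0 + eps, y0 + eps), (x1 - eps, y0 + eps),
                   (x0 + eps, y1 - eps), (x1 - eps, y1 - eps)]
        cells = {self.coarse_cell_index(x, y) for x, y in corners}
        if len(cells) != 1:
            raise ValueError("the coarse grid must have exactly one cell containing the niche")

    def inside(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width_cm) & (y >= 0) & (y <= self.length_cm)

    def grid_cell(self, x, y, rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
        """Row (along length) and column (across width) of each position.

        Positions on an interior gridline fall in the higher-index cell;
        the far cage walls are clipped into the last cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        row = np.clip(np.floor(y / (self.length_cm / rows)).astype(int), 0, rows - 1)
        col = np.clip(np.floor(x / (self.width_cm / cols)).astype(int), 0, cols - 1)
        return row, col

    def coarse_cell_index(self, x, y) -> np.ndarray:
        """Flat index into the coarse (home-base) grid, row-major, 0..7."""
        row, col = self.grid_cell(x, y, self.coarse_rows, self.coarse_cols)
        return row * self.coarse_cols + col

    @property
    def n_coarse_cells(self) -> int:
        return self.coarse_rows * self.coarse_cols

    @property
    def n_fine_cells(self) -> int:
        return self.fine_rows * self.fine_cols

    @property
    def niche_cell(self) -> int:
        x0, y0, x1, y1 = self.niche_rect
        return int(self.coarse_cell_index((x0 + x1) / 2, (y0 + y1) / 2))

    def coarse_cell_center(self, cell: int) -> tuple[float, float]:
        row, col = divmod(int(cell), self.coarse_cols)
        cw = self.width_cm / self.coarse_cols
        ch = self.length_cm / self.coarse_rows
        return ((col + 0.5) * cw, (row + 0.5) * ch)

    def coarse_cell_rect(self, cell: int) -> tuple[float, float, float, float]:
        row, col = divmod(int(cell), self.coarse_cols)
        cw = self.width_cm / self.coarse_cols
        ch = self.length_cm / self.coarse_rows
        return (col * cw, row * ch, (col + 1) * cw, (row + 1) * ch)


DEFAULT_GEOMETRY = CageGeometry()


# ---------------------------------------------------------------------------
# Events and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementEvent:
    """A position fix emitted when displacement exceeded the 1 cm threshold."""

    t: float
    x: float
    y: float


@dataclass(frozen=True)
class IngestionEvent:
    """A feeding or drinking bout specified by a time interval.

    ``amount`` (grams) is unset on raw records; it is assigned later by
    proportional allocation of the daily total.
    """

    kind: str  # 'feed' | 'drink'
    interval: Interval
    amount: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("feed", "drink"):
            raise ValueError(f"unknown ingestion kind {self.kind!r}")


class MouseDayRecord:
    """One mouse-day of events plus daily totals and metadata.

    Movement events are stored internally as flat numpy arrays (``t, x, y``)
    because downstream stages are vectorised; the ``movement`` property
    materialises :class:`MovementEvent` objects on demand.
    """

    def __init__(
        self,
        mouse_id: str,
        strain_id: str,
        day_index: int,
        movement,
        ingestion: Sequence[IngestionEvent],
        food_total_g: float,
        water_total_g: float,
        window: Interval = DEFAULT_WINDOW,
        observed_nest_cell: Optional[int] = None,
    ) -> None:
        self.mouse_id = str(mouse_id)
        self.strain_id = str(strain_id)
        self.day_index = int(day_index)
        self.window = window
        self.food_total_g = float(food_total_g)
        self.water_total_g = float(water_total_g)
        self.observed_nest_cell = observed_nest_cell
        if isinstance(movement, tuple) and len(movement) == 3:
            t, x, y = (np.asarray(a, dtype=float).ravel() for a in movement)
        else:
            evs = list(movement)
            t = np.array([e.t for e in evs], dtype=float)
            x = np.array([e.x for e in evs], dtype=float)
            y = np.array([e.y for e in evs], dtype=float)
        order = np.argsort(t, kind="stable")
        self._mt, self._mx, self._my = t[order], x[order], y[order]
        self.ingestion: list[IngestionEvent] = sorted(
            ingestion, key=lambda e: (e.interval.start, e.interval.end)
        )

    # -- accessors ---------------------------------------------------------

    def movement_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._mt, self._mx, self._my

    @property
    def movement(self) -> list[MovementEvent]:
        return [MovementEvent(t, x, y) for t, x, y in zip(self._mt, self._mx, self._my)]

    @property
    def n_movement(self) -> int:
        return len(self._mt)

    def ingestion_arrays(self, kind: Optional[str] = None) -> np.ndarray:
        """Intervals of ingestion events as an (n, 2) array, optionally by kind."""
        rows = [e.interval.as_tuple() for e in self.ingestion if kind is None or e.kind == kind]
        return as_interval_array(rows)

    @property
    def key(self) -> tuple[str, int]:
        return (self.mouse_id, self.day_index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MouseDayRecord):
            return NotImplemented
        return (
            self.mouse_id == other.mouse_id
            and self.strain_id == other.strain_id
            and self.day_index == other.day_index
            and self.window == other.window
            and np.array_equal(self._mt, other._mt)
            and np.array_equal(self._mx, other._mx)
            and np.array_equal(self._my, other._my)
            and self.ingestion == other.ingestion
            and self.food_total_g == other.food_total_g
            and self.water_total_g == other.water_total_g
            and self.observed_nest_cell == other.observed_nest_cell
        )

    def __repr__(self) -> str:
        return (
            f"MouseDayRecord({self.mouse_id!r}, strain={self.strain_id!r}, "
            f"day={self.day_index}, n_move={self.n_movement}, "
            f"n_ingest={len(self.ingestion)})"
        )


class CohortDataset:
    """A collection of mouse-day records with a strain roster."""

    def __init__(self, records: Iterable[MouseDayRecord]) -> None:
        self.records: list[MouseDayRecord] = sorted(
            records, key=lambda r: (r.strain_id, r.mouse_id, r.day_index)
        )
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate mouse-day {rec.key}")
            seen.add(rec.key)

    @property
    def strains(self) -> list[str]:
        return sorted({r.strain_id for r in self.records})

    def mice_of(self, strain_id: str) -> list[str]:
        return sorted({r.mouse_id for r in self.records if r.strain_id == strain_id})

    @property
    def mice(self) -> list[str]:
        return sorted({r.mouse_id for r in self.records})

    def records_for_mouse(self, mouse_id: str) -> list[MouseDayRecord]:
        return [r for r in self.records if r.mouse_id == mouse_id]

    def strain_of(self, mouse_id: str) -> str:
        for r in self.records:
            if r.mouse_id == mouse_id:
                return r.strain_id
        raise KeyError(mouse_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        return self.records == other.records


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """List of invariant violations; empty iff the record is analysable."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def validate_mouse_day(
    rec: MouseDayRecord, geometry: CageGeometry = DEFAULT_GEOMETRY
) -> ValidationReport:
    """Check a record against the acquisition contract.

    Stands in for the platform's (unpublished) quality-control stage: rather
    than correcting drift, records violating the contract are rejected.
    """
    rep = ValidationReport()
    t, x, y = rec.movement_arrays()
    if np.any(np.diff(t) < 0):
        rep.add("movement events not sorted by time")
    bad = ~geometry.inside(x, y)
    for i in np.flatnonzero(bad):
        rep.add(f"movement event {i} at ({x[i]:.2f}, {y[i]:.2f}) cm outside cage")
    if len(t) and (t[0] < rec.window.start or t[-1] >= rec.window.end):
        rep.add("movement event outside observation window")
    for kind in ("feed", "drink"):
        ivs = rec.ingestion_arrays(kind)
        if len(ivs):
            if ivs[0, 0] < rec.window.start or ivs[-1, 1] > rec.window.end:
                rep.add(f"{kind} event outside observation window")
            gaps = ivs[1:, 0] - ivs[:-1, 1]
            for i in np.flatnonzero(gaps < 0):
                rep.add(
                    f"overlapping {kind} events at "
                    f"[{ivs[i, 0]:.0f},{ivs[i, 1]:.0f}) and [{ivs[i + 1, 0]:.0f},{ivs[i + 1, 1]:.0f})"
                )
    if rec.food_total_g < 0 or rec.water_total_g < 0:
        rep.add("negative daily total")
    feed_time = interval_set_length(rec.ingestion_arrays("feed"))
    if any(e.kind == "feed" for e in rec.ingestion) and feed_time <= 0:
        rep.add("feeding events present but total feeding time is zero")
    return rep


# ---------------------------------------------------------------------------
# Circadian bin scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZtBinScheme:
    """Eleven contiguous 2 h bins covering the 22 h observation window."""

    bins: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if len(self.bins) != 11:
            raise ValueError("expected exactly 11 bins")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.end != b.start:
                raise ValueError("bins must be contiguous")

    @property
    def labels(self) -> list[str]:
        out = []
        for iv in self.bins:
            h0 = (iv.start / SECONDS_PER_HOUR) % 24
            h1 = (iv.end / SECONDS_PER_HOUR) % 24
            h1 = 24 if h1 == 0 else h1
            out.append(f"{h0:g}-{h1:g}")
        return out

    def index_of(self, t: float) -> int:
        for i, iv in enumerate(self.bins):
            if iv.contains(t):
                return i
        raise ValueError(f"time {t} outside the bin scheme")

    def index_of_array(self, t: np.ndarray) -> np.ndarray:
        edges = np.array([iv.start for iv in self.bins] + [self.bins[-1].end])
        idx = np.searchsorted(edges, np.asarray(t, dtype=float), side="right") - 1
        if np.any((idx < 0) | (idx >= len(self.bins))):
            raise ValueError("time outside the bin scheme")
        return idx

    def __len__(self) -> int:
        return len(self.bins)


def zt_bin_partition(window: Interval = DEFAULT_WINDOW) -> ZtBinScheme:
    """Partition the standard 22 h window into 11 two-hour bins.

    Raises for any window whose duration is not exactly 22 h: the bin
    scheme is tied to the daily maintenance gap (ZT6-8) that shortens the
    observation day.
    """
    if abs(window.duration - WINDOW_HOURS * SECONDS_PER_HOUR) > 1e-6:
        raise ValueError(f"nonstandard window length {window.duration} s; expected 22 h")
    width = 2 * SECONDS_PER_HOUR
    bins = tuple(
        Interval(window.start + i * width, window.start + (i + 1) * width) for i in range(11)
    )
    return ZtBinScheme(bins)


# ---------------------------------------------------------------------------
# Cohort I/O (CSV dialect)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["mouse_id", "strain", "day", "kind", "t_start", "t_end", "x", "y"]
TOTALS_COLUMNS = ["mouse_id", "day", "food_g", "water_g", "nest_cell"]
EVENTS_FILE = "events.csv"
TOTALS_FILE = "totals.csv"


def write_cohort(cohort: CohortDataset, path: str) -> None:
    """Write a cohort to ``path`` (a directory) as events.csv + totals.csv."""
    os.makedirs(path, exist_ok=True)
    ev_rows = []
    tot_rows = []
    for rec in cohort:
        t, x, y = rec.movement_arrays()
        for i in range(len(t)):
            ev_rows.append(
                (rec.mouse_id, rec.strain_id, rec.day_index, "move", t[i], None, x[i], y[i])
            )
        for e in rec.ingestion:
            ev_rows.append(
                (rec.mouse_id, rec.strain_id, rec.day_index, e.kind,
                 e.interval.start, e.interval.end, None, None)
            )
        tot_rows.append(
            (rec.mouse_id, rec.day_index, rec.food_total_g, rec.water_total_g,
             rec.observed_nest_cell)
        )
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(
        os.path.join(path, EVENTS_FILE), index=False
    )
    pd.DataFrame(tot_rows, columns=TOTALS_COLUMNS).to_csv(
        os.path.join(path, TOTALS_FILE), index=False
    )


def read_cohort(
    path: str,
    window: Interval = DEFAULT_WINDOW,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> CohortDataset:
    """Read a cohort from a directory holding events.csv and totals.csv.

    The parse is a lossless round-trip with :func:`write_cohort`.  Errors
    name the offending file and (1-based, header-inclusive) line.
    """
    ev_path = os.path.join(path, EVENTS_FILE)
    tot_path = os.path.join(path, TOTALS_FILE)
    for p in (ev_path, tot_path):
        if not os.path.exists(p):
            raise CohortFormatError(f"missing cohort file {p}")
    ev = pd.read_csv(ev_path, float_precision="round_trip")
    if list(ev.columns) != EVENT_COLUMNS:
        raise CohortFormatError(f"{ev_path}: expected header {','.join(EVENT_COLUMNS)}")
    tot = pd.read_csv(tot_path, float_precision="round_trip")
    if list(tot.columns) != TOTALS_COLUMNS:
        raise CohortFormatError(f"{tot_path}: expected header {','.join(TOTALS_COLUMNS)}")

    def _line(i: int) -> int:  # header is line 1
        return int(i) + 2

    bad_kind = ~ev["kind"].isin(["move", "feed", "drink"])
    if bad_kind.any():
        i = int(np.flatnonzero(bad_kind.to_numpy())[0])
        raise CohortFormatError(f"{ev_path}:{_line(i)}: unknown kind {ev['kind'].iloc[i]!r}")
    move = ev["kind"] == "move"
    if ev.loc[move, ["t_start", "x", "y"]].isna().any().any():
        i = int(ev.index[move & ev[["t_start", "x", "y"]].isna().any(axis=1)][0])
        raise CohortFormatError(f"{ev_path}:{_line(i)}: move row missing t_start/x/y")
    if ev.loc[~move, ["t_start", "t_end"]].isna().any().any():
        i = int(ev.index[(~move) & ev[["t_start", "t_end"]].isna().any(axis=1)][0])
        raise CohortFormatError(f"{ev_path}:{_line(i)}: ingestion row missing t_start/t_end")
    out_win = (ev["t_start"] < window.start) | (
        np.where(move, ev["t_start"], ev["t_end"].fillna(window.start)) > window.end
    ) | (move & (ev["t_start"] >= window.end))
    if out_win.any():
        i = int(np.flatnonzero(out_win.to_numpy())[0])
        raise CohortFormatError(f"{ev_path}:{_line(i)}: event outside observation window")

    if tot.duplicated(["mouse_id", "day"]).any():
        i = int(np.flatnonzero(tot.duplicated(["mouse_id", "day"]).to_numpy())[0])
        raise CohortFormatError(f"{tot_path}:{_line(i)}: duplicate (mouse_id, day)")
    totals = {
        (str(r.mouse_id), int(r.day)): r for r in tot.itertuples(index=False)
    }

    records = []
    for (mouse_id, day), grp in ev.groupby(["mouse_id", "day"], sort=True):
        mouse_id, day = str(mouse_id), int(day)
        strains = grp["strain"].unique()
        if len(strains) != 1:
            raise CohortFormatError(
                f"{ev_path}: conflicting strain labels for mouse {mouse_id} day {day}"
            )
        key = (mouse_id, day)
        if key not in totals:
            raise CohortFormatError(f"{tot_path}: missing totals row for {key}")
        trow = totals[key]
        mv = grp[grp["kind"] == "move"]
        ing = grp[grp["kind"] != "move"]
        ingestion = [
            IngestionEvent(str(r.kind), Interval(float(r.t_start), float(r.t_end)))
            for r in ing.itertuples(index=False)
        ]
        nest = trow.nest_cell
        nest = None if pd.isna(nest) else int(nest)
        records.append(
            MouseDayRecord(
                mouse_id=mouse_id,
                strain_id=str(strains[0]),
                day_index=day,
                movement=(
                    mv["t_start"].to_numpy(float),
                    mv["x"].to_numpy(float),
                    mv["y"].to_numpy(float),
                ),
                ingestion=ingestion,
                food_total_g=float(trow.food_g),
                water_total_g=float(trow.water_g),
                window=window,
                observed_nest_cell=nest,
            )
        )
    cohort = CohortDataset(records)
    for rec in cohort:
        rep = validate_mouse_day(rec, geometry)
        if not rep.ok:
            raise CohortFormatError(
                f"{ev_path}: invalid record {rec.key}: {rep.violations[0]}"
            )
    return cohort
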