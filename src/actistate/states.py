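"""Active State / Inactive State designation by inter-event gap bridging.

An Active State (AS) is built from the union of movement, feeding, and
drinking events occurring while the animal is outside its Home Base:
consecutive events separated by a gap of at most the Inactive State
Threshold (IST, default 20 min) are connected into a single AS running
from the first event's start to the last event's end.  Gaps exceeding the
IST become Inactive States (ISs), together with any leading or trailing
event-free remainder of the observation window.  The two state sets are
mutually exclusive and exhaustively cover the window.

Conventions:

* a gap exactly equal to the IST is bridged (only gaps *exceeding* the
  threshold split states);
* ingestion events always count as activity regardless of position (the
  feeder and lickometer are sites of active behavior); only movement
  events are filtered by Home Base membership;
* an isolated event with greater-than-IST gaps on both sides yields a
  degenerate zero-length AS, which carries no time but marks the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_GEOMETRY,
    CageGeometry,
    Interval,
    MouseDayRecord,
    as_interval_array,
    complement_set,
    interval_set_length,
    union_intervals,
)
from .spatial import HomeBase

DEFAULT_IST_S = 1200.0  # 20 min


@dataclass
class StatePartition:
    """Exhaustive, disjoint AS/IS partition of one observation window.

    ``active`` and ``inactive`` are ``(n, 2)`` arrays of half-open
    intervals in seconds.  Active intervals may be zero-length (isolated
    single events); inactive intervals always have positive length.
    """

    window: Interval
    active: np.ndarray
    inactive: np.ndarray
    ist_s: float

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=float).reshape(-1, 2)
        self.inactive = np.asarray(self.inactive, dtype=float).reshape(-1, 2)
        if np.any(self.active[:, 1] < self.active[:, 0]):
            raise ValueError("active intervals must have start <= end")
        if np.any(self.inactive[:, 1] <= self.inactive[:, 0]):
            raise ValueError("inactive intervals must have start < end")
        for arr in (self.active, self.inactive):
            if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("state intervals must be sorted and disjoint")
        total = interval_set_length(self.active) + interval_set_length(self.inactive)
        if abs(total - self.window.duration) > 1e-6:
            raise ValueError("states do not partition the window")
        if len(self.active) > 1:
            gaps = self.active[1:, 0] - self.active[:-1, 1]
            if np.any(gaps <= self.ist_s + 1e-9):
                raise ValueError("internal gap between active states must exceed the IST")

    @property
    def n_active(self) -> int:
        return len(self.active)

    @property
    def total_active_s(self) -> float:
        return interval_set_length(self.active)

    @property
    def as_durations_s(self) -> np.ndarray:
        return self.active[:, 1] - self.active[:, 0]


def activity_intervals(
    rec: MouseDayRecord,
    hb: HomeBase,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Out-of-Home-Base activity events as a sorted (n, 2) interval array.

    Movement events contribute zero-length intervals at their timestamp and
    are dropped when their position lies inside a Home Base cell; ingestion
    events contribute their full interval unconditionally.
    """
    t, x, y = rec.movement_arrays()
    rows = []
    if len(t):
        cells = geometry.coarse_cell_index(x, y)
        outside = ~np.isin(cells, list(hb.cells))
        rows.append(np.column_stack([t[outside], t[outside]]))
    ing = rec.ingestion_arrays()
    if len(ing):
        rows.append(ing)
    if not rows:
        return np.empty((0, 2), dtype=float)
    arr = np.concatenate(rows, axis=0)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def _merge_events(events: np.ndarray, ist_s: float) -> np.ndarray:
    """Connect events whose inter-event gap is at most ``ist_s``."""
    if len(events) == 0:
        return np.empty((0, 2), dtype=float)
    starts = events[:, 0]
    ends = np.maximum.accumulate(events[:, 1])
    gaps = starts[1:] - ends[:-1]
    cut = np.flatnonzero(gaps > ist_s) + 1
    seg_starts = starts[np.concatenate([[0], cut])]
    seg_ends = ends[np.concatenate([cut - 1, [len(events) - 1]])]
    return np.column_stack([seg_starts, seg_ends])


def designate_states(
    rec: MouseDayRecord,
    hb: HomeBase,
    ist_s: float = DEFAULT_IST_S,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> StatePartition:
    """Partition a mouse-day into Active and Inactive States.

    A record with no out-of-Home-Base activity yields zero ASs and a
    single IS spanning the window (not an error).
    """
    if ist_s <= 0:
        raise ValueError("ist_s must be positive")
    events = activity_intervals(rec, hb, geometry)
    active = _merge_events(events, ist_s)
    # clip to the observation window (events are validated to lie inside)
    if len(active):
        active[:, 0] = np.clip(active[:, 0], rec.window.start, rec.window.end)
        active[:, 1] = np.clip(active[:, 1], rec.window.start, rec.window.end)
    positive = active[active[:, 1] > active[:, 0]] if len(active) else active
    inactive = complement_set(positive, rec.window)
    return StatePartition(rec.window, active, inactive, float(ist_s))


def states_oracle(
    rec: MouseDayRecord,
    hb: HomeBase,
    ist_s: float = DEFAULT_IST_S,
    tick_s: float = 1.0,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> StatePartition:
    """Brute-force state labeling on a regular tick grid (test oracle).

    Labels every tick of the window active or inactive from first
    principles: a tick is active iff it falls inside an activity event, or
    lies in a gap whose flanking event times are within the IST of each
    other.  Event groups are then assembled from the tick labels, with AS
    boundaries snapped to exact event times.  Quadratic bookkeeping and a
    per-tick scan make this slow but transparent; it exists for testing.
    """
    events = activity_intervals(rec, hb, geometry)
    if len(events) == 0:
        return StatePartition(
            rec.window,
            np.empty((0, 2)),
            as_interval_array([rec.window]),
            float(ist_s),
        )
    comps = union_intervals(events)
    n_ticks = int(np.floor((rec.window.duration) / tick_s))
    ticks = rec.window.start + tick_s * np.arange(n_ticks + 1)

    # label ticks: covered by an event component, or inside a bridgeable gap
    starts, ends = comps[:, 0], comps[:, 1]
    idx = np.searchsorted(starts, ticks, side="right")  # component started at/before tick
    prev_end = np.where(idx > 0, ends[np.maximum(idx - 1, 0)], -np.inf)
    next_start = np.where(idx < len(comps), starts[np.minimum(idx, len(comps) - 1)], np.inf)
    covered = (idx > 0) & (ticks <= prev_end)
    bridged = (next_start - prev_end) <= ist_s
    tick_active = covered | bridged

    # group consecutive components: same AS iff every tick strictly inside
    # the gap between them is labeled active (gaps without ticks merge)
    group = np.zeros(len(comps), dtype=int)
    for k in range(1, len(comps)):
        lo, hi = ends[k - 1], starts[k]
        inside = (ticks > lo) & (ticks < hi)
        joined = bool(np.all(tick_active[inside])) if inside.any() else True
        group[k] = group[k - 1] + (0 if joined else 1)
    active_rows = []
    for g in range(group[-1] + 1):
        members = np.flatnonzero(group == g)
        active_rows.append((starts[members[0]], ends[members[-1]]))
    active = np.asarray(active_rows, dtype=float)
    positive = active[active[:, 1] > active[:, 0]]
    inactive = complement_set(positive, rec.window)
    return StatePartition(rec.window, active, inactive, float(ist_s))


def ist_sweep(
    rec: MouseDayRecord,
    hb: HomeBase,
    ist_values_s: Sequence[float],
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """AS count as a function of the IST (robustness sweep).

    Counts are non-increasing in the threshold: a larger IST can only
    bridge more gaps.
    """
    ist_values_s = list(ist_values_s)
    if sorted(ist_values_s) != ist_values_s:
        raise ValueError("ist_values_s must be sorted ascending")
    rows = [
        (v, designate_states(rec, hb, ist_s=v, geometry=geometry).n_active)
        for v in ist_values_s
    ]
    return pd.DataFrame(rows, columns=["ist_s", "n_as"])
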