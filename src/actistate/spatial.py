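"""Spatial occupancy maps and Home Base designation.

Position is interpolated by sample-and-hold: the animal is taken to occupy
its last recorded position until the next movement event (consistent with
events being emitted only on >= 1 cm displacement).  Time before the first
movement event of a record is uncounted (position undefined); occupancy
proportions are normalised by total counted time.

Home Base designation on the coarse 2 x 4 grid follows three ordered
rules applied to full-day occupancy:

1. if the cell with the largest occupancy is the niche cell, the Home
   Base is the niche cell;
2. otherwise, if the top cell holds more than half of total time, it is
   the Home Base on its own;
3. otherwise the Home Base is the edge-adjacent pair of cells with the
   largest summed occupancy (ties broken by lowest cell-index pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import (
    DEFAULT_GEOMETRY,
    CageGeometry,
    MouseDayRecord,
    overlap_with_set,
)


class OccupancyError(ValueError):
    """Raised when occupancy is undefined (no movement events / no time)."""


@dataclass
class OccupancyGrid:
    """Time-fraction occupancy over a rows x cols partition of the cage."""

    rows: int
    cols: int
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (self.rows, self.cols):
            raise ValueError("proportions shape must be (rows, cols)")
        if np.any(self.proportions < -1e-12):
            raise ValueError("occupancy proportions must be nonnegative")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy proportions must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def flat(self) -> np.ndarray:
        return self.proportions.ravel()

    def argmax_cell(self) -> int:
        return int(np.argmax(self.flat()))


@dataclass(frozen=True)
class HomeBase:
    """One or two coarse-grid cells where the animal nests.

    ``basis`` records which designation rule fired: ``niche-max``,
    ``single-majority``, or ``contiguous-pair``.
    """

    cells: tuple[int, ...]
    basis: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.cells) <= 2:
            raise ValueError("Home Base must consist of 1 or 2 cells")
        if self.basis not in ("niche-max", "single-majority", "contiguous-pair"):
            raise ValueError(f"unknown basis {self.basis!r}")

    def contains_xy(self, x, y, geometry: CageGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
        cells = geometry.coarse_cell_index(x, y)
        return np.isin(cells, list(self.cells))


def position_occupancy(
    rec: MouseDayRecord,
    rows: int,
    cols: int,
    restrict_to: Optional[np.ndarray] = None,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
) -> OccupancyGrid:
    """Sample-and-hold dwell-time occupancy on a rows x cols grid.

    ``restrict_to`` (an (n, 2) interval array, e.g. the Inactive States of
    a partition) clips every dwell segment to the given set before
    counting.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dimensions must be positive")
    t, x, y = rec.movement_arrays()
    if len(t) == 0:
        raise OccupancyError(f"record {rec.key} has no movement events; position undefined")
    seg_lo = t
    seg_hi = np.concatenate([t[1:], [rec.window.end]])
    if restrict_to is not None:
        dwell = overlap_with_set(np.asarray(restrict_to, float).reshape(-1, 2), seg_lo, seg_hi)
    else:
        dwell = seg_hi - seg_lo
    r, c = geometry.grid_cell(x, y, rows, cols)
    grid = np.zeros((rows, cols), dtype=float)
    np.add.at(grid, (r, c), dwell)
    total = grid.sum()
    if total <= 0:
        raise OccupancyError(f"record {rec.key}: no counted dwell time")
    return OccupancyGrid(rows, cols, grid / total)


def adjacent_cell_pairs(rows: int, cols: int) -> list[tuple[int, int]]:
    """All edge-adjacent cell-index pairs of a rows x cols grid (row-major)."""
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                pairs.append((i, i + 1))
            if r + 1 < rows:
                pairs.append((i, i + cols))
    return pairs


def designate_home_base(
    rec: MouseDayRecord, geometry: CageGeometry = DEFAULT_GEOMETRY
) -> HomeBase:
    """Apply the three ordered Home Base rules to full-day coarse occupancy."""
    occ = position_occupancy(rec, geometry.coarse_rows, geometry.coarse_cols, geometry=geometry)
    p = occ.flat()
    top = int(np.argmax(p))
    if top == geometry.niche_cell:
        return HomeBase((top,), "niche-max")
    if p[top] > 0.5:
        return HomeBase((top,), "single-majority")
    pairs = adjacent_cell_pairs(geometry.coarse_rows, geometry.coarse_cols)
    sums = [p[i] + p[j] for i, j in pairs]
    best = pairs[int(np.argmax(sums))]  # argmax takes the first = lowest index pair on ties
    return HomeBase(tuple(sorted(best)), "contiguous-pair")
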