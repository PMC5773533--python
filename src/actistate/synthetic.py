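"""Generative model of home-cage behavior with known ground truth.

Each simulated mouse-day is an alternating renewal process of Inactive
and Active States.  Within a circadian bin ``b`` the AS duration is
exponential around a strain's ``mean_as_duration_min[b]`` and the IS
duration is a hard floor (``min_is_duration_min``) plus an exponential
chosen so the expected AS time fraction matches the strain's target AS
probability for that bin.  During ISs the animal sits in its nest cell
(emitting only within-nest position jitter); during ASs it leaves the
nest and random-walks through the open cage, emitting a movement event
every few seconds, feeding with a probability that decays exponentially
from AS onset, and drinking at a baseline rate that rises in the final
seconds before AS offset.

Because every simulated between-AS gap is at least ``min_is_duration_min``
(default 21 min, above the 20 min Inactive State Threshold) and every
within-AS inter-event gap is far below it, gap-bridging state designation
recovers the ground-truth AS intervals *exactly*; the simulator therefore
serves as an oracle for the full analysis chain.  Event times are
quantised to whole seconds so that tick-grid brute-force labeling is also
exact.

Event counts default to roughly two orders of magnitude below the real
acquisition system (hundreds to thousands of events per day rather than
tens of thousands) to keep test runtime low; ``movement_dt_s`` scales
this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core_model import (
    DEFAULT_GEOMETRY,
    DEFAULT_WINDOW,
    CageGeometry,
    CohortDataset,
    IngestionEvent,
    Interval,
    MouseDayRecord,
    zt_bin_partition,
)

SLOT_S = 5.0  # ingestion scheduling granularity (matches profile bins)


@dataclass
class StrainParams:
    """Ground-truth behavioral parameters of one simulated strain."""

    strain_id: str
    asp_profile: np.ndarray  # 11 target AS-time fractions in (0, 1)
    mean_as_duration_min: np.ndarray  # per bin
    feed_onset_decay: float  # per minute of elapsed AS time
    drink_offset_width_s: float
    feed_rate_g_per_min: float
    drink_rate_g_per_min: float
    speed_cm_per_s: float
    nest_cell: int
    feed_p0: float = 0.4  # extra per-5 s-slot feeding probability at AS onset
    feed_p_base: float = 0.06  # persistent within-AS feeding probability
    drink_p_base: float = 0.03
    drink_p_offset: float = 0.5

    def __post_init__(self) -> None:
        self.asp_profile = np.asarray(self.asp_profile, dtype=float)
        self.mean_as_duration_min = np.asarray(self.mean_as_duration_min, dtype=float)
        if self.asp_profile.shape != (11,) or self.mean_as_duration_min.shape != (11,):
            raise ValueError("asp_profile and mean_as_duration_min must have 11 entries")
        if np.any((self.asp_profile <= 0) | (self.asp_profile >= 1)):
            raise ValueError("asp_profile entries must lie in (0, 1)")
        if (
            np.any(self.mean_as_duration_min <= 0)
            or self.feed_onset_decay < 0
            or self.drink_offset_width_s <= 0
            or self.feed_rate_g_per_min <= 0
            or self.drink_rate_g_per_min <= 0
            or self.speed_cm_per_s <= 0
        ):
            raise ValueError("durations, widths, and rates must be positive")


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    The default cohort shape (9 mice per strain, 12 days each) mirrors a
    one-cage-per-animal monitoring run with a 12-day analysis period.
    ``min_is_duration_min`` must exceed the 20 min designation threshold
    and ``max_within_as_gap_min`` must stay below it; this separation is
    what makes state recovery exact.
    """

    strains: list[StrainParams] = field(default_factory=list)
    mice_per_strain: int = 9
    days_per_mouse: int = 12
    seed: int = 0
    min_is_duration_min: float = 21.0
    max_within_as_gap_min: float = 10.0
    min_as_duration_min: float = 2.0
    movement_dt_s: float = 15.0
    is_jitter_dt_s: float = 300.0

    def __post_init__(self) -> None:
        if not self.min_is_duration_min > 20.0:
            raise ValueError("min_is_duration_min must exceed the default 20 min IST")
        if not self.max_within_as_gap_min < 20.0:
            raise ValueError("max_within_as_gap_min must stay below the default IST")
        if self.movement_dt_s > self.max_within_as_gap_min * 60.0:
            raise ValueError("movement_dt_s would violate the within-AS gap bound")


@dataclass
class GroundTruth:
    """What the generator knows and the analysis should recover."""

    as_intervals: np.ndarray  # (k, 2) seconds
    nest_cell: int


def _required_is_mean_s(p: float, mean_as_s: float, min_is_s: float) -> float:
    """Exponential excess IS mean so that E[AS]/(E[AS]+E[IS]) = p."""
    mean_is_s = mean_as_s * (1.0 - p) / p
    excess = mean_is_s - min_is_s
    if excess <= 0:
        raise ValueError(
            f"target AS fraction {p:.3f} incompatible with the minimum IS duration"
        )
    return excess


def _piecewise_exponential(rng, start_s: float, bins, mean_of_bin, window_end: float) -> float:
    """Waiting time with a piecewise-constant hazard 1/mean_of_bin(b(t)).

    The state-ending hazard follows the circadian bin active at the
    *current* time rather than the bin at state onset, so expected state
    fractions track the target profile within each bin instead of lagging
    by a full state duration across bin boundaries.
    """
    t = start_s
    total = 0.0
    while t < window_end - 1e-9:
        b = int(np.searchsorted([iv.end for iv in bins.bins], t, side="right"))
        b = min(b, len(bins.bins) - 1)
        e = rng.exponential(mean_of_bin(b))
        bin_end = bins.bins[b].end
        if t + e < bin_end:
            return total + e
        total += bin_end - t
        t = bin_end
    return total


def _nest_jitter(rng, geometry: CageGeometry, nest_cell: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    x0, y0, x1, y1 = geometry.coarse_cell_rect(nest_cell)
    pad = 1.0
    return (
        rng.uniform(x0 + pad, x1 - pad, n),
        rng.uniform(y0 + pad, y1 - pad, n),
    )


def _walk_positions(
    rng,
    geometry: CageGeometry,
    nest_cell: int,
    times: np.ndarray,
    speed: float,
    start_xy: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Random walk over the cage floor avoiding the nest cell.

    Step lengths follow speed x elapsed time (capped at the cage
    diagonal) with uniform headings; wall collisions are handled by
    billiard reflection (unfold-and-fold), and any point landing inside
    the nest cell is displaced one cell across the cage width.
    """
    n = len(times)
    dts = np.diff(times, prepend=times[0])
    cap = np.hypot(geometry.width_cm, geometry.length_cm)
    steps = np.minimum(speed * np.maximum(dts, 1.0), cap) * rng.uniform(0.3, 1.0, n)
    steps[0] = 0.0
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    ux = start_xy[0] + np.cumsum(steps * np.cos(theta))
    uy = start_xy[1] + np.cumsum(steps * np.sin(theta))

    def _fold(u: np.ndarray, lim: float) -> np.ndarray:
        m = np.mod(np.abs(u), 2.0 * lim)
        return lim - np.abs(m - lim)

    xs = np.clip(_fold(ux, geometry.width_cm), 0.05, geometry.width_cm - 0.05)
    ys = np.clip(_fold(uy, geometry.length_cm), 0.05, geometry.length_cm - 0.05)
    nx0, ny0, nx1, ny1 = geometry.coarse_cell_rect(nest_cell)
    inside = (xs >= nx0) & (xs <= nx1) & (ys >= ny0) & (ys <= ny1)
    cell_w = geometry.width_cm / geometry.coarse_cols
    shift = -cell_w if nx0 > 0 else cell_w
    xs = np.where(inside, np.clip(xs + shift, 0.05, geometry.width_cm - 0.05), xs)
    return xs, ys


def simulate_mouse_day(
    params: StrainParams,
    cfg: SimulationConfig,
    seed,
    mouse_id: str = "m00",
    day_index: int = 0,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
    window: Interval = DEFAULT_WINDOW,
) -> tuple[MouseDayRecord, GroundTruth]:
    """Simulate one mouse-day; returns the record and its ground truth."""
    rng = np.random.default_rng(seed)
    bins = zt_bin_partition(window)
    min_is_s = cfg.min_is_duration_min * 60.0
    min_as_s = cfg.min_as_duration_min * 60.0
    # feasibility of every bin's target, up-front
    for b in range(11):
        _required_is_mean_s(
            float(params.asp_profile[b]),
            float(params.mean_as_duration_min[b]) * 60.0,
            min_is_s,
        )

    move_t: list[np.ndarray] = []
    move_x: list[np.ndarray] = []
    move_y: list[np.ndarray] = []
    ingestion: list[IngestionEvent] = []
    as_rows: list[tuple[float, float]] = []

    # anchor position at window start so sample-and-hold occupancy is defined
    jx, jy = _nest_jitter(rng, geometry, params.nest_cell, 1)
    move_t.append(np.array([window.start]))
    move_x.append(jx)
    move_y.append(jy)

    def _is_excess_mean(b: int) -> float:
        return _required_is_mean_s(
            float(params.asp_profile[b]),
            float(params.mean_as_duration_min[b]) * 60.0,
            min_is_s,
        )

    def _as_excess_mean(b: int) -> float:
        return max(float(params.mean_as_duration_min[b]) * 60.0 - min_as_s, 60.0)

    t = window.start
    end_guard = window.end - 1.0  # events strictly inside the half-open window
    while True:
        is_dur = min_is_s + _piecewise_exponential(
            rng, t + min_is_s, bins, _is_excess_mean, window.end
        )
        is_dur = float(np.round(is_dur))
        # within-nest jitter events during the IS
        n_jit = int(max(0, (min(t + is_dur, end_guard) - t) // cfg.is_jitter_dt_s))
        if n_jit:
            jt = np.round(t + cfg.is_jitter_dt_s * (np.arange(n_jit) + 1))
            jt = jt[jt < end_guard]
            jx, jy = _nest_jitter(rng, geometry, params.nest_cell, len(jt))
            move_t.append(jt)
            move_x.append(jx)
            move_y.append(jy)
        t += is_dur
        if t >= end_guard - min_as_s:
            break
        as_dur = min_as_s + _piecewise_exponential(
            rng, t + min_as_s, bins, _as_excess_mean, window.end
        )
        as_start = float(np.round(t))
        as_end = float(np.round(min(t + as_dur, end_guard)))
        if as_end - as_start < min_as_s:
            as_end = min(as_start + min_as_s, end_guard)
        # movement: waypoints every ~movement_dt_s (first at onset, last at
        # offset), each expanded into a 1 s-spaced micro-burst so locomotor
        # episodes carry measurable duration
        n_steps = max(2, int((as_end - as_start) / cfg.movement_dt_s) + 1)
        mt = np.unique(
            np.round(np.linspace(as_start, as_end, n_steps))
        )
        mx, my = _walk_positions(
            rng, geometry, params.nest_cell, mt, params.speed_cm_per_s,
            geometry.coarse_cell_center((params.nest_cell + 4) % geometry.n_coarse_cells),
        )
        burst_t = [mt]
        burst_x = [mx]
        burst_y = [my]
        for lag in (1.0, 2.0):
            keep = mt + lag <= as_end
            jx = np.clip(mx[keep] + rng.uniform(-1.5, 1.5, keep.sum()), 0.05,
                         geometry.width_cm - 0.05)
            jy = np.clip(my[keep] + rng.uniform(-1.5, 1.5, keep.sum()), 0.05,
                         geometry.length_cm - 0.05)
            burst_t.append(mt[keep] + lag)
            burst_x.append(jx)
            burst_y.append(jy)
        bt = np.concatenate(burst_t)
        order = np.argsort(bt, kind="stable")
        move_t.append(bt[order])
        move_x.append(np.concatenate(burst_x)[order])
        move_y.append(np.concatenate(burst_y)[order])
        # ingestion on 5 s slots inside the AS; a random integer phase per
        # AS avoids locking event edges to the onset-aligned profile grid
        phase = float(rng.integers(0, int(SLOT_S)))
        n_slots = int((as_end - as_start - phase) // SLOT_S)
        if n_slots > 0:
            slot_t0 = as_start + phase + SLOT_S * np.arange(n_slots)
            mins_from_onset = (slot_t0 - as_start) / 60.0
            p_feed = params.feed_p_base + params.feed_p0 * np.exp(
                -params.feed_onset_decay * mins_from_onset
            )
            near_offset = (as_end - (slot_t0 + SLOT_S)) <= params.drink_offset_width_s
            p_drink = np.where(
                near_offset, params.drink_p_base + params.drink_p_offset, params.drink_p_base
            )
            u = rng.uniform(size=(2, n_slots))
            feed_on = u[0] < p_feed
            drink_on = (u[1] < p_drink) & ~feed_on  # keep slots single-behavior
            for s0 in slot_t0[feed_on]:
                ingestion.append(IngestionEvent("feed", Interval(s0, s0 + SLOT_S)))
            for s0 in slot_t0[drink_on]:
                ingestion.append(IngestionEvent("drink", Interval(s0, s0 + SLOT_S)))
        as_rows.append((as_start, as_end))
        t = as_end

    feed_s = sum(e.interval.duration for e in ingestion if e.kind == "feed")
    drink_s = sum(e.interval.duration for e in ingestion if e.kind == "drink")
    rec = MouseDayRecord(
        mouse_id=mouse_id,
        strain_id=params.strain_id,
        day_index=day_index,
        movement=(np.concatenate(move_t), np.concatenate(move_x), np.concatenate(move_y)),
        ingestion=ingestion,
        food_total_g=feed_s / 60.0 * params.feed_rate_g_per_min,
        water_total_g=drink_s / 60.0 * params.drink_rate_g_per_min,
        window=window,
        observed_nest_cell=params.nest_cell,
    )
    truth = GroundTruth(np.asarray(as_rows, dtype=float).reshape(-1, 2), params.nest_cell)
    return rec, truth


def simulate_cohort(
    cfg: SimulationConfig,
    geometry: CageGeometry = DEFAULT_GEOMETRY,
    window: Interval = DEFAULT_WINDOW,
) -> tuple[CohortDataset, dict[tuple[str, int], GroundTruth]]:
    """Simulate mice x days for every strain with per-MD derived seeds."""
    if not cfg.strains:
        raise ValueError("SimulationConfig.strains is empty")
    records = []
    truths: dict[tuple[str, int], GroundTruth] = {}
    for si, params in enumerate(cfg.strains):
        for mi in range(cfg.mice_per_strain):
            mouse_id = f"{params.strain_id}_m{mi:02d}"
            for day in range(cfg.days_per_mouse):
                ss = np.random.SeedSequence([cfg.seed, si, mi, day])
                rec, truth = simulate_mouse_day(
                    params, cfg, ss, mouse_id=mouse_id, day_index=day,
                    geometry=geometry, window=window,
                )
                records.append(rec)
                truths[rec.key] = truth
    return CohortDataset(records), truths


def default_strain_library(
    n_strains: int, seed: int = 0, nocturnal_bins=range(2, 8)
) -> list[StrainParams]:
    """Distinct, nocturnally biased strain parameter sets.

    Activity profiles are Gaussian bumps over the dark-cycle bins with
    strain-specific peak phase, amplitude, and width, on a low light-cycle
    baseline; rejection sampling enforces a pairwise L2 distance floor of
    0.05 between profiles.  Nest cells alternate between the niche cell
    and its neighbor to exercise both Home Base designation rules.
    """
    if not 2 <= n_strains <= 32:
        raise ValueError("n_strains must be between 2 and 32")
    rng = np.random.default_rng(seed)
    dark = np.array(sorted(nocturnal_bins))
    profiles: list[np.ndarray] = []
    params: list[StrainParams] = []
    geometry = DEFAULT_GEOMETRY
    for i in range(n_strains):
        for _attempt in range(200):
            base = rng.uniform(0.06, 0.16)
            amp = rng.uniform(0.22, 0.38)
            peak = dark[0] + (len(dark) - 1) * (i % n_strains) / max(n_strains - 1, 1) \
                + rng.uniform(-0.5, 0.5)
            width = rng.uniform(1.0, 2.5)
            prof = np.full(11, base) + rng.uniform(-0.02, 0.02, 11)
            prof[dark] += amp * np.exp(-((dark - peak) ** 2) / (2 * width**2)) + 0.08
            prof = np.clip(prof, 0.05, 0.50)
            if all(np.linalg.norm(prof - q) > 0.05 for q in profiles):
                break
        else:
            raise RuntimeError("could not place a sufficiently distinct profile")
        profiles.append(prof)
        durations = np.where(
            np.isin(np.arange(11), dark),
            rng.uniform(28.0, 42.0),
            rng.uniform(9.0, 16.0),
        )
        nest = geometry.niche_cell if i % 4 != 3 else geometry.niche_cell - 1
        params.append(
            StrainParams(
                strain_id=f"S{i:02d}",
                asp_profile=prof,
                mean_as_duration_min=durations,
                feed_onset_decay=float(rng.uniform(0.3, 0.8)),
                drink_offset_width_s=60.0,
                feed_rate_g_per_min=float(rng.uniform(0.03, 0.07)),
                drink_rate_g_per_min=float(rng.uniform(0.02, 0.06)),
                speed_cm_per_s=float(2.0 + 4.0 * i / max(n_strains - 1, 1)),
                nest_cell=nest,
            )
        )
    # feasibility at the default separation floor
    probe = SimulationConfig(strains=params)
    for p in params:
        for b in range(11):
            _required_is_mean_s(
                float(p.asp_profile[b]),
                float(p.mean_as_duration_min[b]) * 60.0,
                probe.min_is_duration_min * 60.0,
            )
    return params


def uniform_ingestion_variant(params: StrainParams) -> StrainParams:
    """A copy with no onset/offset ingestion structure (flat probabilities).

    Feeding probability is constant through the AS and drinking has no
    offset bump, so intensities are constant by construction; used to
    test that structure detectors report nothing on structureless data.
    """
    return replace(
        params,
        feed_onset_decay=0.0,
        drink_p_offset=0.0,
        feed_p0=min(params.feed_p0, 0.25),
    )
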