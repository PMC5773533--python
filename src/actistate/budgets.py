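"""Behavioral time budgets and their dark/light Kullback-Leibler divergence.

A *Total* time budget allocates all observed time in a period among the
categories IS, feeding, drinking, locomotion, and other (the remainder of
Active State time, covering behaviors the platform cannot resolve, such as
grooming and rearing).  An *AS* budget excludes Inactive State time and
normalises within Active State time only.

Periods: the full 24 h record ('24h'), the dark cycle ZT12-24 ('DC'), or
the light cycle ZT0-12 ('LC'; 10 h of it fall inside the 22 h window
because maintenance removes ZT6-8).  Proportions, not durations, are
compared between periods.

Categories are made disjoint by priority feeding > drinking > locomotion:
drinking time excludes any overlap with feeding, and locomotion time
excludes overlap with either ingestion category, so every budget is a
probability vector.  Locomotion is operationalised as movement *episodes*:
maximal runs of movement events with inter-event gaps at most
``locomotion_gap_s`` (default 1 s), intersected with AS time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    Interval,
    MouseDayRecord,
    as_interval_array,
    intersect_sets,
    interval_set_length,
    union_intervals,
    zt,
)
from .states import StatePartition

TOTAL_CATEGORIES = ("IS", "feed", "drink", "locomotion", "other")
AS_CATEGORIES = ("feed", "drink", "locomotion", "other")
PERIODS = ("24h", "DC", "LC")
DEFAULT_LOCOMOTION_GAP_S = 1.0


def period_intervals(window: Interval, period: str) -> np.ndarray:
    """The portion of the observation window belonging to a light period."""
    if period == "24h":
        return as_interval_array([window])
    if period == "DC":
        segs = [(zt(12), zt(24))]
    elif period == "LC":
        segs = [(zt(0), zt(12)), (zt(24), zt(36))]
    else:
        raise ValueError(f"unknown period {period!r}")
    clipped = [
        (max(lo, window.start), min(hi, window.end)) for lo, hi in segs
    ]
    return as_interval_array([(lo, hi) for lo, hi in clipped if lo < hi])


@dataclass
class TimeBudget:
    """Normalized allocation of time among behavior categories."""

    scope: str  # 'total' | 'as'
    period: str  # '24h' | 'DC' | 'LC'
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        expected = TOTAL_CATEGORIES if self.scope == "total" else AS_CATEGORIES
        if self.scope not in ("total", "as"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if tuple(self.proportions) != expected:
            raise ValueError(f"budget categories must be {expected}")
        vals = np.array(list(self.proportions.values()))
        if np.any(vals < -1e-12):
            raise ValueError("budget proportions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("budget proportions must sum to 1")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.proportions)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.proportions.values()), dtype=float)


def movement_episodes(rec: MouseDayRecord, gap_s: float = DEFAULT_LOCOMOTION_GAP_S) -> np.ndarray:
    """Maximal runs of movement events with inter-event gaps <= gap_s.

    Episodes are intervals [first event, last event]; a lone event yields
    a zero-length episode contributing no time.
    """
    t, _, _ = rec.movement_arrays()
    if len(t) == 0:
        return np.empty((0, 2))
    cut = np.flatnonzero(np.diff(t) > gap_s) + 1
    starts = t[np.concatenate([[0], cut])]
    ends = t[np.concatenate([cut - 1, [len(t) - 1]])]
    return np.column_stack([starts, ends])


def category_seconds(
    rec: MouseDayRecord,
    partition: StatePartition,
    period: str,
    locomotion_gap_s: float = DEFAULT_LOCOMOTION_GAP_S,
) -> dict[str, float]:
    """Raw seconds per category within the period (pre-normalisation).

    Keys: the total-scope categories plus 'period_total' and 'as_total'.
    """
    per = period_intervals(rec.window, period)
    period_total = interval_set_length(per)
    pos_active = partition.active[partition.active[:, 1] > partition.active[:, 0]]
    as_per = intersect_sets(pos_active, per)
    as_total = interval_set_length(as_per)

    feed = intersect_sets(union_intervals(rec.ingestion_arrays("feed")), as_per)
    drink = intersect_sets(union_intervals(rec.ingestion_arrays("drink")), as_per)
    feed_s = interval_set_length(feed)
    # disjointness: drinking excludes feeding overlap, locomotion excludes both
    drink_s = interval_set_length(drink) - interval_set_length(intersect_sets(drink, feed))
    loco = intersect_sets(movement_episodes(rec, locomotion_gap_s), as_per)
    ing = union_intervals(np.concatenate([feed, drink]) if len(feed) or len(drink)
                          else np.empty((0, 2)))
    loco_s = interval_set_length(loco) - interval_set_length(intersect_sets(loco, ing))
    other_s = max(0.0, as_total - feed_s - drink_s - loco_s)
    return {
        "IS": period_total - as_total,
        "feed": feed_s,
        "drink": drink_s,
        "locomotion": loco_s,
        "other": other_s,
        "period_total": period_total,
        "as_total": as_total,
    }


def budget_from_seconds(seconds: Mapping[str, float], scope: str, period: str) -> TimeBudget:
    if scope == "total":
        denom = seconds["period_total"]
        cats = TOTAL_CATEGORIES
    else:
        denom = seconds["as_total"]
        cats = AS_CATEGORIES
    if denom <= 0:
        raise ValueError(f"no {'observed' if scope == 'total' else 'AS'} time in period {period!r}")
    return TimeBudget(scope, period, {c: seconds[c] / denom for c in cats})


def compute_time_budget(
    rec: MouseDayRecord,
    partition: StatePartition,
    scope: str,
    period: str,
    locomotion_gap_s: float = DEFAULT_LOCOMOTION_GAP_S,
) -> TimeBudget:
    """Total or AS time budget of one mouse-day for one light period."""
    if scope not in ("total", "as"):
        raise ValueError(f"unknown scope {scope!r}")
    sec = category_seconds(rec, partition, period, locomotion_gap_s)
    return budget_from_seconds(sec, scope, period)


def kl_divergence(p: TimeBudget, q: TimeBudget, eps: float = 1e-6) -> float:
    """D(P || Q) in nats with epsilon-smoothing of empty categories.

    Both budgets must share scope and category set.  A pseudocount of
    ``eps`` is added to every category and the vectors renormalised, so
    the divergence is finite, nonnegative, and zero iff P = Q.
    """
    if p.scope != q.scope or p.categories != q.categories:
        raise ValueError("budgets must share scope and categories")
    pa = p.as_array() + eps
    qa = q.as_array() + eps
    pa /= pa.sum()
    qa /= qa.sum()
    return float(np.sum(pa * np.log(pa / qa)))


def dc_lc_divergence_bootstrap(
    records_partitions: list[tuple[MouseDayRecord, StatePartition]],
    scope: str,
    trials: int = 20,
    seed: int = 0,
    locomotion_gap_s: float = DEFAULT_LOCOMOTION_GAP_S,
) -> pd.DataFrame:
    """Per-strain bootstrap of the KL divergence D(DC || LC).

    Each trial pools category seconds over a random half of each mouse's
    days, builds strain-level DC and LC budgets of the requested scope,
    and evaluates their divergence.  Returns a DataFrame indexed by strain
    with columns ``mean`` and ``sd`` over trials.
    """
    per_md = []
    for rec, part in records_partitions:
        per_md.append(
            (
                rec.strain_id,
                rec.mouse_id,
                category_seconds(rec, part, "DC", locomotion_gap_s),
                category_seconds(rec, part, "LC", locomotion_gap_s),
            )
        )
    by_mouse: dict[str, list[int]] = {}
    strain_of: dict[str, str] = {}
    for i, (st, m, _, _) in enumerate(per_md):
        by_mouse.setdefault(m, []).append(i)
        strain_of[m] = st
    for m, idxs in by_mouse.items():
        if len(idxs) < 2:
            raise ValueError(f"mouse {m!r} has fewer than 2 days")
    strains = sorted({st for st, *_ in per_md})
    rng = np.random.default_rng(seed)
    keys = ["IS", "feed", "drink", "locomotion", "other", "period_total", "as_total"]
    out = {st: [] for st in strains}
    for _ in range(trials):
        pooled = {st: {"DC": dict.fromkeys(keys, 0.0), "LC": dict.fromkeys(keys, 0.0)}
                  for st in strains}
        for m, idxs in by_mouse.items():
            k = max(1, len(idxs) // 2)
            take = rng.choice(len(idxs), size=k, replace=False)
            st = strain_of[m]
            for j in take:
                _, _, dc, lc = per_md[idxs[j]]
                for key in keys:
                    pooled[st]["DC"][key] += dc[key]
                    pooled[st]["LC"][key] += lc[key]
        for st in strains:
            p = budget_from_seconds(pooled[st]["DC"], scope, "DC")
            q = budget_from_seconds(pooled[st]["LC"], scope, "LC")
            out[st].append(kl_divergence(p, q))
    return pd.DataFrame(
        {
            "mean": [float(np.mean(out[st])) for st in strains],
            "sd": [float(np.std(out[st], ddof=0)) for st in strains],
        },
        index=pd.Index(strains, name="strain"),
    )
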