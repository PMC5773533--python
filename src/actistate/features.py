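"""Per-bin circadian behavioral features and daily-pattern correlations.

Nine feature classes are computed for each mouse-day over the 11 two-hour
bins of the observation window:

====== =====================================================================
F      food consumed per bin (g), event amounts prorated by time overlap
W      water consumed per bin (g)
D      distance traveled per bin (cm), summed over movement steps
ASP    Active State probability: fraction of bin time spent in ASs
ASN    number of ASs whose onset falls in the bin
ASD    mean full duration (min) of the ASs counted by ASN (0 if none)
ASI_F  feeding intensity: g consumed per minute of AS time in the bin
ASI_W  drinking intensity: g per AS-minute
ASI_D  movement intensity: cm per AS-minute
====== =====================================================================

Per-event ingestion amounts are not measured by the hardware; they are
assigned by proportional allocation: an event's amount is its share of the
day's total ingestion time of that kind multiplied by the daily total.

An AS spanning a bin boundary is counted once (in its onset bin) for
ASN/ASD but contributes time to every bin it overlaps for ASP and the
intensities; this keeps ASN a count and ASP a true fraction.  Distance
steps are assigned to the bin containing the later event of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    MouseDayRecord,
    ZtBinScheme,
    as_interval_array,
    overlap_with_set,
    zt_bin_partition,
)
from .states import StatePartition

FEATURE_CLASSES = ("F", "W", "D", "ASP", "ASN", "ASD", "ASI_F", "ASI_W", "ASI_D")


@dataclass
class EventAmounts:
    """Grams assigned to each ingestion event of a record (record order)."""

    amounts: np.ndarray

    def __post_init__(self) -> None:
        self.amounts = np.asarray(self.amounts, dtype=float)
        if np.any(self.amounts < 0):
            raise ValueError("event amounts must be nonnegative")


def assign_event_amounts(rec: MouseDayRecord) -> EventAmounts:
    """Allocate daily food/water totals to events by time proportion.

    amount_e = (duration_e / total duration of same-kind events) x daily
    total of that kind.  A kind with no events contributes nothing; events
    with zero total duration are an error (the allocation is undefined).
    """
    durs = np.array([e.interval.duration for e in rec.ingestion], dtype=float)
    kinds = np.array([e.kind for e in rec.ingestion])
    amounts = np.zeros(len(durs), dtype=float)
    for kind, total in (("feed", rec.food_total_g), ("drink", rec.water_total_g)):
        mask = kinds == kind
        if mask.any():
            tot_dur = durs[mask].sum()
            if tot_dur <= 0:
                raise ValueError(f"{kind} events present but total duration is zero")
            amounts[mask] = durs[mask] / tot_dur * total
    return EventAmounts(amounts)


@dataclass
class DayFeatures:
    """The nine 11-dimensional feature vectors of one mouse-day."""

    mouse_id: str
    strain_id: str
    day_index: int
    bins: ZtBinScheme
    F: np.ndarray
    W: np.ndarray
    D: np.ndarray
    ASP: np.ndarray
    ASN: np.ndarray
    ASD: np.ndarray
    ASI_F: np.ndarray
    ASI_W: np.ndarray
    ASI_D: np.ndarray

    def vector(self, feature: str) -> np.ndarray:
        if feature not in FEATURE_CLASSES:
            raise KeyError(feature)
        return getattr(self, feature)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat in FEATURE_CLASSES:
            vec = self.vector(feat)
            for b, v in enumerate(vec):
                rows.append((self.mouse_id, self.strain_id, self.day_index, feat, b, v))
        return pd.DataFrame(
            rows, columns=["mouse_id", "strain", "day", "feature", "bin", "value"]
        )


def compute_day_features(
    rec: MouseDayRecord,
    partition: StatePartition,
    amounts: EventAmounts,
    bins: Optional[ZtBinScheme] = None,
) -> DayFeatures:
    if bins is None:
        bins = zt_bin_partition(rec.window)
    if partition.window != rec.window:
        raise ValueError("record and partition windows differ")
    n_bins = len(bins)
    bin_arr = as_interval_array(bins.bins)

    ing_ivs = rec.ingestion_arrays()
    ing_kinds = np.array([e.kind for e in rec.ingestion])
    amt = amounts.amounts
    if len(amt) != len(ing_ivs):
        raise ValueError("amounts not aligned with the record's ingestion events")
    ing_dur = ing_ivs[:, 1] - ing_ivs[:, 0] if len(ing_ivs) else np.empty(0)

    t, x, y = rec.movement_arrays()
    if len(t) > 1:
        step = np.hypot(np.diff(x), np.diff(y))
        step_t = t[1:]  # step assigned to the bin of the later event
        step_bin = bins.index_of_array(step_t)
    else:
        step = np.empty(0)
        step_t = np.empty(0)
        step_bin = np.empty(0, dtype=int)

    active = partition.active
    pos_active = active[active[:, 1] > active[:, 0]] if len(active) else active
    onsets = active[:, 0] if len(active) else np.empty(0)
    as_dur_min = (active[:, 1] - active[:, 0]) / 60.0 if len(active) else np.empty(0)
    onset_bin = bins.index_of_array(onsets) if len(onsets) else np.empty(0, dtype=int)

    F = np.zeros(n_bins)
    W = np.zeros(n_bins)
    D = np.zeros(n_bins)
    ASP = np.zeros(n_bins)
    ASN = np.zeros(n_bins)
    ASD = np.zeros(n_bins)
    ASI_F = np.zeros(n_bins)
    ASI_W = np.zeros(n_bins)
    ASI_D = np.zeros(n_bins)

    if len(step):
        np.add.at(D, step_bin, step)
    if len(onsets):
        np.add.at(ASN, onset_bin, 1.0)
        sums = np.zeros(n_bins)
        np.add.at(sums, onset_bin, as_dur_min)
        nz = ASN > 0
        ASD[nz] = sums[nz] / ASN[nz]

    # distance restricted to AS time, per bin (step counted if its later
    # event timestamp lies inside an AS)
    if len(step) and len(pos_active):
        flat = pos_active.ravel()
        in_as = np.searchsorted(flat, step_t, side="right") % 2 == 1
    else:
        in_as = np.zeros(len(step), dtype=bool)

    for b in range(n_bins):
        lo, hi = bin_arr[b]
        if len(ing_ivs):
            ov_bin = np.clip(np.minimum(ing_ivs[:, 1], hi) - np.maximum(ing_ivs[:, 0], lo), 0, None)
            frac = np.divide(ov_bin, ing_dur, out=np.zeros_like(ov_bin), where=ing_dur > 0)
            F[b] = np.sum(amt[ing_kinds == "feed"] * frac[ing_kinds == "feed"])
            W[b] = np.sum(amt[ing_kinds == "drink"] * frac[ing_kinds == "drink"])
        as_in_bin_s = float(overlap_with_set(pos_active, np.array([lo]), np.array([hi]))[0]) \
            if len(pos_active) else 0.0
        ASP[b] = as_in_bin_s / (hi - lo)
        as_min = as_in_bin_s / 60.0
        if as_min > 0:
            if len(ing_ivs):
                # amount prorated into the part of the event inside AS & bin
                clipped_lo = np.maximum(ing_ivs[:, 0], lo)
                clipped_hi = np.minimum(ing_ivs[:, 1], hi)
                ov_as = np.where(
                    clipped_lo < clipped_hi,
                    overlap_with_set(pos_active, clipped_lo, np.maximum(clipped_hi, clipped_lo)),
                    0.0,
                )
                frac_as = np.divide(ov_as, ing_dur, out=np.zeros_like(ov_as), where=ing_dur > 0)
                ASI_F[b] = np.sum(amt[ing_kinds == "feed"] * frac_as[ing_kinds == "feed"]) / as_min
                ASI_W[b] = np.sum(amt[ing_kinds == "drink"] * frac_as[ing_kinds == "drink"]) / as_min
            if len(step):
                sel = in_as & (step_bin == b)
                ASI_D[b] = step[sel].sum() / as_min
    return DayFeatures(
        rec.mouse_id, rec.strain_id, rec.day_index, bins,
        F=F, W=W, D=D, ASP=ASP, ASN=ASN, ASD=ASD,
        ASI_F=ASI_F, ASI_W=ASI_W, ASI_D=ASI_D,
    )


def cohort_features(
    day_features: Iterable[DayFeatures],
) -> pd.DataFrame:
    """Stack per-day features into a tidy long table.

    Columns: mouse_id, strain, day, feature, bin, value.
    """
    frames = [df.to_frame() for df in day_features]
    if not frames:
        return pd.DataFrame(columns=["mouse_id", "strain", "day", "feature", "bin", "value"])
    return pd.concat(frames, ignore_index=True)


def feature_matrix(
    table: pd.DataFrame, features: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-MD design matrix (rows = mouse-days, columns = features x bins).

    Returns ``(X, strain_labels, mouse_ids)`` with MD rows ordered by
    (strain, mouse, day).  Concatenating all nine classes yields the 99-D
    representation used for whole-repertoire classification.
    """
    sub = table[table["feature"].isin(features)]
    wide = sub.pivot_table(
        index=["strain", "mouse_id", "day"], columns=["feature", "bin"], values="value",
        sort=True,
    )
    cols = [(f, b) for f in features for b in sorted(sub["bin"].unique())]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    if wide.isna().any().any():
        raise ValueError("feature table is not complete over (MD, feature, bin)")
    idx = wide.index.to_frame(index=False)
    return wide.to_numpy(float), idx["strain"].to_numpy(), idx["mouse_id"].to_numpy()


def mean_pattern_vectors(table: pd.DataFrame, feature: str, level: str) -> pd.DataFrame:
    """Mean 11-D daily-pattern vector per mouse or per strain (wide form)."""
    sub = table[table["feature"] == feature]
    if level == "mouse":
        keys = ["strain", "mouse_id"]
    elif level == "strain":
        keys = ["strain"]
    else:
        raise ValueError("level must be 'mouse' or 'strain'")
    return sub.pivot_table(index=keys, columns="bin", values="value", aggfunc="mean")


def pattern_correlations(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    level: str = "strain",
) -> pd.DataFrame:
    """Pearson and Spearman correlations between feature daily patterns.

    For each requested pair of feature classes the mean 11-D pattern
    vectors (per mouse or per strain) are stacked and correlated across
    all (unit, bin) cells.  A constant vector makes the correlation
    undefined; such pairs are returned flagged ``valid=False`` rather than
    propagating NaN.
    """
    rows = []
    for fa, fb in pairs:
        va = mean_pattern_vectors(table, fa, level)
        vb = mean_pattern_vectors(table, fb, level)
        if va.shape[1] < 3:
            raise ValueError("need at least 3 bins of data")
        a = va.to_numpy(float).ravel()
        b = vb.loc[va.index].to_numpy(float).ravel()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rows.append((fa, fb, np.nan, np.nan, np.nan, np.nan, False))
            continue
        pr = stats.pearsonr(a, b)
        sr = stats.spearmanr(a, b)
        rows.append((fa, fb, pr.statistic, pr.pvalue, sr.statistic, sr.pvalue, True))
    return pd.DataFrame(
        rows,
        columns=["feature_a", "feature_b", "pearson_r", "pearson_p",
                 "spearman_rho", "spearman_p", "valid"],
    )
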