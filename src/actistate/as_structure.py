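"""Within-Active-State temporal structure of feeding and drinking.

For every Active State the 15 min window following its onset (or
preceding its offset) is divided into 180 five-second bins; a bin scores
1 if an event of the behavior of interest overlaps it.  Mouse-day
profiles are the mean of these 180-bit strings over the day's ASs;
mouse-level profiles average a mouse's day profiles.

Only events belonging to the aligned AS are scored (the window is masked
to the AS), so an AS shorter than 15 min has its out-of-state bins fixed
at 0 and events of a neighboring AS are never attributed twice.

The null model replaces AS onsets/offsets with randomly chosen movement
events (as many as the animal's average daily AS count) and scores the
same windows without AS masking; peak probabilities, real versus null,
are compared across mice with Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .core_model import MouseDayRecord
from .states import StatePartition

N_PROFILE_BINS = 180
PROFILE_BIN_S = 5.0
PROFILE_WINDOW_S = N_PROFILE_BINS * PROFILE_BIN_S  # 15 min


@dataclass
class EventProbabilityProfile:
    """Per-bin event probability aligned to AS onset or offset."""

    alignment: str  # 'onset' | 'offset'
    behavior: str  # 'feed' | 'drink'
    values: np.ndarray
    level: str = "md"  # 'md' | 'mouse' | 'strain'

    def __post_init__(self) -> None:
        if self.alignment not in ("onset", "offset"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if self.behavior not in ("feed", "drink"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PROFILE_BINS,):
            raise ValueError(f"profile must have exactly {N_PROFILE_BINS} bins")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("profile values must lie in [0, 1]")

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def peak_bin(self) -> int:
        return int(self.values.argmax())


def _score_window(
    events: np.ndarray, anchor: float, alignment: str, mask: Optional[tuple[float, float]]
) -> np.ndarray:
    """Binary 180-bin string for one aligned window.

    ``events`` is an (n, 2) interval array; ``mask`` restricts scoring to
    [mask0, mask1) (the aligned AS) when given.
    """
    if alignment == "onset":
        w0 = anchor
    else:
        w0 = anchor - PROFILE_WINDOW_S
    bits = np.zeros(N_PROFILE_BINS)
    if len(events) == 0:
        return bits
    lo = np.asarray(events[:, 0], dtype=float)
    hi = np.asarray(events[:, 1], dtype=float)
    if mask is not None:
        lo = np.maximum(lo, mask[0])
        hi = np.minimum(hi, mask[1])
    keep = lo < hi
    lo, hi = lo[keep], hi[keep]
    # bins overlapped by [lo, hi): half-open on both sides
    b0 = np.floor((lo - w0) / PROFILE_BIN_S).astype(int)
    b1 = np.ceil((hi - w0) / PROFILE_BIN_S).astype(int)  # exclusive
    for a, b in zip(b0, b1):
        a = max(a, 0)
        b = min(b, N_PROFILE_BINS)
        if a < b:
            bits[a:b] = 1.0
    return bits


def as_aligned_profile(
    rec: MouseDayRecord,
    partition: StatePartition,
    alignment: str,
    behavior: str,
) -> EventProbabilityProfile:
    """Mouse-day profile: mean 180-bit string over the day's ASs."""
    if partition.n_active == 0:
        raise ValueError(f"record {rec.key} has no Active States")
    events = rec.ingestion_arrays(behavior)
    acc = np.zeros(N_PROFILE_BINS)
    for s, e in partition.active:
        anchor = s if alignment == "onset" else e
        acc += _score_window(events, anchor, alignment, mask=(s, e))
    return EventProbabilityProfile(alignment, behavior, acc / partition.n_active, level="md")


def null_model_profile(
    rec: MouseDayRecord,
    alignment: str,
    behavior: str,
    k: int,
    seed: int = 0,
) -> EventProbabilityProfile:
    """Null profile anchored at ``k`` randomly chosen movement events.

    ``k`` should be the round of the animal's mean daily AS count.  The
    windows are scored exactly as for real alignments but without AS
    masking (the null has no states).
    """
    t, _, _ = rec.movement_arrays()
    if k < 1:
        raise ValueError("k must be at least 1")
    if len(t) < k:
        raise ValueError(f"record {rec.key} has fewer movement events than k={k}")
    rng = np.random.default_rng(seed)
    anchors = rng.choice(t, size=k, replace=False)
    events = rec.ingestion_arrays(behavior)
    acc = np.zeros(N_PROFILE_BINS)
    for anchor in anchors:
        acc += _score_window(events, float(anchor), alignment, mask=None)
    return EventProbabilityProfile(alignment, behavior, acc / k, level="md")


def mouse_profiles(
    records_partitions: list[tuple[MouseDayRecord, StatePartition]],
    alignment: str,
    behavior: str,
    null: bool = False,
    seed: int = 0,
) -> dict[str, EventProbabilityProfile]:
    """Mouse-level profiles: average of each mouse's day profiles.

    With ``null=True`` the anchors are random movement events, with the
    per-day count fixed at the round of the mouse's mean daily AS count
    (minimum 1).
    """
    by_mouse: dict[str, list[tuple[MouseDayRecord, StatePartition]]] = {}
    for rec, part in records_partitions:
        by_mouse.setdefault(rec.mouse_id, []).append((rec, part))
    out: dict[str, EventProbabilityProfile] = {}
    rng = np.random.default_rng(seed)
    for mouse, items in sorted(by_mouse.items()):
        day_profiles = []
        k = max(1, int(round(float(np.mean([p.n_active for _, p in items])))))
        for rec, part in items:
            if null:
                day_profiles.append(
                    null_model_profile(
                        rec, alignment, behavior, k=k,
                        seed=int(rng.integers(2**31 - 1)),
                    ).values
                )
            elif part.n_active > 0:
                day_profiles.append(as_aligned_profile(rec, part, alignment, behavior).values)
        if not day_profiles:
            continue
        out[mouse] = EventProbabilityProfile(
            alignment, behavior, np.mean(day_profiles, axis=0), level="mouse"
        )
    return out


@dataclass
class PeakTest:
    t: float
    df: float
    p: float


def peak_significance(real_peaks: np.ndarray, null_peaks: np.ndarray) -> PeakTest:
    """Welch's unequal-variance t-test on per-mouse peak probabilities.

    By convention two groups with zero variance and equal means give
    t = 0, p = 1 (no evidence of structure) instead of NaN.
    """
    a = np.asarray(real_peaks, dtype=float)
    b = np.asarray(null_peaks, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 mice per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return PeakTest(0.0, float(len(a) + len(b) - 2), 1.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(getattr(res, "df", _welch_df(a, b)))
    return PeakTest(float(res.statistic), df, float(res.pvalue))


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
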