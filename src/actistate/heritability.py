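"""Broad-sense heritability from balanced one-way ANOVA variance components.

For a balanced design of ``s`` strains with ``n`` mice each (``N = s*n``),
with per-mouse feature means mu_ij, strain means mu_i and grand mean mu:

    MS_between = n / (s - 1) * sum_i (mu - mu_i)^2
    MS_within  = 1 / (N - s) * sum_ij (mu_ij - mu_i)^2
    V_g = (MS_between - MS_within) / n      (clipped at 0)
    V_e = MS_within
    H^2 = V_g / (V_g + V_e)                 (0 when both components are 0)

H^2 is the intraclass correlation: the fraction of total feature variance
attributable to strain.  Robustness is assessed by bootstrapping: each
trial recomputes per-mouse means from a random half of that mouse's days,
draws a balanced subsample of ``n_per_strain`` mice per strain, and
re-evaluates H^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HeritabilityResult:
    ms_between: float
    ms_within: float
    v_g: float
    v_e: float
    h2: float


def broad_sense_heritability(values: np.ndarray) -> HeritabilityResult:
    """Evaluate H^2 on a balanced (s strains x n mice) matrix.

    The formula assumes balance; unbalanced input is an error.  A negative
    between-strain component estimate is clipped to zero, so H^2 is always
    in [0, 1].
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D (strains x mice) matrix")
    s, n = m.shape
    if s < 2 or n < 2:
        raise ValueError("need at least 2 strains and 2 mice per strain")
    if np.any(~np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries (unbalanced design?)")
    N = s * n
    strain_means = m.mean(axis=1)
    grand = m.mean()
    ms_between = n / (s - 1) * np.sum((grand - strain_means) ** 2)
    ms_within = np.sum((m - strain_means[:, None]) ** 2) / (N - s)
    v_g = max(0.0, (ms_between - ms_within) / n)
    v_e = ms_within
    denom = v_g + v_e
    h2 = v_g / denom if denom > 0 else 0.0
    return HeritabilityResult(float(ms_between), float(ms_within), float(v_g), float(v_e), float(h2))


def _per_mouse_bin_values(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Wide (mouse-day) x bin values of one feature class, with strain index."""
    sub = table[table["feature"] == feature]
    if sub.empty:
        raise ValueError(f"feature {feature!r} absent from the table")
    return sub.pivot_table(
        index=["strain", "mouse_id", "day"], columns="bin", values="value"
    )


def bootstrap_heritability(
    table: pd.DataFrame,
    feature: str,
    trials: int = 20,
    n_per_strain: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap mean/sd of H^2 per bin plus the daily average.

    Per trial: sample half of each mouse's days (floor, minimum 1) without
    replacement, average per mouse, draw ``n_per_strain`` mice per strain
    (strains with more mice are randomly subsampled; fewer is an error),
    and evaluate the balanced-design H^2 for each of the 11 bins and for
    the across-bin daily average.

    Returns a DataFrame indexed by bin (0..10 and 'daily') with columns
    ``mean`` and ``sd``.
    """
    wide = _per_mouse_bin_values(table, feature)
    rng = np.random.default_rng(seed)
    idx = wide.index.to_frame(index=False)
    strains = sorted(idx["strain"].unique())
    mice_by_strain = {
        st: sorted(idx.loc[idx["strain"] == st, "mouse_id"].unique()) for st in strains
    }
    for st, mice in mice_by_strain.items():
        if len(mice) < n_per_strain:
            raise ValueError(f"strain {st!r} has {len(mice)} mice < n_per_strain={n_per_strain}")
    days_by_mouse = {
        m: wide.xs(m, level="mouse_id", drop_level=False) for m in idx["mouse_id"].unique()
    }
    for m, d in days_by_mouse.items():
        if len(d) < 2:
            raise ValueError(f"mouse {m!r} has fewer than 2 days")

    bin_cols = list(wide.columns)
    results = np.empty((trials, len(bin_cols) + 1))
    for trial in range(trials):
        # per-mouse means from a random half of days
        mouse_means: dict[str, np.ndarray] = {}
        for m, d in days_by_mouse.items():
            k = max(1, len(d) // 2)
            take = rng.choice(len(d), size=k, replace=False)
            mouse_means[m] = d.iloc[take].to_numpy(float).mean(axis=0)
        chosen = {
            st: rng.choice(mice, size=n_per_strain, replace=False)
            for st, mice in mice_by_strain.items()
        }
        mats = np.stack(
            [np.stack([mouse_means[m] for m in chosen[st]]) for st in strains]
        )  # (s, n, bins)
        for b_i in range(len(bin_cols)):
            results[trial, b_i] = broad_sense_heritability(mats[:, :, b_i]).h2
        results[trial, -1] = broad_sense_heritability(mats.mean(axis=2)).h2
    index = [str(b) for b in bin_cols] + ["daily"]
    return pd.DataFrame(
        {"mean": results.mean(axis=0), "sd": results.std(axis=0, ddof=0)}, index=index
    )
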