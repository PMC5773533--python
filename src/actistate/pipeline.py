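"""End-to-end orchestration: cohort in, full analysis report out.

The stages run in dependency order — spatial (Home Base) -> state
designation -> per-bin features -> {heritability, time budgets, within-AS
structure, discrimination} — with all randomness drawn from named
substreams of one root seed, so a fixed configuration yields an
identical report.  Intermediate tables are written as CSV alongside the
report for stage-by-stage inspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .as_structure import mouse_profiles, peak_significance
from .budgets import dc_lc_divergence_bootstrap
from .core_model import CohortDataset, read_cohort
from .discrimination import (
    all_pairwise_scores,
    overlap_matrix,
    pca_projection,
    strain_classifier,
    strain_ellipsoids,
)
from .features import (
    FEATURE_CLASSES,
    assign_event_amounts,
    cohort_features,
    compute_day_features,
    feature_matrix,
    mean_pattern_vectors,
)
from .heritability import bootstrap_heritability
from .spatial import designate_home_base
from .states import DEFAULT_IST_S, designate_states

log = logging.getLogger("actistate")


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and offending MD."""


def _substream(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    cohort_dir: str
    out_dir: Optional[str] = None
    ist_s: float = DEFAULT_IST_S
    locomotion_gap_s: float = 1.0
    trials: int = 20
    seed: int = 0
    train_fraction: float = 0.5
    heritability_features: tuple[str, ...] = ("ASP", "D")
    run_pairwise: bool = False
    run_bootstrap: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("heritability_features",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256((payload + __version__).encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-stage outputs plus provenance."""

    config_hash: str
    version: str
    home_bases: pd.DataFrame
    states: pd.DataFrame
    features: pd.DataFrame
    heritability: dict[str, pd.DataFrame]
    budget_divergence: dict[str, pd.DataFrame]
    profile_peaks: pd.DataFrame
    classifier: dict[str, float]
    pairwise: Optional[pd.DataFrame]
    ellipsoids: pd.DataFrame
    overlaps: Optional[pd.DataFrame]

    def report_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.config_hash.encode())
        for df in (self.home_bases, self.states, self.features, self.profile_peaks):
            h.update(df.round(9).to_csv().encode())
        h.update(json.dumps(self.classifier, sort_keys=True).encode())
        return h.hexdigest()[:16]


def run_full_analysis(
    cfg: AnalysisConfig, cohort: Optional[CohortDataset] = None
) -> AnalysisReport:
    """Execute every analysis stage on a cohort.

    ``cohort`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``cfg.cohort_dir``.  Any stage failure is
    re-raised as :class:`StageError` naming the stage and mouse-day.
    """
    if cohort is None:
        cohort = read_cohort(cfg.cohort_dir)
    log.info("cohort: %d records, %d strains", len(cohort), len(cohort.strains))

    hb_rows, state_rows, day_feats, parts = [], [], [], []
    for rec in cohort:
        try:
            hb = designate_home_base(rec)
            part = designate_states(rec, hb, ist_s=cfg.ist_s)
            amounts = assign_event_amounts(rec)
            feats = compute_day_features(rec, part, amounts)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"per-day stage failed on MD {rec.key}: {exc}") from exc
        hb_rows.append(
            (rec.mouse_id, rec.day_index, ";".join(map(str, hb.cells)), hb.basis)
        )
        for s, e in part.active:
            state_rows.append((rec.mouse_id, rec.day_index, "AS", s, e))
        for s, e in part.inactive:
            state_rows.append((rec.mouse_id, rec.day_index, "IS", s, e))
        day_feats.append(feats)
        parts.append((rec, part))

    home_bases = pd.DataFrame(hb_rows, columns=["mouse_id", "day", "cells", "basis"])
    states = pd.DataFrame(state_rows, columns=["mouse_id", "day", "state", "start", "end"])
    table = cohort_features(day_feats)

    n_per_strain = min(len(cohort.mice_of(st)) for st in cohort.strains)
    heritability: dict[str, pd.DataFrame] = {}
    budget_div: dict[str, pd.DataFrame] = {}
    if cfg.run_bootstrap:
        for feat in cfg.heritability_features:
            heritability[feat] = bootstrap_heritability(
                table, feat, trials=cfg.trials, n_per_strain=n_per_strain,
                seed=_substream(cfg.seed, f"heritability:{feat}"),
            )
        for scope in ("total", "as"):
            budget_div[scope] = dc_lc_divergence_bootstrap(
                parts, scope, trials=cfg.trials,
                seed=_substream(cfg.seed, f"budgets:{scope}"),
                locomotion_gap_s=cfg.locomotion_gap_s,
            )

    peak_rows = []
    for alignment, behavior in (("onset", "feed"), ("offset", "drink")):
        real = mouse_profiles(parts, alignment, behavior, null=False)
        null = mouse_profiles(
            parts, alignment, behavior, null=True,
            seed=_substream(cfg.seed, f"null:{alignment}:{behavior}"),
        )
        mice = sorted(set(real) & set(null))
        test = peak_significance(
            np.array([real[m].peak for m in mice]),
            np.array([null[m].peak for m in mice]),
        )
        peak_bin = int(np.round(np.mean([real[m].peak_bin for m in mice])))
        peak_rows.append((alignment, behavior, peak_bin, test.t, test.df, test.p))
    profile_peaks = pd.DataFrame(
        peak_rows, columns=["alignment", "behavior", "mean_peak_bin", "t", "df", "p"]
    )

    X, strain_labels, mouse_ids = feature_matrix(table, list(FEATURE_CLASSES))
    clf = strain_classifier(
        X, strain_labels, mouse_ids,
        train_fraction=cfg.train_fraction, trials=cfg.trials,
        seed=_substream(cfg.seed, "classifier"),
    )
    classifier = {
        "md_mean": clf.md_mean, "md_sd": clf.md_sd,
        "mouse_mean": clf.mouse_mean, "mouse_sd": clf.mouse_sd,
    }

    pairwise = None
    if cfg.run_pairwise and len(cohort.strains) >= 2:
        Xp, sp, mp = feature_matrix(table, ["ASP"])
        pairwise = all_pairwise_scores(
            Xp, sp, mp, trials=cfg.trials, seed=_substream(cfg.seed, "pairwise")
        )

    asp_mouse = mean_pattern_vectors(table, "ASP", level="mouse")
    ellipsoids_df = pd.DataFrame()
    overlaps = None
    if asp_mouse.shape[0] >= 4:
        model = pca_projection(asp_mouse.to_numpy(float))
        labels = asp_mouse.index.get_level_values("strain").to_numpy()
        try:
            ells = strain_ellipsoids(model, labels)
            ellipsoids_df = pd.DataFrame(
                [
                    {"strain": e.label,
                     "cx": e.center[0], "cy": e.center[1], "cz": e.center[2],
                     "ax": e.semi_axes[0], "ay": e.semi_axes[1], "az": e.semi_axes[2]}
                    for e in ells
                ]
            )
            overlaps = overlap_matrix(
                ells, seed=_substream(cfg.seed, "overlap")
            )
        except ValueError as exc:
            log.warning("ellipsoid stage skipped: %s", exc)

    report = AnalysisReport(
        config_hash=cfg.hash(),
        version=__version__,
        home_bases=home_bases,
        states=states,
        features=table,
        heritability=heritability,
        budget_divergence=budget_div,
        profile_peaks=profile_peaks,
        classifier=classifier,
        pairwise=pairwise,
        ellipsoids=ellipsoids_df,
        overlaps=overlaps,
    )
    if cfg.out_dir:
        _write_report(report, cfg.out_dir)
    return report


def _write_report(report: AnalysisReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.home_bases.to_csv(os.path.join(out_dir, "home_bases.csv"), index=False)
    report.states.to_csv(os.path.join(out_dir, "states.csv"), index=False)
    report.features.to_csv(os.path.join(out_dir, "features.csv"), index=False)
    for feat, df in report.heritability.items():
        df.to_csv(os.path.join(out_dir, f"heritability_{feat}.csv"))
    for scope, df in report.budget_divergence.items():
        df.to_csv(os.path.join(out_dir, f"budget_divergence_{scope}.csv"))
    report.profile_peaks.to_csv(os.path.join(out_dir, "profile_peaks.csv"), index=False)
    if report.pairwise is not None:
        report.pairwise.to_csv(os.path.join(out_dir, "pairwise_scores.csv"), index=False)
    if len(report.ellipsoids):
        report.ellipsoids.to_csv(os.path.join(out_dir, "ellipsoids.csv"), index=False)
    if report.overlaps is not None:
        report.overlaps.to_csv(os.path.join(out_dir, "overlaps.csv"))
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(
            {
                "version": report.version,
                "config_hash": report.config_hash,
                "report_hash": report.report_hash(),
                "classifier": report.classifier,
            },
            fh,
            indent=2,
        )
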