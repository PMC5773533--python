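"""Shared fixtures: simulated cohorts at two scales.

The session-scoped ``study`` fixture is a 16-strain cohort at the default
study shape (9 mice x 12 days); building it and its derived tables takes
tens of seconds, so every test that needs cohort-scale data shares it.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import actistate as a


def make_record(movement=(), ingestion=(), window=a.DEFAULT_WINDOW, **kw):
    """Small hand-built mouse-day for arithmetic tests."""
    defaults = dict(
        mouse_id="m0", strain_id="S", day_index=0, food_total_g=0.0, water_total_g=0.0
    )
    defaults.update(kw)
    return a.MouseDayRecord(movement=movement, ingestion=ingestion, window=window, **defaults)


@pytest.fixture(scope="session")
def mini_library():
    return a.default_strain_library(3, seed=1)


@pytest.fixture(scope="session")
def mini_cohort(mini_library):
    cfg = a.SimulationConfig(
        strains=mini_library, mice_per_strain=2, days_per_mouse=2, seed=5
    )
    return a.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mini_parts(mini_cohort):
    cohort, _ = mini_cohort
    out = []
    for rec in cohort:
        hb = a.designate_home_base(rec)
        out.append((rec, hb, a.designate_states(rec, hb)))
    return out


@pytest.fixture(scope="session")
def study():
    """16-strain cohort at study scale with all per-day stages computed."""
    lib = a.default_strain_library(16, seed=7)
    cfg = a.SimulationConfig(strains=lib, seed=11)
    cohort, truths = a.simulate_cohort(cfg)
    parts = []
    feats = []
    for rec in cohort:
        hb = a.designate_home_base(rec)
        part = a.designate_states(rec, hb)
        parts.append((rec, hb, part))
        feats.append(a.compute_day_features(rec, part, a.assign_event_amounts(rec)))
    table = a.cohort_features(feats)
    return SimpleNamespace(
        library=lib, cfg=cfg, cohort=cohort, truths=truths, parts=parts, table=table
    )
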