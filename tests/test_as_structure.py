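"""Onset/offset-aligned event probability profiles and peak tests."""

import numpy as np
import pytest
from scipy import stats

import actistate as a
from actistate.as_structure import (
    N_PROFILE_BINS,
    mouse_profiles,
    null_model_profile,
)
from actistate.core_model import complement_set
from actistate.states import StatePartition
from actistate.synthetic import uniform_ingestion_variant
from conftest import make_record


def partition_with(active, window=a.DEFAULT_WINDOW):
    active = np.asarray(active, dtype=float).reshape(-1, 2)
    return StatePartition(window, active, complement_set(active, window), 1200.0)


class TestAlignedProfiles:
    def test_no_feeding_gives_all_zero_profile(self):
        t0 = a.zt(9)
        part = partition_with([[t0, t0 + 1800.0]])
        prof = a.as_aligned_profile(make_record(), part, "onset", "feed")
        assert prof.values.shape == (N_PROFILE_BINS,)
        assert np.all(prof.values == 0)

    def test_event_bins_half_open(self):
        # feeding [onset+30, onset+40) covers 5 s bins 6 and 7 only
        t0 = a.zt(9)
        part = partition_with([[t0, t0 + 1800.0]])
        rec = make_record(
            ingestion=[a.IngestionEvent("feed", a.Interval(t0 + 30.0, t0 + 40.0))],
            food_total_g=1.0,
        )
        prof = a.as_aligned_profile(rec, part, "onset", "feed")
        assert prof.values[6] == 1.0 and prof.values[7] == 1.0
        assert prof.values.sum() == 2.0

    def test_offset_alignment_final_bin_touches_offset(self):
        t0 = a.zt(9)
        part = partition_with([[t0, t0 + 1800.0]])
        end = t0 + 1800.0
        rec = make_record(
            ingestion=[a.IngestionEvent("drink", a.Interval(end - 5.0, end - 1.0))],
            water_total_g=1.0,
        )
        prof = a.as_aligned_profile(rec, part, "offset", "drink")
        assert prof.values[179] == 1.0
        assert prof.values.sum() == 1.0

    def test_short_as_masks_bins_beyond_extent(self):
        # a 100 s AS: events of the following AS must not leak into its window
        t0 = a.zt(9)
        part = partition_with([[t0, t0 + 100.0], [t0 + 2000.0, t0 + 2600.0]])
        rec = make_record(
            ingestion=[
                a.IngestionEvent("feed", a.Interval(t0 + 30.0, t0 + 40.0)),
                a.IngestionEvent("feed", a.Interval(t0 + 2030.0, t0 + 2040.0)),
            ],
            food_total_g=1.0,
        )
        prof = a.as_aligned_profile(rec, part, "onset", "feed")
        # bin 406 would be out of range; the second AS contributes its own bins
        assert np.all(prof.values[20:] == 0)  # nothing beyond the 100 s extent
        assert prof.values[6] == 1.0  # both ASs feed in bins 6-7 -> mean 1.0

    def test_md_profile_averages_over_states(self):
        t0 = a.zt(9)
        part = partition_with([[t0, t0 + 1800.0], [t0 + 4000.0, t0 + 5800.0]])
        rec = make_record(
            ingestion=[a.IngestionEvent("feed", a.Interval(t0 + 30.0, t0 + 40.0))],
            food_total_g=1.0,
        )
        prof = a.as_aligned_profile(rec, part, "onset", "feed")
        assert prof.values[6] == 0.5  # present in 1 of 2 states

    def test_no_states_is_an_error(self):
        part = partition_with(np.empty((0, 2)))
        with pytest.raises(ValueError):
            a.as_aligned_profile(make_record(), part, "onset", "feed")


class TestNullModel:
    def test_seeded_determinism(self, mini_parts):
        rec = mini_parts[0][0]
        p1 = null_model_profile(rec, "onset", "feed", k=5, seed=3)
        p2 = null_model_profile(rec, "onset", "feed", k=5, seed=3)
        assert np.array_equal(p1.values, p2.values)

    def test_too_few_movement_events_rejected(self):
        rec = make_record(movement=(np.array([a.zt(9)]), np.array([5.0]), np.array([5.0])))
        with pytest.raises(ValueError):
            null_model_profile(rec, "onset", "feed", k=5, seed=0)

    def test_uniform_feeding_triggers_no_detection(self):
        """Without onset structure the peak detector must stay silent.

        The null windows run over whatever follows their movement-event
        anchors (including state tails), so their level is close to but
        not identical with the onset-aligned estimate; the meaningful
        invariant is that structureless feeding never registers as a
        significant onset peak.
        """
        lib = [uniform_ingestion_variant(p) for p in a.default_strain_library(2, seed=8)]
        cfg = a.SimulationConfig(strains=lib[:1], mice_per_strain=5, days_per_mouse=4, seed=13)
        cohort, _ = a.simulate_cohort(cfg)
        parts = []
        for rec in cohort:
            hb = a.designate_home_base(rec)
            parts.append((rec, a.designate_states(rec, hb)))
        real = mouse_profiles(parts, "onset", "feed")
        null = mouse_profiles(parts, "onset", "feed", null=True, seed=4)
        mice = sorted(set(real) & set(null))
        res = a.peak_significance(
            np.array([real[m].peak for m in mice]),
            np.array([null[m].peak for m in mice]),
        )
        assert not (res.t > 0 and res.p < 1e-3)


class TestPeakSignificance:
    def test_identical_constant_groups_by_convention(self):
        res = a.peak_significance(np.full(5, 0.3), np.full(6, 0.3))
        assert res.t == 0.0 and res.p == 1.0

    def test_clear_separation_is_significant(self):
        res = a.peak_significance(
            np.array([11.0, 12.0, 13.0]) + 0.001 * np.arange(3),
            np.array([1.0, 2.0, 3.0]),
        )
        assert res.p < 1e-3

    def test_matches_explicit_welch_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.4, 0.1, 12)
        y = rng.normal(0.2, 0.05, 9)
        res = a.peak_significance(x, y)
        va, vb = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(x) - 1) + vb**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert abs(res.t - t) < 1e-6
        assert abs(res.df - df) < 1e-6
        assert abs(res.p - p) < 1e-6

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            a.peak_significance(np.array([1.0]), np.array([1.0, 2.0]))


class TestStructuredSimulation:
    def test_onset_feeding_and_offset_drinking_peaks(self):
        """Onset-loaded feeding and pre-offset drinking are detected where
        the generator put them, and both beat the movement-anchored null."""
        lib = a.default_strain_library(3, seed=4)
        cfg = a.SimulationConfig(strains=lib, mice_per_strain=4, days_per_mouse=3, seed=10)
        cohort, _ = a.simulate_cohort(cfg)
        parts = []
        for rec in cohort:
            hb = a.designate_home_base(rec)
            parts.append((rec, a.designate_states(rec, hb)))
        for alignment, behavior, lo, hi in (
            ("onset", "feed", 0, 24),     # first 2 min after onset
            ("offset", "drink", 168, 180),  # final minute before offset
        ):
            real = mouse_profiles(parts, alignment, behavior)
            null = mouse_profiles(parts, alignment, behavior, null=True, seed=6)
            mice = sorted(set(real) & set(null))
            peaks = np.array([real[m].peak_bin for m in mice])
            assert np.all((peaks >= lo) & (peaks < hi))
            res = a.peak_significance(
                np.array([real[m].peak for m in mice]),
                np.array([null[m].peak for m in mice]),
            )
            assert res.p < 1e-3
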