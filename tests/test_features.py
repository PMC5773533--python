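"""Per-bin feature vectors, amount allocation, pattern correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import actistate as a
from actistate.features import EventAmounts, FEATURE_CLASSES
from actistate.states import StatePartition
from actistate.synthetic import uniform_ingestion_variant
from conftest import make_record


def partition_with(active, window=a.DEFAULT_WINDOW, ist_s=1200.0):
    from actistate.core_model import complement_set

    active = np.asarray(active, dtype=float).reshape(-1, 2)
    return StatePartition(window, active, complement_set(active, window), ist_s)


class TestAmountAllocation:
    def test_proportional_allocation(self):
        t0 = a.zt(9)
        rec = make_record(
            ingestion=[
                a.IngestionEvent("feed", a.Interval(t0, t0 + 30)),
                a.IngestionEvent("feed", a.Interval(t0 + 100, t0 + 170)),
            ],
            food_total_g=5.0,
        )
        amounts = a.assign_event_amounts(rec)
        assert np.allclose(amounts.amounts, [1.5, 3.5])

    def test_single_event_gets_daily_total(self):
        rec = make_record(
            ingestion=[a.IngestionEvent("drink", a.Interval(a.zt(9), a.zt(9) + 60))],
            water_total_g=2.5,
        )
        assert np.allclose(a.assign_event_amounts(rec).amounts, [2.5])

    def test_no_events_zero_total_is_fine(self):
        assert len(a.assign_event_amounts(make_record()).amounts) == 0

    def test_negative_amounts_rejected(self):
        with pytest.raises(ValueError):
            EventAmounts(np.array([-1.0]))


class TestDayFeatures:
    def test_as_probability_number_duration_arithmetic(self):
        # one AS covering the first half of bin 0 (ZT8-9 within ZT8-10)
        part = partition_with([[a.zt(8), a.zt(9)]])
        rec = make_record()
        feats = a.compute_day_features(rec, part, EventAmounts(np.empty(0)))
        assert np.isclose(feats.ASP[0], 0.5)
        assert feats.ASN[0] == 1
        assert np.isclose(feats.ASD[0], 60.0)  # minutes
        assert np.all(feats.ASP[1:] == 0) and np.all(feats.ASN[1:] == 0)

    def test_as_covering_whole_bin(self):
        part = partition_with([[a.zt(10), a.zt(12)]])
        feats = a.compute_day_features(make_record(), part, EventAmounts(np.empty(0)))
        assert np.isclose(feats.ASP[1], 1.0)

    def test_span_counted_in_onset_bin_but_time_in_both(self):
        part = partition_with([[a.zt(9), a.zt(11)]])
        feats = a.compute_day_features(make_record(), part, EventAmounts(np.empty(0)))
        assert feats.ASN.tolist() == [1] + [0] * 10
        assert np.isclose(feats.ASD[0], 120.0)
        assert np.isclose(feats.ASP[0], 0.5) and np.isclose(feats.ASP[1], 0.5)

    def test_feeding_intensity_definition(self):
        # 2 g eaten within a 40 min AS inside bin 0 -> 0.05 g per AS-minute
        t0 = a.zt(8)
        part = partition_with([[t0, t0 + 40 * 60]])
        rec = make_record(
            ingestion=[a.IngestionEvent("feed", a.Interval(t0 + 600, t0 + 700))],
            food_total_g=2.0,
        )
        feats = a.compute_day_features(rec, part, a.assign_event_amounts(rec))
        assert np.isclose(feats.ASI_F[0], 0.05)
        assert np.isclose(feats.F[0], 2.0)

    def test_distance_assigned_to_later_event_bin(self):
        w = a.DEFAULT_WINDOW
        t = np.array([a.zt(10) - 30.0, a.zt(10) + 30.0])  # step crosses into bin 1
        rec = make_record(movement=(t, np.array([5.0, 8.0]), np.array([5.0, 9.0])))
        part = partition_with([[a.zt(8), a.zt(9)]], window=w)
        feats = a.compute_day_features(rec, part, EventAmounts(np.empty(0)))
        assert feats.D[0] == 0.0
        assert np.isclose(feats.D[1], 5.0)

    def test_conservation_and_invariants_on_simulated_days(self, mini_parts):
        for rec, _, part in mini_parts:
            feats = a.compute_day_features(rec, part, a.assign_event_amounts(rec))
            assert np.isclose(feats.F.sum(), rec.food_total_g, atol=1e-9)
            assert np.isclose(feats.W.sum(), rec.water_total_g, atol=1e-9)
            # ASP times bin width sums to total positive AS time
            pos = part.active[part.active[:, 1] > part.active[:, 0]]
            assert np.isclose(feats.ASP.sum() * 7200.0, np.sum(pos[:, 1] - pos[:, 0]))
            # distance is invariant to binning: per-bin sums equal total path
            t, x, y = rec.movement_arrays()
            assert np.isclose(feats.D.sum(), np.hypot(np.diff(x), np.diff(y)).sum())
            assert np.all(np.isfinite(feats.ASI_F))
            assert np.all(feats.ASN == np.round(feats.ASN))

    def test_window_mismatch_rejected(self):
        part = partition_with([[100.0, 200.0]], window=a.Interval(0.0, 79200.0))
        with pytest.raises(ValueError):
            a.compute_day_features(make_record(), part, EventAmounts(np.empty(0)))


class TestPatternCorrelations:
    @staticmethod
    def _table_from_vectors(vectors):
        rows = []
        for feat, vec in vectors.items():
            for b, v in enumerate(vec):
                rows.append(("m0", "S", 0, feat, b, v))
        return pd.DataFrame(rows, columns=["mouse_id", "strain", "day", "feature", "bin", "value"])

    def test_self_correlation_is_one(self):
        table = self._table_from_vectors({"F": np.arange(11.0)})
        out = a.pattern_correlations(table, [("F", "F")], level="mouse")
        assert np.isclose(out.pearson_r[0], 1.0) and np.isclose(out.spearman_rho[0], 1.0)

    def test_linear_and_reversed(self):
        x = np.arange(1.0, 12.0)
        table = self._table_from_vectors({"F": x, "W": 2 * x + 3, "D": (2 * x + 3)[::-1]})
        out = a.pattern_correlations(table, [("F", "W"), ("F", "D")], level="mouse")
        assert np.isclose(out.pearson_r[0], 1.0)
        assert np.isclose(out.pearson_r[1], -1.0)

    def test_constant_vector_flagged_not_nan(self):
        table = self._table_from_vectors({"F": np.arange(11.0), "W": np.full(11, 3.0)})
        out = a.pattern_correlations(table, [("F", "W")], level="mouse")
        assert not out.valid[0]

    def test_food_tracks_activity_not_intensity_when_intensity_constant(self):
        """With flat within-AS ingestion probabilities the food daily
        pattern mirrors AS probability while the pooled feeding intensity
        is flat (so carries no pattern information)."""
        lib = [uniform_ingestion_variant(p) for p in a.default_strain_library(3, seed=4)]
        cfg = a.SimulationConfig(strains=lib, mice_per_strain=4, days_per_mouse=6, seed=9)
        cohort, _ = a.simulate_cohort(cfg)
        feats = []
        for rec in cohort:
            hb = a.designate_home_base(rec)
            part = a.designate_states(rec, hb)
            feats.append(a.compute_day_features(rec, part, a.assign_event_amounts(rec)))
        table = a.cohort_features(feats)
        out = a.pattern_correlations(table, [("ASP", "F")], level="mouse")
        assert out.pearson_r[0] > 0.85
        # pooled (AS-time-weighted) intensity per mouse x bin is near-constant
        wide = table.pivot_table(index=["mouse_id", "day"], columns=["feature", "bin"], values="value")
        asp = wide["ASP"].to_numpy()
        asi = wide["ASI_F"].to_numpy()
        f = wide["F"].to_numpy()
        mice = wide.index.get_level_values("mouse_id")
        pooled, fbar = [], []
        for m in sorted(set(mice)):
            sel = np.asarray(mice == m)
            asmin = asp[sel] * 120.0
            tot = asmin.sum(axis=0)
            keep = tot > 5.0  # only bins with real AS time
            p_m = ((asi[sel] * asmin).sum(axis=0) / np.where(keep, tot, np.nan))[keep]
            f_m = f[sel].mean(axis=0)[keep]
            # each animal's intensity is flat across the day...
            assert p_m.std() / p_m.mean() < 0.1
            pooled.append(p_m - p_m.mean())  # center out strain-level rate differences
            fbar.append(f_m - f_m.mean())
        pooled = np.concatenate(pooled)
        fbar = np.concatenate(fbar)
        # ...so, unlike food itself, it carries no daily-pattern signal
        assert abs(stats.pearsonr(pooled, fbar).statistic) < 0.4

    def test_feature_matrix_shape(self, mini_parts):
        feats = [
            a.compute_day_features(rec, part, a.assign_event_amounts(rec))
            for rec, _, part in mini_parts
        ]
        table = a.cohort_features(feats)
        from actistate.features import feature_matrix

        X, strains, mice = feature_matrix(table, list(FEATURE_CLASSES))
        assert X.shape == (len(feats), 99)
        assert len(strains) == len(mice) == len(feats)
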