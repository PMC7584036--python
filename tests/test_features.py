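"""Cycle segmentation, the seven features, labels, and BP filters."""

import numpy as np
import pandas as pd
import pytest

from pulsebp.features import (
    Cycle,
    apply_bp_filters,
    compute_hr,
    compute_morphology,
    compute_ptt,
    extract_cycle_features,
    extract_labels,
    segment_cycles,
)
from pulsebp.fiducials import detect_fiducials
from pulsebp.pipeline import record_features
from pulsebp.records import FLAG_NO_NOTCH
from pulsebp.synthetic import SimConfig, simulate_record

FS = 125.0


class TestSegmentCycles:
    def test_hr75_cycles_all_valid(self, clean_record):
        # RR = 100 samples, so every R-R-R window is exactly 200 samples
        fid = clean_record.truth_fiducials
        cycles, counts = segment_cycles(fid, FS)
        assert counts["too_long"] == 0
        assert counts["valid"] == len(cycles) > 0
        assert all(c.window_len <= 200 for c in cycles)

    def test_hr50_cycles_all_skipped(self):
        # RR = 150 samples -> every window is 300 > 200
        rec = simulate_record(SimConfig(duration_s=20.0, heart_rate_bpm=50.0))
        cycles, counts = segment_cycles(rec.truth_fiducials, FS)
        assert cycles == []
        assert counts["too_long"] == counts["candidates"] > 0

    def test_flagged_beat_skips_exactly_that_cycle(self, clean_record):
        fid = clean_record.truth_fiducials
        baseline, _ = segment_cycles(fid, FS)
        flags = fid.flags.copy()
        flags[3] |= FLAG_NO_NOTCH
        import dataclasses

        flagged = dataclasses.replace(fid, flags=flags)
        cycles, counts = segment_cycles(flagged, FS)
        assert len(cycles) == len(baseline) - 1
        assert counts["flagged"] == 1
        assert all(c.beat_index != 3 for c in cycles)

    def test_conservation_of_candidates(self, clean_record):
        _, counts = segment_cycles(clean_record.truth_fiducials, FS)
        assert (
            counts["valid"] + counts["too_long"] + counts["flagged"]
            + counts["incomplete"] == counts["candidates"]
        )

    def test_fewer_than_three_r_peaks_warns(self):
        from pulsebp.records import FiducialSet

        with pytest.warns(UserWarning):
            cycles, _ = segment_cycles(FiducialSet(r_peaks=np.array([5, 100])), FS)
        assert cycles == []


class TestScalarFeatures:
    def test_ptt_formula(self):
        assert compute_ptt(1000, 1031, FS) == pytest.approx(31 / 125)

    def test_ptt_requires_causal_ordering(self):
        with pytest.raises(ValueError):
            compute_ptt(1000, 1000, FS)

    @pytest.mark.parametrize("rr_samples, expected", [(100, 75.0), (63, 60.0 / 0.504)])
    def test_hr_formula(self, rr_samples, expected):
        assert compute_hr(0, rr_samples, FS) == pytest.approx(expected)

    def test_hr_zero_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_hr(10, 10, FS)

    def test_simulated_hr_recovered(self):
        rec = simulate_record(SimConfig(duration_s=20.0, heart_rate_bpm=60.0))
        r = rec.truth_fiducials.r_peaks
        hrs = [compute_hr(r[i], r[i + 1], FS) for i in range(len(r) - 1)]
        assert np.all(np.abs(np.array(hrs) - 60.0) <= 1.0)


class TestMorphology:
    def test_rectangle_area_and_amplitude_ratio(self):
        # flat top at 1.0 between foot and notch, then descent to the next
        # foot, with a small bump for the second peak
        x = np.zeros(201)
        x[1:51] = 1.0  # foot=0, plateau to notch at 50 (0.4 s at 125 Hz)
        x[51:100] = np.linspace(1.0, 0.4, 49)
        x[100] = 0.4  # second peak amplitude 0.4 above the foot
        x[101:200] = np.linspace(0.4, 0.0, 99)
        ri, st, ut, sv, dv = compute_morphology(x, 0, 25, 50, 100, 200, FS)
        assert ri == pytest.approx(0.4)
        assert st == pytest.approx(50 / 125)
        assert ut == pytest.approx(25 / 125)
        # trapezoid of the unit plateau: 0.4 minus half-sample edge ramps
        assert sv == pytest.approx(0.4, abs=1.0 / (2 * FS) + 1e-9)
        assert dv == pytest.approx(np.trapezoid(x[50:201], dx=1 / FS))

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            compute_morphology(np.ones(100), 0, 30, 20, 60, 90, FS)

    def test_simulated_reflection_ratio_recovered(self, clean_record):
        table, _ = record_features(clean_record.signals)
        assert np.all(np.abs(table["ri"] - 0.5) < 0.05)


class TestLabels:
    def test_clean_cycle_extrema_exact(self, clean_record):
        feet = clean_record.truth_fiducials.feet
        cycle = Cycle(0, 0, 1, 2, int(feet[2]), int(feet[3]))
        sbp, dbp = extract_labels(clean_record.signals.abp, cycle)
        assert (sbp, dbp) == (120.0, 80.0)

    def test_constant_abp_degenerates(self):
        cycle = Cycle(0, 0, 1, 2, 10, 60)
        sbp, dbp = extract_labels(np.full(100, 90.0), cycle)
        assert sbp == dbp == 90.0

    def test_noisy_labels_within_three_mmhg(self):
        rec = simulate_record(SimConfig(duration_s=20.0, noise_sd=1.0, seed=2))
        feet = rec.truth_fiducials.feet
        for k in range(2, len(feet) - 2):
            cycle = Cycle(0, 0, 1, 2, int(feet[k]), int(feet[k + 1]))
            sbp, dbp = extract_labels(rec.signals.abp, cycle)
            assert abs(sbp - 120.0) <= 3.0
            assert abs(dbp - 80.0) <= 3.0

    def test_span_outside_signal_rejected(self):
        cycle = Cycle(0, 0, 1, 2, 50, 150)
        with pytest.raises(ValueError):
            extract_labels(np.zeros(100), cycle)


class TestBPFilters:
    def test_boundary_cases_removed_at_printed_values(self):
        table = pd.DataFrame(
            {
                "sbp": [180.0, 80.0, 120.0, 120.0, 120.0],
                "dbp": [70.0, 70.0, 60.0, 130.0, 80.0],
            }
        )
        kept, counts = apply_bp_filters(table)
        assert len(kept) == 1
        assert kept.iloc[0]["sbp"] == 120.0 and kept.iloc[0]["dbp"] == 80.0
        assert sum(counts.values()) == 4

    def test_in_range_records_unchanged(self):
        table = pd.DataFrame({"sbp": [81.0, 179.0, 130.0], "dbp": [61.0, 129.0, 75.0]})
        kept, counts = apply_bp_filters(table)
        assert len(kept) == 3 and sum(counts.values()) == 0

    def test_planted_violations_are_counted(self, rng):
        n = 100
        sbp = rng.uniform(90, 170, n)
        dbp = rng.uniform(65, 120, n)
        sbp[:4] = [185, 190, 79, 60]  # 2 high + 2 low systolic
        dbp[:4] = 80
        dbp[4:10] = [135, 131, 140, 59, 55, 50]  # 3 high + 3 low diastolic
        sbp[4:10] = 120
        table = pd.DataFrame({"sbp": sbp, "dbp": dbp})
        kept, counts = apply_bp_filters(table)
        assert len(kept) == 90
        assert counts == {"sbp_high": 2, "sbp_low": 2, "dbp_high": 3, "dbp_low": 3}

    def test_idempotence(self, rng):
        table = pd.DataFrame(
            {"sbp": rng.uniform(70, 200, 50), "dbp": rng.uniform(50, 140, 50)}
        )
        once, _ = apply_bp_filters(table)
        twice, counts = apply_bp_filters(once)
        assert once.equals(twice) and sum(counts.values()) == 0

    def test_empty_table_passes_through(self):
        kept, counts = apply_bp_filters(pd.DataFrame(columns=["sbp", "dbp"]))
        assert len(kept) == 0 and sum(counts.values()) == 0


class TestRecoveryPipeline:
    def test_features_recover_truth_on_clean_record(self, clean_record):
        table, _ = record_features(clean_record.signals)
        truth = clean_record.truth_features.dropna()
        merged = table.merge(
            truth, left_on="cycle_index", right_on="beat_index", suffixes=("", "_t")
        )
        assert len(merged) > 10
        assert np.all(np.abs(merged["ptt"] - merged["ptt_t"]) <= 0.016)
        assert np.all(np.abs(merged["hr"] - merged["hr_t"]) <= 1.0)
        assert np.all(np.abs(merged["ri"] - merged["ri_t"]) <= 0.05)
        assert np.all(np.abs(merged["st"] - merged["st_t"]) <= 0.016)
        assert np.all(np.abs(merged["ut"] - merged["ut_t"]) <= 0.016)
        assert np.all(np.abs(merged["sv"] / merged["sv_t"] - 1) <= 0.05)
        assert np.all(np.abs(merged["dv"] / merged["dv_t"] - 1) <= 0.05)
        assert (merged["sbp"] == 120.0).all() and (merged["dbp"] == 80.0).all()

    def test_low_heart_rate_recovery_without_window_rule(self):
        rec = simulate_record(SimConfig(duration_s=20.0, heart_rate_bpm=50.0))
        with_rule, counts = record_features(rec.signals)
        assert len(with_rule) == 0 and counts["too_long"] > 0
        table, _ = record_features(rec.signals, max_window_samples=None)
        assert len(table) > 5
        assert np.all(np.abs(table["hr"] - 50.0) <= 1.0)
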