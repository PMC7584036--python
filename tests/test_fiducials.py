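"""QRS detection and PPG landmark detectors."""

import numpy as np
import pytest

from pulsebp.fiducials import (
    detect_dicrotic_notch,
    detect_fiducials,
    detect_max_slope,
    detect_ppg_foot,
    detect_r_peaks,
    detect_second_peak,
    detect_systolic_peak,
)
from pulsebp.synthetic import SimConfig, simulate_record

FS = 125.0


class TestRPeaks:
    def test_clean_record_peaks_match_truth(self, clean_record):
        truth = clean_record.truth_fiducials.r_peaks
        detected = detect_r_peaks(clean_record.signals.ecg, FS)
        assert len(detected) == len(truth)
        assert np.all(np.abs(detected - truth) <= 2)

    def test_all_zero_signal_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(5000), FS).size == 0

    def test_short_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_r_peaks(np.zeros(5), FS).size == 0

    @pytest.mark.parametrize("hr", [50.0, 100.0])
    def test_rr_intervals_reproduce_configured_rate(self, hr):
        rec = simulate_record(SimConfig(duration_s=20.0, heart_rate_bpm=hr))
        detected = detect_r_peaks(rec.signals.ecg, FS)
        rr = np.diff(detected)
        assert np.all(np.abs(rr - round(60.0 / hr * FS)) <= 1)

    def test_refractory_spacing(self, clean_record):
        detected = detect_r_peaks(clean_record.signals.ecg, FS)
        assert np.all(np.diff(detected) >= int(0.2 * FS))

    def test_amplitude_and_offset_invariance(self, clean_record):
        ecg = clean_record.signals.ecg
        a = detect_r_peaks(ecg, FS)
        b = detect_r_peaks(3.7 * ecg + 5.0, FS)
        assert np.array_equal(a, b)


class TestPPGLandmarkUnits:
    def test_foot_of_monotone_increase_is_region_start(self):
        x = np.linspace(0, 1, 50)
        assert detect_ppg_foot(x, (10, 40)) == 10

    def test_foot_of_v_shape_is_the_minimum(self):
        x = np.abs(np.arange(60) - 33).astype(float)
        assert detect_ppg_foot(x, (5, 55)) == 33

    def test_foot_empty_region_rejected(self):
        with pytest.raises(ValueError):
            detect_ppg_foot(np.zeros(10), (4, 4))

    def test_systolic_peak_of_unimodal_bump(self):
        x = -((np.arange(80) - 47.0) ** 2)
        assert detect_systolic_peak(x, 10, 70) == 47

    def test_systolic_peak_decreasing_after_foot(self):
        x = np.linspace(5, 0, 50)
        assert detect_systolic_peak(x, 7, 30) == 8  # earliest of the tail

    def test_notch_on_linear_descent_is_degenerate(self):
        x = np.linspace(10, 0, 40)
        idx, degenerate = detect_dicrotic_notch(x, 5, 35)
        assert degenerate and idx == 6

    def test_notch_matches_brute_force_chord_minimum(self, rng):
        x = np.cos(np.linspace(0, np.pi, 60)) + 0.3 * np.sin(
            np.linspace(0, 6 * np.pi, 60)
        )
        peak, foot_next = 3, 55
        chord = x[peak] + (x[foot_next] - x[peak]) * (
            np.arange(peak + 1, foot_next) - peak
        ) / (foot_next - peak)
        brute = peak + 1 + int(np.argmin(x[peak + 1 : foot_next] - chord))
        idx, degenerate = detect_dicrotic_notch(x, peak, foot_next)
        assert not degenerate and idx == brute

    def test_second_peak_on_quadratic_is_degenerate(self):
        x = (np.arange(40, dtype=float) - 20) ** 2
        idx, degenerate = detect_second_peak(x, 5, 35)
        assert degenerate and idx == 6

    def test_second_peak_matches_second_difference_scan(self):
        x = np.sin(np.linspace(0, 3 * np.pi, 90))
        notch, foot_next = 10, 80
        i = np.arange(notch + 1, foot_next - 1)
        brute = int(i[np.argmin(x[i + 1] - 2 * x[i] + x[i - 1])])
        idx, degenerate = detect_second_peak(x, notch, foot_next)
        assert not degenerate and idx == brute

    def test_max_slope_linear_ramp_takes_earliest(self):
        x = np.linspace(0, 5, 50)
        assert detect_max_slope(x, 10, 30) == 10

    def test_max_slope_sigmoid_center(self):
        n = np.arange(100)
        x = 1 / (1 + np.exp(-(n - 50) / 4.0))
        assert abs(detect_max_slope(x, 20, 80) - 50) <= 1

    def test_degenerate_intervals_rejected(self):
        x = np.zeros(20)
        with pytest.raises(ValueError):
            detect_max_slope(x, 10, 10)
        with pytest.raises(ValueError):
            detect_dicrotic_notch(x, 10, 11)
        with pytest.raises(ValueError):
            detect_second_peak(x, 10, 12)


class TestFullDetection:
    def test_per_beat_ordering_invariant(self, clean_record):
        fid = detect_fiducials(
            clean_record.signals.ecg, clean_record.signals.ppg, FS
        )
        fid.validate_ordering()
        assert fid.n_beats > 0

    def test_landmarks_match_truth_on_clean_record(self, clean_record):
        truth = clean_record.truth_fiducials
        fid = detect_fiducials(clean_record.signals.ecg, clean_record.signals.ppg, FS)
        n = min(fid.n_beats, truth.n_beats)
        assert n > 5
        assert np.all(np.abs(fid.feet[:n] - truth.feet[:n]) <= 1)
        assert np.all(np.abs(fid.systolic_peaks[:n] - truth.systolic_peaks[:n]) <= 1)
        assert np.all(np.abs(fid.notches[:n] - truth.notches[:n]) <= 2)
        assert np.all(np.abs(fid.second_peaks[:n] - truth.second_peaks[:n]) <= 3)
        assert np.all(np.abs(fid.max_slopes[:n] - truth.max_slopes[:n]) <= 1)

    def test_translation_equivariance_of_landmark_detectors(self, clean_record):
        ppg = clean_record.signals.ppg
        shift = 40
        shifted = np.concatenate([ppg[-shift:], ppg])
        r = clean_record.truth_fiducials.r_peaks
        foot = detect_ppg_foot(ppg, (int(r[2]), int(r[3])))
        foot_s = detect_ppg_foot(shifted, (int(r[2]) + shift, int(r[3]) + shift))
        assert foot_s == foot + shift

    def test_amplitude_scale_invariance_of_landmarks(self, clean_record):
        ecg, ppg = clean_record.signals.ecg, clean_record.signals.ppg
        a = detect_fiducials(ecg, ppg, FS)
        b = detect_fiducials(ecg, 2.5 * ppg + 1.0, FS, r_peaks=a.r_peaks)
        assert np.array_equal(a.feet, b.feet)
        assert np.array_equal(a.notches, b.notches)
        assert np.array_equal(a.second_peaks, b.second_peaks)
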