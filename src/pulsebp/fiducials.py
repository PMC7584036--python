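"""ECG R-peak detection (Pan-Tompkins) and PPG landmark detection.

The QRS detector follows the classic Pan-Tompkins chain, parameterized
for 125 Hz signals: 5-15 Hz band-pass, five-point derivative, squaring,
150 ms moving-window integration, then adaptive dual thresholds with
search-back and a 200 ms refractory period.  Detected peaks are refined
to the local ECG maximum so downstream intervals are measured between
true R-wave apices.

PPG landmarks per pulse (between two consecutive feet):

* foot           — waveform minimum in the inter-R region
* systolic peak  — waveform maximum after the foot
* dicrotic notch — minimum of (signal - chord), the chord running from
                   the systolic peak down to the *next* foot
* second peak    — minimum of the discrete second difference after the
                   notch
* maximum slope  — maximum of the forward first difference on the
                   rising edge (the PTT reference point)

All argmin/argmax ties resolve to the earliest index, making detection
deterministic and order-stable.  Degenerate geometry (a flat chord
residual or constant curvature — PPG pulses without a dicrotic notch do
occur) sets a per-beat flag instead of failing; flagged beats are later
excluded from feature extraction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from pulsebp.records import (
    FLAG_DEGENERATE_SECOND_PEAK,
    FLAG_NO_NOTCH,
    FLAG_OK,
    FiducialSet,
)

__all__ = [
    "detect_r_peaks",
    "detect_ppg_foot",
    "detect_systolic_peak",
    "detect_dicrotic_notch",
    "detect_second_peak",
    "detect_max_slope",
    "detect_fiducials",
]

# Pan-Tompkins constants (documented configuration, 125 Hz reference)
PT_BANDPASS_HZ = (5.0, 15.0)
PT_BANDPASS_ORDER = 2
PT_INTEGRATION_WINDOW_S = 0.150
PT_REFRACTORY_S = 0.200
PT_THRESHOLD_FRACTION = 0.25  # THR1 = NPK + 0.25 * (SPK - NPK)
PT_SEARCHBACK_FRACTION = 0.5  # THR2 = 0.5 * THR1
PT_REFINE_WINDOW_S = 0.075  # refine to local ECG max within +-75 ms


def detect_r_peaks(ecg: np.ndarray, fs_hz: float) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns indices of R-wave maxima.

    Returns an empty array (with a warning) for signals shorter than one
    integration window or without QRS energy.
    """
    x = np.asarray(ecg, dtype=float)
    win = max(int(round(PT_INTEGRATION_WINDOW_S * fs_hz)), 1)
    if len(x) <= win:
        warnings.warn("signal shorter than the integration window; no peaks")
        return np.array([], dtype=int)
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    nyq = fs_hz / 2.0
    low, high = PT_BANDPASS_HZ[0] / nyq, min(PT_BANDPASS_HZ[1] / nyq, 0.99)
    b, a = sps.butter(PT_BANDPASS_ORDER, [low, high], btype="band")
    filtered = sps.filtfilt(b, a, x)

    deriv = sps.lfilter(np.array([1, 2, 0, -2, -1]) * fs_hz / 8.0, [1.0], filtered)
    squared = deriv**2
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(PT_REFRACTORY_S * fs_hz))
    candidates = _local_maxima(integrated, refractory)
    if candidates.size == 0:
        return np.array([], dtype=int)

    spk = float(np.max(integrated[candidates[: max(1, len(candidates) // 4)]]))
    npk = float(np.mean(integrated)) * 0.5
    peaks: list[int] = []
    missed: list[int] = []
    expected_rr = None
    for idx in candidates:
        level = integrated[idx]
        thr1 = npk + PT_THRESHOLD_FRACTION * (spk - npk)
        if level >= thr1:
            if peaks and idx - peaks[-1] < refractory:
                if level > integrated[peaks[-1]]:
                    peaks[-1] = idx
                continue
            # search-back: a long gap with sub-threshold candidates in it
            if peaks and expected_rr and idx - peaks[-1] > 1.66 * expected_rr:
                thr2 = PT_SEARCHBACK_FRACTION * thr1
                gap = [m for m in missed if peaks[-1] + refractory <= m < idx - refractory]
                if gap:
                    best = max(gap, key=lambda m: integrated[m])
                    if integrated[best] >= thr2:
                        peaks.append(best)
                        spk = 0.25 * integrated[best] + 0.75 * spk
            peaks.append(idx)
            spk = 0.125 * level + 0.875 * spk
            if len(peaks) >= 2:
                rrs = np.diff(peaks[-9:])
                expected_rr = float(np.mean(rrs))
            missed = []
        else:
            npk = 0.125 * level + 0.875 * npk
            missed.append(idx)

    refine = max(int(round(PT_REFINE_WINDOW_S * fs_hz)), 1)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - refine), min(len(x), p + refine + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    if refined.size >= 2:  # enforce refractory spacing after refinement
        keep = [int(refined[0])]
        for p in refined[1:]:
            if p - keep[-1] >= refractory:
                keep.append(int(p))
            elif x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        refined = np.asarray(keep, dtype=int)
    return refined


def _local_maxima(x: np.ndarray, min_distance: int) -> np.ndarray:
    peaks, _ = sps.find_peaks(x, distance=max(min_distance, 1))
    return peaks


def _first_argmin(x: np.ndarray, rel_tol: float = 1e-9) -> int:
    """Earliest index attaining the minimum (to a tiny relative tolerance,
    so numerically flat segments resolve deterministically to the left)."""
    lo = np.min(x)
    tol = rel_tol * max(float(np.max(np.abs(x))), 1e-30)
    return int(np.nonzero(x <= lo + tol)[0][0])


def _first_argmax(x: np.ndarray, rel_tol: float = 1e-9) -> int:
    return _first_argmin(-np.asarray(x, dtype=float), rel_tol)


def _check_region(lo: int, hi: int, n: int, minimum_span: int = 1) -> None:
    if not (0 <= lo < hi <= n):
        raise ValueError(f"region [{lo}, {hi}) outside signal of length {n}")
    if hi - lo < minimum_span:
        raise ValueError(f"region [{lo}, {hi}) too short (need >= {minimum_span})")


def detect_ppg_foot(ppg: np.ndarray, region: tuple[int, int]) -> int:
    """Pulse foot: argmin of the waveform over [start, end); earliest tie."""
    x = np.asarray(ppg, dtype=float)
    lo, hi = int(region[0]), int(region[1])
    _check_region(lo, hi, len(x))
    return lo + _first_argmin(x[lo:hi])


def detect_systolic_peak(ppg: np.ndarray, foot: int, region_end: int) -> int:
    """Systolic peak: argmax over (foot, region_end]; earliest tie."""
    x = np.asarray(ppg, dtype=float)
    _check_region(foot + 1, region_end + 1, len(x))
    return foot + 1 + _first_argmax(x[foot + 1 : region_end + 1])


def detect_dicrotic_notch(
    ppg: np.ndarray, systolic_peak: int, foot_next: int
) -> tuple[int, bool]:
    """Dicrotic notch: argmin of (signal - chord) over the descent.

    The chord runs from the systolic peak to the next pulse's foot.
    Returns ``(index, degenerate)``; ``degenerate`` is True when the
    residual is flat (no distinct notch), in which case the earliest
    interior index is returned.
    """
    x = np.asarray(ppg, dtype=float)
    _check_region(systolic_peak, foot_next, len(x), minimum_span=3)
    span = foot_next - systolic_peak
    u = np.arange(1, span)
    chord = x[systolic_peak] + (x[foot_next] - x[systolic_peak]) * u / span
    residual = x[systolic_peak + 1 : foot_next] - chord
    degenerate = bool(np.ptp(residual) < 1e-12 * max(np.ptp(x), 1.0))
    if degenerate:
        return systolic_peak + 1, True  # earliest interior index
    return systolic_peak + 1 + _first_argmin(residual), False


def detect_second_peak(
    ppg: np.ndarray, notch: int, foot_next: int
) -> tuple[int, bool]:
    """Second peak: argmin of the second difference over (notch, foot_next).

    The second difference x[n+1] - 2x[n] + x[n-1] is most negative where
    the reflected wave crests.  Returns ``(index, degenerate)`` with the
    degenerate flag raised for constant curvature (e.g. an exactly
    quadratic descent).
    """
    x = np.asarray(ppg, dtype=float)
    if not notch < foot_next - 2:
        raise ValueError("interval too short for a second-difference scan")
    _check_region(notch, foot_next, len(x))
    idx = np.arange(notch + 1, foot_next - 1)
    second_diff = x[idx + 1] - 2 * x[idx] + x[idx - 1]
    degenerate = bool(np.ptp(second_diff) < 1e-12 * max(np.ptp(x), 1.0))
    if degenerate:
        return int(idx[0]), True  # earliest interior index
    return int(idx[_first_argmin(second_diff)]), False


def detect_max_slope(ppg: np.ndarray, foot: int, systolic_peak: int) -> int:
    """Maximum-slope point: argmax of the forward difference on [foot, peak)."""
    x = np.asarray(ppg, dtype=float)
    if not foot < systolic_peak:
        raise ValueError("foot must precede the systolic peak")
    _check_region(foot, systolic_peak + 1, len(x), minimum_span=2)
    diff = x[foot + 1 : systolic_peak + 1] - x[foot:systolic_peak]
    return foot + _first_argmax(diff)


def detect_fiducials(
    ecg: np.ndarray,
    ppg: np.ndarray,
    fs_hz: float,
    r_peaks: np.ndarray | None = None,
) -> FiducialSet:
    """Full per-beat landmark detection on a preprocessed record.

    Beat ``i`` spans R peaks ``i`` to ``i+1``: its foot is the PPG minimum
    in that inter-R region, and its descent ends at the following beat's
    foot, so the last two R peaks close the final complete pulse.
    Detector-level degeneracies are recorded in the per-beat flag mask.
    """
    ppg = np.asarray(ppg, dtype=float)
    if r_peaks is None:
        r_peaks = detect_r_peaks(ecg, fs_hz)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        return FiducialSet(r_peaks=r_peaks)

    feet = np.array(
        [detect_ppg_foot(ppg, (r_peaks[i], r_peaks[i + 1])) for i in range(len(r_peaks) - 1)]
    )

    n_beats = len(feet) - 1  # last foot only closes the previous pulse
    slopes = np.zeros(n_beats, dtype=int)
    peaks = np.zeros(n_beats, dtype=int)
    notches = np.zeros(n_beats, dtype=int)
    seconds = np.zeros(n_beats, dtype=int)
    flags = np.zeros(n_beats, dtype=int)
    for i in range(n_beats):
        foot, foot_next = int(feet[i]), int(feet[i + 1])
        if foot_next - foot < 4:  # collapsed pulse (noise); flag and move on
            slopes[i] = peaks[i] = notches[i] = seconds[i] = foot
            flags[i] = FLAG_NO_NOTCH | FLAG_DEGENERATE_SECOND_PEAK
            continue
        peak = detect_systolic_peak(ppg, foot, foot_next - 1)
        slope = detect_max_slope(ppg, foot, peak)
        flag = FLAG_OK
        if foot_next - peak >= 3:
            notch, no_notch = detect_dicrotic_notch(ppg, peak, foot_next)
            if no_notch:
                flag |= FLAG_NO_NOTCH
        else:
            notch, flag = peak, flag | FLAG_NO_NOTCH
        if notch < foot_next - 2:
            second, degen = detect_second_peak(ppg, notch, foot_next)
            if degen:
                flag |= FLAG_DEGENERATE_SECOND_PEAK
        else:
            second, flag = notch, flag | FLAG_DEGENERATE_SECOND_PEAK
        slopes[i], peaks[i], notches[i], seconds[i], flags[i] = (
            slope,
            peak,
            notch,
            second,
            flag,
        )

    return FiducialSet(
        r_peaks=r_peaks,
        feet=feet[:n_beats],
        max_slopes=slopes,
        systolic_peaks=peaks,
        notches=notches,
        second_peaks=seconds,
        flags=flags,
    )
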