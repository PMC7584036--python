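"""Cycle segmentation, the seven per-cycle features, and BP labels.

A *cycle* is the window running from one R peak, through the following
systolic peak and R peak, to the R peak after that (two RR intervals).
Cycles longer than 200 samples at 125 Hz, or whose PPG landmarks are
missing/flagged, are considered abnormal and skipped (counted, never
silently dropped).

Features per cycle (units in parentheses):

* PTT (s)  — R peak to the PPG maximum-slope point, which must fall
             within half a cycle (one RR interval) of the R peak
* HR (bpm) — 60 / RR using the cycle's first R-R interval
* RI (-)   — reflection index b/a: second-peak and systolic-peak
             amplitudes measured above the first foot
* ST (s)   — systolic timespan, foot to dicrotic notch
* UT (s)   — up time, foot to systolic peak
* SV (a.u.)— trapezoidal integral of the normalized PPG, foot to notch
* DV (a.u.)— trapezoidal integral, notch to the next foot

SBP/DBP labels are the ABP extrema over the cycle's foot-to-foot span.
Cycles with extreme pressures (SBP >= 180 or <= 80, DBP >= 130 or <= 60
mmHg) are removed by :func:`apply_bp_filters`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pulsebp.records import FLAG_OK, FiducialSet, SignalRecord

__all__ = [
    "Cycle",
    "MAX_WINDOW_SAMPLES",
    "segment_cycles",
    "compute_ptt",
    "compute_hr",
    "compute_morphology",
    "extract_labels",
    "apply_bp_filters",
    "extract_cycle_features",
    "FEATURE_COLUMNS",
]

MAX_WINDOW_SAMPLES = 200

FEATURE_COLUMNS = ["ptt", "hr", "ri", "st", "ut", "sv", "dv"]

# BP exclusion thresholds (mmHg); records AT the threshold are removed
SBP_HIGH = 180.0
SBP_LOW = 80.0
DBP_HIGH = 130.0
DBP_LOW = 60.0


@dataclass
class Cycle:
    """One candidate window: three consecutive R peaks plus its pulse feet."""

    beat_index: int
    r_start: int
    r_mid: int
    r_end: int
    foot_first: int
    foot_second: int

    def __post_init__(self) -> None:
        if not self.r_start < self.r_mid < self.r_end:
            raise ValueError("R peaks must be strictly increasing")
        if not self.foot_first < self.foot_second:
            raise ValueError("feet must be strictly increasing")

    @property
    def window_len(self) -> int:
        return self.r_end - self.r_start


def segment_cycles(
    fiducials: FiducialSet,
    fs_hz: float,
    max_window_samples: int | None = MAX_WINDOW_SAMPLES,
) -> tuple[list[Cycle], dict[str, int]]:
    """Build valid cycles from consecutive R-peak triples.

    Returns ``(cycles, counts)`` where ``counts`` reports how many
    candidates were skipped and why; ``cycles + skipped == candidates``.
    ``max_window_samples=None`` disables the window-length rule (used when
    measuring per-beat feature recovery at low heart rates, where every
    cycle legitimately exceeds the rule).
    """
    counts = {"candidates": 0, "valid": 0, "too_long": 0, "flagged": 0, "incomplete": 0}
    r = fiducials.r_peaks
    if len(r) < 3:
        warnings.warn("fewer than 3 R peaks; no cycles")
        return [], counts
    cycles: list[Cycle] = []
    for i in range(len(r) - 2):
        counts["candidates"] += 1
        if max_window_samples is not None and r[i + 2] - r[i] > max_window_samples:
            counts["too_long"] += 1
            continue
        if i + 1 >= fiducials.n_beats:
            counts["incomplete"] += 1
            continue
        if fiducials.flags[i] != FLAG_OK:
            counts["flagged"] += 1
            continue
        cycles.append(
            Cycle(
                beat_index=i,
                r_start=int(r[i]),
                r_mid=int(r[i + 1]),
                r_end=int(r[i + 2]),
                foot_first=int(fiducials.feet[i]),
                foot_second=int(fiducials.feet[i + 1]),
            )
        )
        counts["valid"] += 1
    return cycles, counts


def compute_ptt(r_peak: int, max_slope: int, fs_hz: float) -> float:
    """PTT in seconds: (max_slope - r_peak) / fs; must be positive."""
    if max_slope <= r_peak:
        raise ValueError("max-slope point must follow the R peak (PTT > 0)")
    return (max_slope - r_peak) / fs_hz


def compute_hr(r_a: int, r_b: int, fs_hz: float) -> float:
    """Heart rate in bpm from one R-R interval: 60 / ((r_b - r_a) / fs)."""
    if r_b <= r_a:
        raise ValueError("R peaks must be strictly increasing")
    return 60.0 * fs_hz / (r_b - r_a)


def compute_morphology(
    ppg: np.ndarray,
    foot_first: int,
    systolic_peak: int,
    notch: int,
    second_peak: int,
    foot_second: int,
    fs_hz: float,
) -> tuple[float, float, float, float, float]:
    """(RI, ST, UT, SV, DV) for one pulse on the amplitude-normalized PPG.

    RI measures both amplitudes relative to the first foot, making it
    invariant to the pulse's baseline level; SV/DV are trapezoidal
    integrals with dt = 1/fs.
    """
    order = (foot_first, systolic_peak, notch, second_peak, foot_second)
    if any(a > b for a, b in zip(order, order[1:])):
        raise ValueError(f"fiducial ordering violated: {order}")
    x = np.asarray(ppg, dtype=float)
    st = (notch - foot_first) / fs_hz
    ut = (systolic_peak - foot_first) / fs_hz
    a = x[systolic_peak] - x[foot_first]
    b = x[second_peak] - x[foot_first]
    if a <= 0:
        raise ValueError("systolic amplitude above the foot must be positive")
    ri = b / a
    sv = float(np.trapezoid(x[foot_first : notch + 1], dx=1.0 / fs_hz))
    dv = float(np.trapezoid(x[notch : foot_second + 1], dx=1.0 / fs_hz))
    return float(ri), float(st), float(ut), float(sv), float(dv)


def extract_labels(abp: np.ndarray, cycle: Cycle) -> tuple[float, float]:
    """(SBP, DBP) = (max, min) of ABP over the cycle's foot-to-foot span."""
    x = np.asarray(abp, dtype=float)
    if not (0 <= cycle.foot_first < cycle.foot_second < len(x)):
        raise ValueError("cycle span lies outside the ABP signal")
    span = x[cycle.foot_first : cycle.foot_second + 1]
    return float(np.max(span)), float(np.min(span))


def apply_bp_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop cycles with extreme pressures; survivors satisfy
    80 < SBP < 180 and 60 < DBP < 130 (mmHg).

    Each removed record is attributed to the first rule it violates, in
    the order sbp_high, sbp_low, dbp_high, dbp_low, so the per-rule
    counts sum to the number of removals.  Idempotent.
    """
    if len(records) == 0:
        return records.copy(), {"sbp_high": 0, "sbp_low": 0, "dbp_high": 0, "dbp_low": 0}
    sbp = records["sbp"].to_numpy(dtype=float)
    dbp = records["dbp"].to_numpy(dtype=float)
    rules = {
        "sbp_high": sbp >= SBP_HIGH,
        "sbp_low": sbp <= SBP_LOW,
        "dbp_high": dbp >= DBP_HIGH,
        "dbp_low": dbp <= DBP_LOW,
    }
    removed = np.zeros(len(records), dtype=bool)
    counts = {}
    for name, mask in rules.items():
        newly = mask & ~removed
        counts[name] = int(newly.sum())
        removed |= mask
    return records.loc[~removed].reset_index(drop=True), counts


def extract_cycle_features(
    signals: SignalRecord,
    fiducials: FiducialSet,
    max_window_samples: int | None = MAX_WINDOW_SAMPLES,
    ppg_normalized: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-cycle feature table with SBP/DBP labels for one record.

    ``ppg_normalized`` should be the min-max normalized, baseline-filtered
    PPG; when omitted it is derived from ``signals.ppg`` directly.
    Columns: record_id, cycle_index, ptt, hr, ri, st, ut, sv, dv, sbp,
    dbp, flags.  Cycles whose max-slope point is non-causal or outside
    half a cycle are counted under ``ptt_invalid``.
    """
    from pulsebp.preprocess import minmax_normalize

    fs = signals.sampling_rate_hz
    ppg = minmax_normalize(signals.ppg) if ppg_normalized is None else ppg_normalized
    cycles, counts = segment_cycles(fiducials, fs, max_window_samples)
    counts["ptt_invalid"] = 0
    rows = []
    for cycle in cycles:
        i = cycle.beat_index
        slope = int(fiducials.max_slopes[i])
        if slope <= cycle.r_start or slope - cycle.r_start >= cycle.r_mid - cycle.r_start:
            counts["ptt_invalid"] += 1
            counts["valid"] -= 1
            continue
        ptt = compute_ptt(cycle.r_start, slope, fs)
        hr = compute_hr(cycle.r_start, cycle.r_mid, fs)
        ri, st, ut, sv, dv = compute_morphology(
            ppg,
            cycle.foot_first,
            int(fiducials.systolic_peaks[i]),
            int(fiducials.notches[i]),
            int(fiducials.second_peaks[i]),
            cycle.foot_second,
            fs,
        )
        sbp, dbp = extract_labels(signals.abp, cycle)
        rows.append(
            dict(
                record_id=signals.record_id,
                cycle_index=i,
                ptt=ptt,
                hr=hr,
                ri=ri,
                st=st,
                ut=ut,
                sv=sv,
                dv=dv,
                sbp=sbp,
                dbp=dbp,
                flags=int(fiducials.flags[i]),
            )
        )
    columns = ["record_id", "cycle_index", *FEATURE_COLUMNS, "sbp", "dbp", "flags"]
    return pd.DataFrame(rows, columns=columns), counts
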