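"""Synthetic cardiovascular waveform simulator with known ground truth.

Generates synchronized ECG/PPG/ABP triplets in which every quantity the
downstream pipeline estimates — R-peak locations, the four PPG landmarks,
the maximum-slope point, pulse transit time, heart rate, and per-cycle
SBP/DBP — is known by construction.  Morphology is deliberately minimal:

* ECG: one narrow positive Gaussian R spike per beat plus small optional
  P and T bumps.  Only the R peak is consumed downstream, so only the R
  peak needs to be faithful.
* PPG: per beat, the sum of a systolic Gaussian lobe and a smaller,
  later reflected lobe, with the straight line through the beat
  endpoints subtracted so every pulse starts and ends exactly at its
  foot (amplitude 0).  The two-lobe construction yields all four
  landmarks (foot, systolic peak, dicrotic notch, second peak)
  analytically separable, and the reflected-lobe amplitude
  parameterizes the ground-truth reflection index.
* ABP: the same pulse shape rescaled per beat so the foot-to-foot
  extrema equal the configured DBP/SBP exactly (mmHg).

Baseline drift (a sinusoid below 0.1 Hz, i.e. inside the band the DFT
filter removes) and white noise are added only *after* ground truth is
extracted from the clean signals.  A single ``numpy.random.default_rng``
stream seeded from ``seed`` drives all randomness, so records are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pulsebp.records import (
    FLAG_NO_NOTCH,
    FLAG_OK,
    FiducialSet,
    SignalRecord,
)

__all__ = ["SimConfig", "SimRecord", "simulate_record", "planted_feature_table"]

# PPG beat template geometry, as fractions of the beat (foot-to-foot) span
_SYSTOLIC_CENTER = 0.18
_SYSTOLIC_WIDTH = 0.055
_REFLECTED_CENTER = 0.45
_REFLECTED_WIDTH = 0.11
# without a dicrotic notch: single broad descent, no interior minimum
_NONOTCH_CENTER = 0.28
_NONOTCH_WIDTH = 0.22
# parabolic bulge keeping the diastolic tail strictly decreasing into the foot
_TAIL_BULGE = 0.05

_LEAD_IN_S = 0.30  # flat margin before the first R peak


def _as_sequence(value, n_beats: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n_beats, arr.item())
    if arr.size != n_beats:
        raise ValueError(
            f"{name} has length {arr.size} but the record has {n_beats} beats"
        )
    return arr.astype(float)


@dataclass
class SimConfig:
    """Study conditions for one simulated record.

    ``heart_rate_bpm``, ``ptt_s``, ``sbp_mmhg`` and ``dbp_mmhg`` accept a
    scalar (constant across beats) or a per-beat sequence; all sequences
    must share one length, which then fixes the number of beats.  With
    scalars only, the beat count is whatever fits inside ``duration_s``.
    """

    duration_s: float = 20.0
    sampling_rate_hz: float = 125.0
    heart_rate_bpm: float | np.ndarray = 75.0
    ptt_s: float | np.ndarray = 0.25
    sbp_mmhg: float | np.ndarray = 120.0
    dbp_mmhg: float | np.ndarray = 80.0
    reflection_index: float = 0.5
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.05
    noise_sd: float = 0.0
    dicrotic_notch_present: bool = True
    ecg_pt_waves: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        hr = np.atleast_1d(np.asarray(self.heart_rate_bpm, dtype=float))
        if np.any(hr < 30) or np.any(hr > 220):
            raise ValueError("heart_rate_bpm must lie in [30, 220]")
        if np.any(np.atleast_1d(self.ptt_s) <= 0):
            raise ValueError("ptt_s must be positive")
        sbp = np.atleast_1d(np.asarray(self.sbp_mmhg, dtype=float))
        dbp = np.atleast_1d(np.asarray(self.dbp_mmhg, dtype=float))
        if sbp.size == dbp.size and np.any(sbp <= dbp):
            raise ValueError("sbp_mmhg must exceed dbp_mmhg element-wise")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be nonnegative")
        if not 0 < self.drift_freq_hz < 0.1:
            raise ValueError("drift_freq_hz must lie in (0, 0.1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.reflection_index < 1:
            raise ValueError("reflection_index must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        for key, value in payload.items():
            if isinstance(value, np.ndarray):
                payload[key] = value.tolist()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimRecord:
    """A simulated record plus its ground truth."""

    signals: SignalRecord
    truth_fiducials: FiducialSet
    truth_features: pd.DataFrame  # one row per beat: ptt, hr, ri, st, ut, sv, dv
    truth_labels: pd.DataFrame  # one row per beat: sbp, dbp
    config: SimConfig = field(repr=False, default=None)

    def write_truth_csv(self, features_path: str | Path, labels_path: str | Path) -> None:
        self.truth_features.to_csv(features_path, index=False)
        self.truth_labels.to_csv(labels_path, index=False)


def _ppg_beat_template(n: int, reflection_index: float, notch: bool) -> np.ndarray:
    """Sampled pulse over one beat span [foot, next foot).

    Two Gaussian lobes minus the chord through the (virtual) endpoints
    u = 0 and u = 1, plus a small parabolic bulge 4u(1-u) that keeps the
    diastolic tail strictly decreasing into the next foot.  The template
    is exactly 0 at u = 0 (the foot, the unique per-beat minimum) and
    strictly positive elsewhere on the sampled span.
    """
    u = np.arange(n) / n
    if notch:
        centers = ((_SYSTOLIC_CENTER, _SYSTOLIC_WIDTH, 1.0),
                   (_REFLECTED_CENTER, _REFLECTED_WIDTH, reflection_index))
    else:
        centers = ((_SYSTOLIC_CENTER, _SYSTOLIC_WIDTH, 1.0),
                   (_NONOTCH_CENTER, _NONOTCH_WIDTH, reflection_index))

    def lobes(v):
        return sum(a * np.exp(-((v - c) ** 2) / (2 * w**2)) for c, w, a in centers)

    g = lobes(u)
    g0, g1 = lobes(np.array([0.0]))[0], lobes(np.array([1.0]))[0]
    template = g - (g0 + u * (g1 - g0)) + _TAIL_BULGE * 4.0 * u * (1.0 - u)
    template[0] = 0.0
    return template


def _template_max_slope_offset(n: int, reflection_index: float, notch: bool) -> int:
    template = _ppg_beat_template(n, reflection_index, notch)
    return int(np.argmax(np.diff(template)))


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((t - center) ** 2) / (2 * sigma**2))


def simulate_record(config: SimConfig, record_id: str = "sim") -> SimRecord:
    """Generate one record with ground-truth fiducials, features and labels.

    The returned truth satisfies, in the clean (noise- and drift-free)
    case: the PPG maximum-slope point lags its R peak by the configured
    PTT to within one sample, and the ABP foot-to-foot extrema equal the
    configured SBP/DBP exactly.
    """
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    if n_samples < 2:
        raise ValueError("duration too short for the sampling rate")
    t = np.arange(n_samples) / fs

    # ---- beat schedule -------------------------------------------------
    seq_lengths = {
        np.atleast_1d(np.asarray(v)).size
        for v in (config.heart_rate_bpm, config.ptt_s, config.sbp_mmhg, config.dbp_mmhg)
        if np.atleast_1d(np.asarray(v)).size > 1
    }
    if len(seq_lengths) > 1:
        raise ValueError(f"inconsistent per-beat sequence lengths: {sorted(seq_lengths)}")
    if seq_lengths:
        n_beats = seq_lengths.pop()
        hr = _as_sequence(config.heart_rate_bpm, n_beats, "heart_rate_bpm")
        r_times = _LEAD_IN_S + np.concatenate([[0.0], np.cumsum(60.0 / hr[:-1])])
        if r_times[-1] + 60.0 / hr[-1] + 0.2 > config.duration_s:
            raise ValueError("duration_s too short for the configured beat sequences")
    else:
        hr_scalar = float(np.atleast_1d(config.heart_rate_bpm)[0])
        rr = 60.0 / hr_scalar
        n_beats = int(np.floor((config.duration_s - _LEAD_IN_S - 0.2) / rr))
        if n_beats < 1:
            raise ValueError("duration_s too short for a single beat")
        r_times = _LEAD_IN_S + rr * np.arange(n_beats)
        hr = np.full(n_beats, hr_scalar)

    ptt = _as_sequence(config.ptt_s, n_beats, "ptt_s")
    sbp = _as_sequence(config.sbp_mmhg, n_beats, "sbp_mmhg")
    dbp = _as_sequence(config.dbp_mmhg, n_beats, "dbp_mmhg")
    if np.any(sbp <= dbp):
        raise ValueError("sbp_mmhg must exceed dbp_mmhg element-wise")
    rr_s = 60.0 / hr

    r_idx = np.round(r_times * fs).astype(int)

    # ---- ECG -----------------------------------------------------------
    ecg = np.zeros(n_samples)
    r_sigma = 0.008  # ~1 sample at 125 Hz: a narrow spike, unambiguous max
    for k in range(n_beats):
        center = r_idx[k] / fs
        ecg += _gauss(t, center, r_sigma)
        if config.ecg_pt_waves:
            ecg += 0.12 * _gauss(t, center - 0.16, 0.025)  # P wave
            ecg += 0.20 * _gauss(t, center + 0.05 + 0.20 * rr_s[k], 0.04)  # T wave

    # ---- PPG: feet placed so max-slope lags R by PTT -------------------
    beat_len = np.round(rr_s * fs).astype(int)
    slope_offset = np.array(
        [
            _template_max_slope_offset(
                beat_len[k], config.reflection_index, config.dicrotic_notch_present
            )
            for k in range(n_beats)
        ]
    )
    foot_idx = r_idx + np.round(ptt * fs).astype(int) - slope_offset
    if foot_idx[0] < 0:
        raise ValueError("lead-in too short for the configured PTT")
    if foot_idx[-1] + beat_len[-1] >= n_samples:
        raise ValueError("record too short for the final beat")

    ppg = np.zeros(n_samples)
    abp = np.full(n_samples, dbp[0])
    for k in range(n_beats):
        start = foot_idx[k]
        end = foot_idx[k + 1] if k + 1 < n_beats else foot_idx[k] + beat_len[k]
        template = _ppg_beat_template(
            end - start, config.reflection_index, config.dicrotic_notch_present
        )
        ppg[start:end] = template
        pulse = template / template.max()
        abp[start:end] = dbp[k] + (sbp[k] - dbp[k]) * pulse
    # fill the record edges with virtual-beat context so the pulse train has
    # no flat segments (flats act as a boxcar envelope whose sub-cutoff DFT
    # leakage would turn into a baseline ripple after filtering)
    head = _ppg_beat_template(beat_len[0], config.reflection_index,
                              config.dicrotic_notch_present)
    lead = foot_idx[0]
    if lead > 0:
        tail_fill = head[-lead:] if lead <= len(head) else np.concatenate(
            [np.zeros(lead - len(head)), head]
        )
        ppg[:lead] = tail_fill
        pulse = head / head.max()
        abp_fill = dbp[0] + (sbp[0] - dbp[0]) * pulse
        abp[:lead] = abp_fill[-lead:] if lead <= len(head) else np.concatenate(
            [np.full(lead - len(head), dbp[0]), abp_fill]
        )
    last_end = foot_idx[-1] + beat_len[-1]
    trail = n_samples - last_end
    if trail > 0:
        tail_tpl = _ppg_beat_template(beat_len[-1], config.reflection_index,
                                      config.dicrotic_notch_present)
        reps = int(np.ceil(trail / len(tail_tpl)))
        fill = np.tile(tail_tpl, reps)[:trail]
        ppg[last_end:] = fill
        pulse = np.tile(tail_tpl / tail_tpl.max(), reps)[:trail]
        abp[last_end:] = dbp[-1] + (sbp[-1] - dbp[-1]) * pulse

    # ---- ground truth from the clean signals ---------------------------
    truth = _extract_truth(ppg, foot_idx, beat_len, r_idx, fs)
    feet_t, slopes_t, peaks_t, notches_t, second_t, flags_t = truth

    n_truth = len(feet_t)  # last beat has no following foot; it still has one
    fiducials = FiducialSet(
        r_peaks=r_idx,
        feet=feet_t,
        max_slopes=slopes_t,
        systolic_peaks=peaks_t,
        notches=notches_t,
        second_peaks=second_t,
        flags=flags_t,
    )

    features = _truth_features(ppg, fiducials, r_idx, fs)
    labels = pd.DataFrame(
        {
            "beat_index": np.arange(n_truth),
            "sbp": sbp[:n_truth],
            "dbp": dbp[:n_truth],
        }
    )

    # ---- drift and noise, after truth extraction -----------------------
    rng = np.random.default_rng(config.seed)
    if config.drift_amplitude > 0:
        drift = config.drift_amplitude * np.sin(2 * np.pi * config.drift_freq_hz * t)
        ecg = ecg + drift
        ppg = ppg + drift
    if config.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, config.noise_sd, n_samples)
        ppg = ppg + rng.normal(0.0, config.noise_sd, n_samples)
        abp = abp + rng.normal(0.0, config.noise_sd, n_samples)

    signals = SignalRecord(
        ecg=ecg, ppg=ppg, abp=abp, sampling_rate_hz=fs, record_id=record_id
    )
    return SimRecord(
        signals=signals,
        truth_fiducials=fiducials,
        truth_features=features,
        truth_labels=labels,
        config=config,
    )


def _extract_truth(ppg, foot_idx, beat_len, r_idx, fs):
    """Landmarks measured on the clean sampled PPG, one row per beat.

    Feet and systolic peaks are geometric (construction / argmax); the
    dicrotic notch and second peak are located with their definitional
    procedures (chord subtraction, second-difference minimum) applied to
    the clean waveform, since those procedures *are* what defines these
    landmarks.  A beat whose descent has no interior local minimum is
    flagged as notch-free.
    """
    from pulsebp.fiducials import detect_dicrotic_notch, detect_second_peak

    n_beats = len(foot_idx)
    feet, slopes, peaks, notches, seconds, flags = [], [], [], [], [], []
    for k in range(n_beats):
        start = int(foot_idx[k])
        end = int(foot_idx[k + 1]) if k + 1 < n_beats else int(foot_idx[k] + beat_len[k])
        seg = ppg[start:end]
        flag = FLAG_OK
        peak = start + int(np.argmax(seg))
        # a genuine notch requires an interior local minimum on the descent
        rel = seg[peak - start :]
        has_notch = bool(
            np.any((rel[1:-1] < rel[:-2]) & (rel[1:-1] <= rel[2:]))
        )
        if has_notch and end - peak >= 3:
            notch, degenerate = detect_dicrotic_notch(ppg, peak, end)
            if degenerate:
                flag |= FLAG_NO_NOTCH
            if notch < end - 2:
                second, _ = detect_second_peak(ppg, notch, end)
            else:
                second = notch
        else:
            flag |= FLAG_NO_NOTCH
            notch = peak
            second = peak
        slope = start + int(np.argmax(np.diff(ppg[start : peak + 1])))
        feet.append(start)
        slopes.append(slope)
        peaks.append(peak)
        notches.append(notch)
        seconds.append(second)
        flags.append(flag)
    return (
        np.array(feet),
        np.array(slopes),
        np.array(peaks),
        np.array(notches),
        np.array(seconds),
        np.array(flags),
    )


def _truth_features(ppg, fiducials: FiducialSet, r_idx, fs) -> pd.DataFrame:
    """Seven features per beat, computed on the min-max normalized clean PPG."""
    from pulsebp.features import compute_hr, compute_morphology, compute_ptt
    from pulsebp.preprocess import minmax_normalize

    norm = minmax_normalize(ppg)
    rows = []
    n = fiducials.n_beats
    for k in range(n):
        foot_next = fiducials.feet[k + 1] if k + 1 < n else None
        if k + 1 >= len(r_idx):
            break
        hr = compute_hr(r_idx[k], r_idx[k + 1], fs)
        ptt = compute_ptt(r_idx[k], fiducials.max_slopes[k], fs)
        if foot_next is None or fiducials.flags[k] != FLAG_OK:
            rows.append(
                dict(beat_index=k, ptt=ptt, hr=hr, ri=np.nan, st=np.nan, ut=np.nan,
                     sv=np.nan, dv=np.nan)
            )
            continue
        ri, st, ut, sv, dv = compute_morphology(
            norm,
            fiducials.feet[k],
            fiducials.systolic_peaks[k],
            fiducials.notches[k],
            fiducials.second_peaks[k],
            foot_next,
            fs,
        )
        rows.append(
            dict(beat_index=k, ptt=ptt, hr=hr, ri=ri, st=st, ut=ut, sv=sv, dv=dv)
        )
    return pd.DataFrame(rows)


def planted_feature_table(
    n_cycles: int = 2000,
    noise_sd_mmhg: float = 1.0,
    seed: int = 0,
    record_id: str = "planted",
) -> pd.DataFrame:
    """Feature-level benchmark with a known linear pressure law.

    Generates a per-cycle feature table in which systolic pressure is a
    planted linear function of pulse transit time,

        SBP = 200 - 120 * PTT + N(0, noise_sd_mmhg),   DBP = SBP - 40,

    with the remaining six features drawn independently from
    physiologically plausible ranges (they carry no signal).  With unit
    noise the best achievable test MAE is that of the half-normal mean,
    sigma * sqrt(2/pi) ~= 0.80 mmHg, which any well-behaved regressor
    should approach; a mis-specified one cannot.  PTT spans 0.15-0.40 s
    so SBP stays inside the (80, 180) mmHg survival band.
    """
    rng = np.random.default_rng(seed)
    ptt = rng.uniform(0.15, 0.40, n_cycles)
    sbp = 200.0 - 120.0 * ptt + rng.normal(0.0, noise_sd_mmhg, n_cycles)
    return pd.DataFrame(
        {
            "record_id": record_id,
            "cycle_index": np.arange(n_cycles),
            "ptt": ptt,
            "hr": rng.uniform(60.0, 100.0, n_cycles),
            "ri": rng.uniform(0.3, 0.7, n_cycles),
            "st": rng.uniform(0.20, 0.30, n_cycles),
            "ut": rng.uniform(0.10, 0.20, n_cycles),
            "sv": rng.uniform(0.08, 0.15, n_cycles),
            "dv": rng.uniform(0.05, 0.12, n_cycles),
            "sbp": sbp,
            "dbp": sbp - 40.0,
        }
    )
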