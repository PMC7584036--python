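"""Core containers: synchronized signal triplets and per-beat fiducial sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: column order used by every fiducial CSV written by this package
FIDUCIAL_COLUMNS = [
    "beat_index",
    "r_peak",
    "foot",
    "max_slope",
    "systolic_peak",
    "notch",
    "second_peak",
    "flags",
]


@dataclass
class SignalRecord:
    """Synchronized ECG/PPG/ABP sample arrays for one recording.

    ECG and PPG amplitudes are in arbitrary units; ABP is in mmHg so that
    systolic/diastolic labels can be read from it directly.
    """

    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    sampling_rate_hz: float
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        n = len(self.ecg)
        if n < 2 or len(self.ppg) != n or len(self.abp) != n:
            raise ValueError(
                "ecg, ppg and abp must have equal length >= 2 "
                f"(got {len(self.ecg)}, {len(self.ppg)}, {len(self.abp)})"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    def to_csv(self, path: str | Path) -> None:
        """Write columns (sample_index, ecg, ppg, abp)."""
        pd.DataFrame(
            {
                "sample_index": np.arange(len(self)),
                "ecg": self.ecg,
                "ppg": self.ppg,
                "abp": self.abp,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, sampling_rate_hz: float, record_id: str | None = None
    ) -> "SignalRecord":
        df = pd.read_csv(path)
        for col in ("ecg", "ppg", "abp"):
            if col not in df.columns:
                raise ValueError(f"signal CSV is missing column {col!r}")
        return cls(
            ecg=df["ecg"].to_numpy(),
            ppg=df["ppg"].to_numpy(),
            abp=df["abp"].to_numpy(),
            sampling_rate_hz=sampling_rate_hz,
            record_id=record_id or Path(path).stem,
        )


# beat-level quality flags
FLAG_OK = 0
FLAG_NO_NOTCH = 1  # dicrotic notch degenerate (flat chord residual)
FLAG_DEGENERATE_SECOND_PEAK = 2  # second-difference minimum not unique/flat


@dataclass
class FiducialSet:
    """Per-beat fiducial indices, aligned across arrays.

    Beat ``i`` pairs ``r_peaks[i]`` with the PPG pulse it launches; the pulse
    ends at the next beat's foot, so only beats with a successor carry the
    full landmark set and ``n_beats == len(feet) <= len(r_peaks) - 1``.
    ``flags`` holds a bitmask of degenerate-landmark markers per beat.
    """

    r_peaks: np.ndarray
    feet: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    max_slopes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    systolic_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    notches: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    second_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for name in (
            "r_peaks",
            "feet",
            "max_slopes",
            "systolic_peaks",
            "notches",
            "second_peaks",
            "flags",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        n = self.n_beats
        for name in ("max_slopes", "systolic_peaks", "notches", "second_peaks", "flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must align with feet (length {n})")
        if np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.feet)

    def validate_ordering(self) -> None:
        """Check foot <= max_slope <= systolic_peak <= notch <= second_peak."""
        for i in range(self.n_beats):
            seq = (
                self.feet[i],
                self.max_slopes[i],
                self.systolic_peaks[i],
                self.notches[i],
                self.second_peaks[i],
            )
            if any(a > b for a, b in zip(seq, seq[1:])):
                raise ValueError(f"fiducial ordering violated in beat {i}: {seq}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_index": np.arange(self.n_beats),
                "r_peak": self.r_peaks[: self.n_beats],
                "foot": self.feet,
                "max_slope": self.max_slopes,
                "systolic_peak": self.systolic_peaks,
                "notch": self.notches,
                "second_peak": self.second_peaks,
                "flags": self.flags,
            },
            columns=FIDUCIAL_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, r_peaks: np.ndarray | None = None) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(
            r_peaks=df["r_peak"].to_numpy() if r_peaks is None else r_peaks,
            feet=df["foot"].to_numpy(),
            max_slopes=df["max_slope"].to_numpy(),
            systolic_peaks=df["systolic_peak"].to_numpy(),
            notches=df["notch"].to_numpy(),
            second_peaks=df["second_peak"].to_numpy(),
            flags=df["flags"].to_numpy(),
        )
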