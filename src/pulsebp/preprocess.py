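"""Low-frequency artifact removal in the DFT domain and min-max scaling.

Baseline wander (respiration, electrode drift — everything below ~0.1 Hz)
is removed by zeroing the DFT bins whose frequency lies below the cutoff
and reconstructing with the inverse transform.  The cutoff bin is

    k_c = floor(N * f_c / f_s)

so with f_s = 125 Hz, f_c = 0.1 Hz and N = 4096 the first three bins
(including DC) are suppressed.  Zeroing the DC bin removes the signal
mean; that is intended baseline removal, not a side effect.  To keep the
reconstruction real-valued, the conjugate mirror bins N-k_c+1 .. N-1 are
zeroed together with bins 0 .. k_c-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FilterSpec", "derive_kc", "remove_low_freq", "minmax_normalize"]


def derive_kc(fs_hz: float, fc_hz: float, n_dft: int) -> int:
    """Cutoff bin index: floor(N * fc / fs).

    Parameters
    ----------
    fs_hz : sampling frequency in Hz.
    fc_hz : upper limit of the low-frequency artifact band in Hz; must lie
        below the Nyquist frequency.
    n_dft : DFT length.
    """
    if fs_hz <= 0 or fc_hz <= 0:
        raise ValueError("fs_hz and fc_hz must be positive")
    if n_dft < 2:
        raise ValueError("n_dft must be at least 2")
    if not fc_hz < fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    return int(np.floor(n_dft * fc_hz / fs_hz))


@dataclass
class FilterSpec:
    """Configuration of the DFT low-frequency filter.

    ``mode='full'`` (default) transforms the whole signal at once with the
    cutoff bin recomputed from the actual length — no block-edge
    discontinuities.  ``mode='blocks'`` processes non-overlapping
    ``dft_length_n``-sample blocks (the final short block is zero-padded,
    filtered, then truncated), matching a fixed N = 4096 transform length.
    """

    dft_length_n: int = 4096
    cutoff_fc_hz: float = 0.1
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.dft_length_n < 2:
            raise ValueError("dft_length_n must be at least 2")
        if self.cutoff_fc_hz <= 0:
            raise ValueError("cutoff_fc_hz must be positive")
        if self.mode not in ("full", "blocks"):
            raise ValueError("mode must be 'full' or 'blocks'")

    def cutoff_bin_kc(self, fs_hz: float, n: int | None = None) -> int:
        """k_c for a transform of length ``n`` (defaults to dft_length_n)."""
        return derive_kc(fs_hz, self.cutoff_fc_hz, self.dft_length_n if n is None else n)


def _filter_block(block: np.ndarray, kc: int) -> np.ndarray:
    if kc == 0:
        return block.copy()
    n = len(block)
    spectrum = np.fft.fft(block)
    spectrum[:kc] = 0.0
    spectrum[n - kc + 1 :] = 0.0  # conjugate mirrors of bins 1..kc-1
    restored = np.fft.ifft(spectrum)
    scale = max(np.max(np.abs(block)), 1.0)
    if np.max(np.abs(restored.imag)) > 1e-9 * scale:
        raise AssertionError("imaginary residue after symmetric bin zeroing")
    return restored.real


def remove_low_freq(
    signal: np.ndarray, fs_hz: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero all DFT bins below the cutoff frequency and reconstruct.

    Returns a real-valued sequence of the same length.  Bins at or above
    the cutoff are untouched; the DC bin is always inside the zeroed band,
    so the output is (block-wise) zero-mean.
    """
    spec = spec or FilterSpec()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("signal must be one-dimensional with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")

    if spec.mode == "full":
        kc = spec.cutoff_bin_kc(fs_hz, len(x))
        return _filter_block(x, kc)

    n_block = spec.dft_length_n
    kc = spec.cutoff_bin_kc(fs_hz)
    out = np.empty_like(x)
    for start in range(0, len(x), n_block):
        block = x[start : start + n_block]
        if len(block) < n_block:  # zero-pad the final short block
            padded = np.zeros(n_block)
            padded[: len(block)] = block
            out[start:] = _filter_block(padded, kc)[: len(block)]
        else:
            out[start : start + n_block] = _filter_block(block, kc)
    return out


def minmax_normalize(signal: np.ndarray) -> np.ndarray:
    """Scale amplitudes to [0, 1]: x' = (x - min) / (max - min).

    A constant signal has no amplitude information (a dead ECG/PPG channel)
    and is rejected rather than silently mapped to zeros.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValueError("signal is empty")
    lo, hi = np.min(x), np.max(x)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("signal contains non-finite samples")
    if hi <= lo:
        raise ValueError("constant signal cannot be min-max normalized")
    return (x - lo) / (hi - lo)
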