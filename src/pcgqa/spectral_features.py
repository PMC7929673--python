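"""Signal kurtosis and Welch band-energy ratios.

Heart sounds concentrate their energy between roughly 24 and 144 Hz, so the
share of Welch-PSD power falling into the low [24, 144) Hz, middle
[144, 200) Hz and high [200, 500] Hz bands relative to the whole 0-500 Hz
range separates clean recordings from broadband noise.  Kurtosis
E(x^4)/E(x^2)^2 measures non-Gaussianity: broadband noise sits near 3 while
pulse-like heart sounds are super-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateSignalError, PCGQAError, TooShortError

MAX_SEGMENTS = 8
BAND_LOW = (24.0, 144.0)
BAND_MID = (144.0, 200.0)
BAND_HIGH = (200.0, 500.0)


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density on a 0..fs/2 grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    segment_len: int


def kurtosis(x) -> float:
    """Fourth-moment ratio E(x^4)/E(x^2)^2 (no centering, no bias correction).

    Gaussian input gives 3 in expectation; a zero-mean sinusoid gives 1.5.
    The ratio is invariant to amplitude scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise TooShortError("kurtosis needs at least 4 samples")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("kurtosis undefined for a constant sequence")
    m2 = np.mean(x * x)
    m4 = np.mean(x ** 4)
    return float(m4 / (m2 * m2))


def welch_segment_length(n: int, max_segments: int = MAX_SEGMENTS) -> int:
    """Longest segment length giving at most ``max_segments`` half-overlapping segments."""
    return int(2 * n // (max_segments + 1))


def welch_psd(x, fs: float = 1000.0) -> PowerSpectrum:
    """Welch PSD with Hamming-windowed, 50%-overlapping segments.

    The signal is split into the longest segments that keep the segment count
    at or below 8 (L = floor(2N/9)); no zero padding is applied.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * (MAX_SEGMENTS + 1):
        raise TooShortError(f"need at least {2 * (MAX_SEGMENTS + 1)} samples, got {n}")
    nperseg = welch_segment_length(n)
    noverlap = nperseg // 2
    freqs, power = signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap, detrend=False
    )
    hop = nperseg - noverlap
    n_segments = (n - nperseg) // hop + 1
    return PowerSpectrum(freqs=freqs, power=power, n_segments=n_segments,
                         segment_len=nperseg)


def band_energy_ratio(ps: PowerSpectrum, band) -> float:
    """Share of PSD power in ``band`` relative to the full 0..fs/2 range.

    Band edges are half-open [lo, hi) so adjacent bands do not double-count a
    shared edge bin; a band ending at the Nyquist frequency includes it.
    """
    lo, hi = band
    top = ps.freqs[-1]
    df = ps.freqs[1] - ps.freqs[0]
    # the discrete grid's top bin may sit just below fs/2 for odd segment lengths
    if lo < 0 or hi > top + df or lo >= hi:
        raise PCGQAError(f"band {band} outside the spectrum's 0..{top:.6g} Hz range")
    mask = (ps.freqs >= lo) & ((ps.freqs <= hi) if hi >= top else (ps.freqs < hi))
    if not mask.any():
        raise PCGQAError(f"band {band} is empty after discretisation")
    total = ps.power.sum()
    if total == 0:
        raise DegenerateSignalError("zero total power")
    return float(ps.power[mask].sum() / total)


def band_energy_ratios(ps: PowerSpectrum) -> tuple[float, float, float]:
    """The (low, mid, high) band-energy ratio triple."""
    return (
        band_energy_ratio(ps, BAND_LOW),
        band_energy_ratio(ps, BAND_MID),
        band_energy_ratio(ps, BAND_HIGH),
    )
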