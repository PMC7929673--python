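"""Envelope statistics and envelope-autocorrelation features.

A clean heart-sound envelope is quasi-periodic: its normalised
autocorrelation shows a dominant peak at the cardiac period, its standard
deviation is large relative to a noisy recording's (both being z-normalised
upstream), and its sample entropy is low.  The peak search window 0.3-2.0 s
corresponds to cardiac periods between 200 and 30 beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .envelope import Envelope, ENVELOPE_TARGET_FS
from .errors import DegenerateSignalError, PCGQAError, TooShortError
from .spectral_features import kurtosis

MAX_LAG_S = 6.0
PEAK_LAG_WINDOW_S = (0.3, 2.0)


@dataclass
class AutocorrSeries:
    """Normalised autocorrelation r(l) of the envelope, lags 0..max_lag_s."""

    values: np.ndarray
    fs: float
    max_lag_s: float = MAX_LAG_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding length m and tolerance fraction.

    The tolerance is ``r_tol`` times the series' population standard
    deviation; m = 2 and r_tol = 0.2 are the customary defaults for
    physiological series.
    """

    m: int = 2
    r_tol: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise PCGQAError("embedding length m must be >= 1")
        if self.r_tol <= 0:
            raise PCGQAError("tolerance fraction must be positive")


def envelope_std(env: Envelope) -> float:
    """Population standard deviation of the envelope values."""
    if len(env.values) == 0:
        raise TooShortError("empty envelope")
    return float(np.std(env.values))


def sample_entropy_counts(series, m: int, r: float) -> tuple[int, int]:
    """Template-match counts (A, B) for sample entropy.

    B counts ordered pairs (i, j), i != j, of m-length templates whose
    Chebyshev distance is <= r; A counts the same for length m+1.  Both use
    the first N-m templates so the two counts are over the same index set.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise TooShortError(f"need at least m+2={m + 2} points, got {n}")

    def pair_count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        within = d <= r
        np.fill_diagonal(within, False)
        return int(within.sum())

    return pair_count(m + 1), pair_count(m)


def sample_entropy(series, params: SampEnParams = SampEnParams()) -> float:
    """SampEn(m, r_tol*std): -ln(A/B) with self-matches excluded.

    Returns 0 for a constant series (all templates match) and +inf when no
    template pair matches at either length (the documented sentinel).
    """
    x = np.asarray(series, dtype=float)
    r = params.r_tol * float(np.std(x))
    a, b = sample_entropy_counts(x, params.m, r)
    if b == 0 or a == 0:
        # no matching templates: entropy is undefined / unbounded
        return float("inf")
    return float(-np.log(a / b))


def normalized_autocorr(env: Envelope, max_lag_s: float = MAX_LAG_S) -> AutocorrSeries:
    """Autocorrelation of the mean-subtracted envelope, normalised to r(0)=1.

    Computed by FFT with >= 2N zero padding (no circular wrap-around); only
    nonnegative lags are kept and the series is truncated to ``max_lag_s``
    (or to the longest available lag for envelopes barely longer than it).
    The envelope mean is removed first: the raw envelope's large DC offset
    would otherwise pin r(l) near 1 at every lag.
    """
    e = env.values
    n = len(e)
    if n / env.fs_env < max_lag_s - 0.1:
        raise TooShortError(
            f"envelope covers {n / env.fs_env:.2f} s, need about {max_lag_s} s of lags"
        )
    e = e - e.mean()
    if np.ptp(e) == 0:
        raise DegenerateSignalError("constant envelope has no autocorrelation structure")
    nfft = sp_fft.next_fast_len(2 * n)
    spec = np.fft.rfft(e, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)
    n_lags = min(int(round(max_lag_s * env.fs_env)), n - 1)
    r = ac[: n_lags + 1] / ac[0]
    return AutocorrSeries(values=r, fs=env.fs_env, max_lag_s=n_lags / env.fs_env)


def max_autocorr_peak(
    ac: AutocorrSeries, lag_window_s: tuple[float, float] = PEAK_LAG_WINDOW_S
) -> float:
    """Maximum of r(l) over the cardiac-period lag window (ties: smallest lag)."""
    lo = int(round(lag_window_s[0] * ac.fs))
    hi = int(round(lag_window_s[1] * ac.fs))
    if hi >= len(ac.values) or lo < 0 or lo > hi:
        raise PCGQAError(
            f"lag window {lag_window_s} s outside available 0..{ac.max_lag_s} s lags"
        )
    return float(ac.values[lo : hi + 1].max())


def max_autocorr_peak_lag(
    ac: AutocorrSeries, lag_window_s: tuple[float, float] = PEAK_LAG_WINDOW_S
) -> tuple[float, float]:
    """(peak value, lag in seconds) of the autocorrelation maximum."""
    lo = int(round(lag_window_s[0] * ac.fs))
    hi = int(round(lag_window_s[1] * ac.fs))
    if hi >= len(ac.values) or lo < 0 or lo > hi:
        raise PCGQAError(
            f"lag window {lag_window_s} s outside available 0..{ac.max_lag_s} s lags"
        )
    window = ac.values[lo : hi + 1]
    k = int(np.argmax(window))
    return float(window[k]), (lo + k) / ac.fs


def lag_window_heart_rate_bpm(
    lag_window_s: tuple[float, float] = PEAK_LAG_WINDOW_S,
) -> tuple[float, float]:
    """Heart-rate bounds (max bpm, min bpm) implied by the peak-search lags.

    A 0.3 s minimum period corresponds to 200 bpm and a 2.0 s maximum to
    30 bpm.
    """
    return 60.0 / lag_window_s[0], 60.0 / lag_window_s[1]


def autocorr_kurtosis(ac: AutocorrSeries) -> float:
    """Kurtosis of the standardised autocorrelation sequence.

    r(l) is brought to zero mean and unit standard deviation first, so the
    statistic reflects the shape of the lag profile: a single sharp cardiac
    peak over a flat baseline is strongly super-Gaussian.
    """
    r = ac.values
    if np.ptp(r) == 0:
        raise DegenerateSignalError("constant autocorrelation sequence")
    z = (r - r.mean()) / r.std()
    return kurtosis(z)


def autocorr_sample_entropy(
    ac: AutocorrSeries,
    params: SampEnParams = SampEnParams(),
    target_fs: float = ENVELOPE_TARGET_FS,
) -> float:
    """Sample entropy of the autocorrelation after decimation to 30 Hz."""
    from fractions import Fraction

    frac = Fraction(target_fs / ac.fs).limit_denominator(10000)
    y = signal.resample_poly(ac.values, frac.numerator, frac.denominator)
    return sample_entropy(y, params)
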