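"""Cyclostationary analysis: cyclic autocorrelation, CFSD and periodicity degree.

A quasi-periodic heart-sound signal is (almost) cyclostationary: its
autocorrelation varies periodically with time at the cardiac cycle rate.  The
cyclic autocorrelation R_x(alpha, tau) -- the Fourier coefficient of that
periodic variation at cycle frequency alpha -- is therefore concentrated near
the heart rate and its harmonics for a clean recording, and flat for
stationary noise.  Integrating the magnitude of its Fourier transform over
spectral frequency yields the cycle frequency spectral density (CFSD)
gamma_x(alpha); the ratio of the CFSD's dominant peak to its median is the
degree of periodicity, the single most informative quality feature.

Estimator notes: with x real, the symmetric-lag time average is exactly even
in tau, so only tau >= 0 is computed (asymmetric-lag products with an
exp(-j*pi*alpha*tau/fs) phase compensation) and lags are mirrored before the
tau-DFT.  At alpha = 0 the estimator reduces to the ordinary biased
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal

from .errors import PCGQAError, TooShortError
from .preprocess import Recording

#: Cycle-frequency grid, Hz: 0.2..4.0 in 0.02 Hz steps.  Covers cardiac
#: fundamentals for 30..200 bpm plus low harmonics; alpha = 0 is excluded
#: because the stationary spectrum would trivially dominate the CFSD.
DEFAULT_ALPHA_GRID = np.round(np.arange(0.2, 4.0 + 1e-9, 0.02), 10)
DEFAULT_TAU_MAX_S = 0.5
DEFAULT_SEGMENT_S = 6.0


@dataclass
class CyclicSpectrumResult:
    """Cyclic autocorrelation matrix, CFSD and degree of periodicity."""

    alpha_grid: np.ndarray
    tau_grid_s: np.ndarray
    R: np.ndarray  # complex, shape (n_alpha, n_tau), tau >= 0
    gamma: np.ndarray  # CFSD over alpha_grid
    dp: float = field(default=float("nan"))


def cyclic_autocorrelation(
    rec: Recording,
    alpha_grid=DEFAULT_ALPHA_GRID,
    tau_max_s: float = DEFAULT_TAU_MAX_S,
    segment_s: float = DEFAULT_SEGMENT_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic autocorrelation R_x(alpha, tau) of the first ``segment_s`` seconds.

    For each cycle frequency alpha and integer lag tau >= 0:

        R(alpha, tau) = (1/M) sum_t x(t + tau) x(t) exp(-j 2 pi alpha (t + tau/2) / fs)

    which is the discretised symmetric-lag time average; division by the full
    segment length M makes the alpha = 0 column the conventional biased
    autocorrelation.  Returns ``(R, tau_grid_s)`` with R of shape
    ``(len(alpha_grid), n_tau)``.
    """
    alpha = np.asarray(alpha_grid, dtype=float)
    if alpha.size == 0:
        raise PCGQAError("alpha grid is empty")
    fs = rec.fs
    m = int(round(segment_s * fs))
    x = rec.samples[:m]
    m = len(x)
    n_tau = int(round(tau_max_s * fs)) + 1
    if m <= n_tau:
        raise TooShortError(
            f"segment of {m} samples too short for lags up to {n_tau - 1}"
        )

    taus = np.arange(n_tau)
    # lag products, zero-padded to common length M
    y = np.zeros((n_tau, m))
    for tau in taus:
        y[tau, : m - tau] = x[tau:] * x[: m - tau]

    # DFT of each lag-product row at the alpha grid, as one matrix product
    t = np.arange(m)
    basis = np.exp(-2j * np.pi * np.outer(t, alpha) / fs)  # (M, n_alpha)
    z = y @ basis  # (n_tau, n_alpha)
    phase = np.exp(-1j * np.pi * np.outer(taus, alpha) / fs)
    R = (z * phase).T / m
    return R, taus / fs


def cfsd(R: np.ndarray, tau_grid_s, fs: float = 1000.0) -> np.ndarray:
    """Cycle frequency spectral density gamma(alpha) from R_x(alpha, tau).

    A Hamming lag window is applied over the mirrored two-sided lags to
    control spectral leakage, the lag axis is Fourier-transformed to get the
    cyclic spectral density S_x(alpha, f), and |S| is integrated over f.
    """
    R = np.asarray(R)
    if not np.all(np.isfinite(R)):
        raise PCGQAError("R contains non-finite values")
    n_tau = R.shape[1]
    # mirror tau > 0 (R is even in tau for real input)
    two_sided = np.concatenate([R[:, :0:-1], R], axis=1)  # (n_alpha, 2*n_tau-1)
    n_full = two_sided.shape[1]
    lag_window = np.hamming(n_full)
    S = np.fft.fft(two_sided * lag_window, axis=1)
    df = fs / n_full
    return np.abs(S).sum(axis=1) * df


def degree_of_periodicity(gamma) -> float:
    """Peak-to-median ratio of the CFSD.

    1 for a flat CFSD, large when one cycle frequency dominates.  A zero
    median (degenerate all-zero CFSD) yields the +inf sentinel with a warning.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size == 0:
        raise PCGQAError("empty CFSD")
    med = float(np.median(gamma))
    if med == 0.0:
        warnings.warn("CFSD median is zero; degree of periodicity undefined (+inf)")
        return float("inf")
    return float(gamma.max() / med)


def cyclic_spectrum(
    rec: Recording,
    alpha_grid=DEFAULT_ALPHA_GRID,
    tau_max_s: float = DEFAULT_TAU_MAX_S,
    segment_s: float = DEFAULT_SEGMENT_S,
) -> CyclicSpectrumResult:
    """Full cyclostationary analysis of a preprocessed recording."""
    R, tau_grid_s = cyclic_autocorrelation(rec, alpha_grid, tau_max_s, segment_s)
    gamma = cfsd(R, tau_grid_s, fs=rec.fs)
    dp = degree_of_periodicity(gamma)
    return CyclicSpectrumResult(
        alpha_grid=np.asarray(alpha_grid, dtype=float),
        tau_grid_s=tau_grid_s,
        R=R,
        gamma=gamma,
        dp=dp,
    )
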