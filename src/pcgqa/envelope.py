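"""Frequency-smoothed envelope of a heart-sound signal.

A short-time Fourier transform is taken with a 30-sample rectangular window
hopping one sample at a time, and the STFT magnitude is averaged across
frequency bins at each frame.  Averaging in the frequency domain smooths the
envelope without an explicit time-domain moving average, which is why the
result tracks S1/S2 bursts closely while suppressing in-band oscillation.
For the entropy features the envelope is decimated to 30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import PCGQAError, TooShortError
from .preprocess import Recording

WINDOW_LEN_SAMPLES = 30
HOP_SAMPLES = 1
ENVELOPE_TARGET_FS = 30.0


@dataclass
class Envelope:
    """Nonnegative amplitude envelope e(m) with its sampling rate."""

    values: np.ndarray
    fs_env: float
    window_len_samples: int = WINDOW_LEN_SAMPLES
    hop_samples: int = HOP_SAMPLES
    n_bins: int = WINDOW_LEN_SAMPLES // 2 + 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_env


def frequency_smoothed_envelope(
    rec: Recording, window_len: int = WINDOW_LEN_SAMPLES
) -> Envelope:
    """Average the one-sided STFT magnitude over frequency at each frame.

    Frames are taken only where the full window fits (no padding), with a hop
    of one sample, so the envelope is ``len(x) - window_len + 1`` samples long
    at the recording's native rate; each value belongs to the window centre.
    """
    x = rec.samples
    if len(x) < window_len:
        raise TooShortError(
            f"need at least {window_len} samples for the envelope, got {len(x)}"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)
    mag = np.abs(np.fft.rfft(frames, axis=1))
    e = mag.mean(axis=1)
    return Envelope(values=e, fs_env=rec.fs, window_len_samples=window_len,
                    n_bins=mag.shape[1])


def downsample_envelope(env: Envelope, target_fs: float = ENVELOPE_TARGET_FS) -> Envelope:
    """Antialiased decimation of the envelope to ``target_fs`` Hz.

    Tiny negative ringing introduced by the antialiasing filter is clipped to
    zero so the envelope stays nonnegative.
    """
    if target_fs >= env.fs_env:
        raise PCGQAError(
            f"target rate {target_fs} Hz must be below envelope rate {env.fs_env} Hz"
        )
    frac = Fraction(target_fs / env.fs_env).limit_denominator(10000)
    y = signal.resample_poly(env.values, frac.numerator, frac.denominator)
    y = np.clip(y, 0.0, None)
    return Envelope(values=y, fs_env=target_fs,
                    window_len_samples=env.window_len_samples, n_bins=env.n_bins)
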