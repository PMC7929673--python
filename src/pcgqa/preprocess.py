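"""Recording container, preprocessing chain and label handling.

Every recording entering the feature extractors goes through the same chain:
rational-factor resampling to 1 kHz behind a polyphase antialiasing low-pass,
baseline-wander removal with a zero-phase 3rd-order Butterworth high-pass at
2 Hz, and z-normalisation to zero mean / unit (population) standard deviation.
Recordings shorter than 6 s are excluded from analysis, and multi-annotator
quality grades (1-5) are merged by rounding their average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import DegenerateSignalError, PCGQAError, UnsupportedRateError

TARGET_FS = 1000.0
HIGHPASS_ORDER = 3
HIGHPASS_CUTOFF_HZ = 2.0
MIN_DURATION_S = 6.0

UNACCEPTABLE = "unacceptable"
ACCEPTABLE = "acceptable"
GOOD = "good"
EXCELLENT = "excellent"


@dataclass
class Recording:
    """A single-channel heart-sound recording.

    Parameters
    ----------
    samples : ndarray
        Real-valued sample sequence (dimensionless after normalisation).
    fs : float
        Sampling rate in Hz.
    id : str
        Opaque identifier, e.g. the source file stem.
    """

    samples: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise PCGQAError("samples must be one-dimensional")
        if self.fs <= 0:
            raise PCGQAError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        """Duration in seconds (n_samples / fs)."""
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class QualityLabel:
    """Quality grade 1..5 and the derived class labels.

    Grades 1-3 ("very bad", "bad", "borderline") map to *unacceptable*;
    grade 4 is *good* and grade 5 *excellent*, both *acceptable* in the
    binary scheme.
    """

    grade: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.grade) <= 5) or int(self.grade) != self.grade:
            raise PCGQAError(f"grade must be an integer in 1..5, got {self.grade!r}")
        object.__setattr__(self, "grade", int(self.grade))

    @property
    def binary_class(self) -> str:
        return UNACCEPTABLE if self.grade <= 3 else ACCEPTABLE

    @property
    def triple_class(self) -> str:
        if self.grade <= 3:
            return UNACCEPTABLE
        return GOOD if self.grade == 4 else EXCELLENT


def _resample_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Rational-factor polyphase resampling with antialiasing low-pass."""
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    if frac == 1:
        return x
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def preprocess_recording(rec: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Resample to 1 kHz, high-pass at 2 Hz (zero phase) and z-normalise.

    Raises
    ------
    UnsupportedRateError
        If ``rec.fs`` is below ``target_fs``.
    DegenerateSignalError
        If the input is constant, all-zero or non-finite.
    """
    x = rec.samples
    if rec.fs < target_fs:
        raise UnsupportedRateError(
            f"sampling rate {rec.fs} Hz below supported minimum {target_fs} Hz"
        )
    if not np.all(np.isfinite(x)):
        raise DegenerateSignalError("samples contain non-finite values")
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateSignalError("constant or empty signal")

    y = _resample_to(x, rec.fs, target_fs)
    sos = signal.butter(
        HIGHPASS_ORDER, HIGHPASS_CUTOFF_HZ, btype="highpass", fs=target_fs, output="sos"
    )
    y = signal.sosfiltfilt(sos, y)
    sd = y.std()
    if sd == 0:
        raise DegenerateSignalError("signal is constant after filtering")
    y = (y - y.mean()) / sd
    return Recording(samples=y, fs=target_fs, id=rec.id)


def exclude_short(recs, min_duration_s: float = MIN_DURATION_S):
    """Drop recordings shorter than ``min_duration_s`` seconds, keeping order."""
    return [r for r in recs if r.duration_s >= min_duration_s]


def merge_annotations(grades) -> QualityLabel:
    """Merge several annotators' grades by rounding their average.

    Half-values round away from zero, so a mean of 3.5 becomes grade 4.
    """
    grades = list(grades)
    if not grades:
        raise PCGQAError("at least one grade required")
    for g in grades:
        if not (1 <= g <= 5) or int(g) != g:
            raise PCGQAError(f"grades must be integers in 1..5, got {g!r}")
    mean = float(np.mean(grades))
    return QualityLabel(grade=int(np.floor(mean + 0.5)))


def load_wav(path) -> Recording:
    """Load a WAV file into a float :class:`Recording`.

    Integer PCM is scaled to [-1, 1); of a multi-channel file only the first
    channel is kept (with a warning).
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        warnings.warn(f"{path.name}: multi-channel WAV, taking first channel")
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    return Recording(samples=data, fs=float(fs), id=path.stem)


def write_wav(path, rec: Recording) -> None:
    """Write a recording as 32-bit float WAV."""
    wavfile.write(Path(path), int(rec.fs), rec.samples.astype(np.float32))


def read_annotations(path) -> dict[str, QualityLabel]:
    """Read a delimited annotation table (columns id, annotator, grade).

    Returns one merged :class:`QualityLabel` per recording id.
    """
    df = pd.read_csv(path)
    required = {"id", "annotator", "grade"}
    if not required.issubset(df.columns):
        raise PCGQAError(f"annotation table must have columns {sorted(required)}")
    return {
        str(rid): merge_annotations(group["grade"].tolist())
        for rid, group in df.groupby("id", sort=False)
    }
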