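"""Feature-vector assembly, SVM classification, metrics and feature selection.

The ten quality features, in their canonical index order (1-10):

1. kurtosis_signal          -- fourth-moment ratio of the preprocessed signal
2. energy_ratio_low         -- Welch-PSD share in [24, 144) Hz
3. energy_ratio_mid         -- Welch-PSD share in [144, 200) Hz
4. energy_ratio_high        -- Welch-PSD share in [200, 500] Hz
5. envelope_std             -- std of the frequency-smoothed envelope
6. envelope_sampen          -- SampEn of the 30 Hz envelope
7. autocorr_kurtosis        -- kurtosis of the envelope autocorrelation
8. autocorr_max_peak        -- max autocorrelation peak, lags 0.3..2.0 s
9. autocorr_sampen          -- SampEn of the 30 Hz autocorrelation
10. degree_of_periodicity   -- CFSD peak-to-median ratio

Binary quality classification (unacceptable vs acceptable) uses a single
RBF-kernel SVM; the triple scheme (unacceptable / good / excellent) trains
the three pairwise SVMs of a one-vs-one design and decodes their votes,
falling back to "unacceptable" when all three classes receive one vote each.
Performance is summarised by per-class rates, accuracy, and the unweighted
"overall rate" that is fair under class imbalance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cyclostationary import cyclic_spectrum
from .envelope import downsample_envelope, frequency_smoothed_envelope
from .errors import PCGQAError
from .periodicity_features import (
    SampEnParams,
    autocorr_kurtosis,
    autocorr_sample_entropy,
    envelope_std,
    max_autocorr_peak,
    normalized_autocorr,
    sample_entropy,
)
from .preprocess import ACCEPTABLE, EXCELLENT, GOOD, Recording, UNACCEPTABLE
from .spectral_features import band_energy_ratios, kurtosis, welch_psd

FEATURE_NAMES: tuple[str, ...] = (
    "kurtosis_signal",
    "energy_ratio_low",
    "energy_ratio_mid",
    "energy_ratio_high",
    "envelope_std",
    "envelope_sampen",
    "autocorr_kurtosis",
    "autocorr_max_peak",
    "autocorr_sampen",
    "degree_of_periodicity",
)

BINARY_CLASSES = (UNACCEPTABLE, ACCEPTABLE)
TRIPLE_CLASSES = (UNACCEPTABLE, GOOD, EXCELLENT)
_PAIRS = ((UNACCEPTABLE, GOOD), (UNACCEPTABLE, EXCELLENT), (GOOD, EXCELLENT))


@dataclass(frozen=True)
class FeatureVector:
    """The ten quality features of one recording, in index order 1-10."""

    kurtosis_signal: float
    energy_ratio_low: float
    energy_ratio_mid: float
    energy_ratio_high: float
    envelope_std: float
    envelope_sampen: float
    autocorr_kurtosis: float
    autocorr_max_peak: float
    autocorr_sampen: float
    degree_of_periodicity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def extract_features(rec: Recording, sampen_params: SampEnParams = SampEnParams()) -> FeatureVector:
    """Compute all ten features of a preprocessed recording (deterministic)."""
    x = rec.samples
    f1 = kurtosis(x)
    ps = welch_psd(x, fs=rec.fs)
    f2, f3, f4 = band_energy_ratios(ps)
    env = frequency_smoothed_envelope(rec)
    f5 = envelope_std(env)
    env30 = downsample_envelope(env)
    f6 = sample_entropy(env30.values, sampen_params)
    ac = normalized_autocorr(env)
    f7 = autocorr_kurtosis(ac)
    f8 = max_autocorr_peak(ac)
    f9 = autocorr_sample_entropy(ac, sampen_params)
    f10 = cyclic_spectrum(rec).dp
    return FeatureVector(f1, f2, f3, f4, f5, f6, f7, f8, f9, f10)


def extract_feature_table(cohort, preprocess: bool = True) -> pd.DataFrame:
    """Feature table for ``(Recording, QualityLabel)`` pairs (or bare recordings).

    Columns: id, the ten features, and (when labels are present) grade.
    Recordings are preprocessed first unless ``preprocess=False``.
    """
    from .preprocess import preprocess_recording

    rows = []
    for item in cohort:
        rec, label = item if isinstance(item, tuple) else (item, None)
        if preprocess:
            rec = preprocess_recording(rec)
        fv = extract_features(rec)
        row = {"id": rec.id, **dict(zip(FEATURE_NAMES, fv.as_array()))}
        if label is not None:
            row["grade"] = label.grade
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _make_svm(C: float = 1.0, gamma="scale") -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(C=C, kernel="rbf", gamma=gamma)),
    ])


def train_binary(features, labels, C: float = 1.0, gamma="scale") -> Pipeline:
    """Train the binary quality SVM (features standardised inside the pipeline)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise PCGQAError("binary training needs examples of both classes")
    model = _make_svm(C, gamma)
    model.fit(X, y)
    return model


class TripleSVM:
    """One-vs-one triple classifier: three pairwise SVMs plus vote decoding."""

    def __init__(self, C: float = 1.0, gamma="scale"):
        self.C = C
        self.gamma = gamma
        self.models_: dict[tuple[str, str], Pipeline] = {}

    def fit(self, X, y) -> "TripleSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        present = set(np.unique(y))
        missing = set(TRIPLE_CLASSES) - present
        if missing:
            raise PCGQAError(f"triple training set lacks class(es): {sorted(missing)}")
        for pair in _PAIRS:
            mask = np.isin(y, pair)
            model = _make_svm(self.C, self.gamma)
            model.fit(X[mask], y[mask])
            self.models_[pair] = model
        return self

    def votes(self, X) -> list[tuple[str, str, str]]:
        X = np.asarray(X, dtype=float)
        per_pair = [self.models_[pair].predict(X) for pair in _PAIRS]
        return list(zip(*per_pair))

    def predict(self, X) -> np.ndarray:
        return np.array([decode_votes(v) for v in self.votes(X)])


def train_triple(features, labels, C: float = 1.0, gamma="scale") -> TripleSVM:
    """Train the one-vs-one triple scheme on grade classes u/g/e."""
    return TripleSVM(C, gamma).fit(features, labels)


def decode_votes(votes) -> str:
    """Combine the three pairwise votes into a final class.

    Majority (>= 2 votes) wins; the three-way 1-1-1 ambiguity resolves to
    "unacceptable" -- the safe choice for a quality gate.
    """
    votes = list(votes)
    if len(votes) != 3:
        raise PCGQAError(f"expected exactly 3 pairwise votes, got {len(votes)}")
    cls, count = Counter(votes).most_common(1)[0]
    return cls if count >= 2 else UNACCEPTABLE


# ---------------------------------------------------------------------------
# confusion matrices and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrixBinary:
    """Counts N_xy = (true class x, predicted y); u = unacceptable, a = acceptable."""

    n_uu: int
    n_ua: int
    n_au: int
    n_aa: int

    @property
    def total(self) -> int:
        return self.n_uu + self.n_ua + self.n_au + self.n_aa

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrixBinary":
        m = confusion_matrix(y_true, y_pred, labels=list(BINARY_CLASSES))
        return cls(int(m[0, 0]), int(m[0, 1]), int(m[1, 0]), int(m[1, 1]))


@dataclass(frozen=True)
class ConfusionMatrixTriple:
    """Counts N_xy over u/g/e true (rows) and predicted (columns) classes."""

    n_uu: int
    n_ug: int
    n_ue: int
    n_gu: int
    n_gg: int
    n_ge: int
    n_eu: int
    n_eg: int
    n_ee: int

    @property
    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrixTriple":
        m = confusion_matrix(y_true, y_pred, labels=list(TRIPLE_CLASSES))
        return cls(*(int(v) for v in m.ravel()))


def _rate(num: float, den: float) -> float:
    """Percentage num/den, NaN sentinel on a zero denominator."""
    return float("nan") if den == 0 else 100.0 * num / den


def evaluate_binary(cm: ConfusionMatrixBinary) -> dict[str, float]:
    """Binary metrics in percent: SP_b_u, TP_b_a, TN_b_u, SE_b_a, ACC_b, OR_b.

    The overall rate OR_b is the unweighted mean of the first four rates,
    fair under class imbalance.
    """
    sp = _rate(cm.n_uu, cm.n_uu + cm.n_ua)
    tp = _rate(cm.n_aa, cm.n_au + cm.n_aa)
    tn = _rate(cm.n_uu, cm.n_uu + cm.n_au)
    se = _rate(cm.n_aa, cm.n_aa + cm.n_ua)
    acc = _rate(cm.n_uu + cm.n_aa, cm.total)
    return {
        "SP_b_u": sp,
        "TP_b_a": tp,
        "TN_b_u": tn,
        "SE_b_a": se,
        "ACC_b": acc,
        "OR_b": float(np.mean([sp, tp, tn, se])),
    }


def evaluate_triple(cm: ConfusionMatrixTriple) -> dict[str, float]:
    """Triple metrics in percent: per-class SE and PP, ACC_t, OR_t (mean of six)."""
    se_u = _rate(cm.n_uu, cm.n_uu + cm.n_ug + cm.n_ue)
    se_g = _rate(cm.n_gg, cm.n_gu + cm.n_gg + cm.n_ge)
    se_e = _rate(cm.n_ee, cm.n_eu + cm.n_eg + cm.n_ee)
    pp_u = _rate(cm.n_uu, cm.n_uu + cm.n_gu + cm.n_eu)
    pp_g = _rate(cm.n_gg, cm.n_ug + cm.n_gg + cm.n_eg)
    pp_e = _rate(cm.n_ee, cm.n_ue + cm.n_ge + cm.n_ee)
    acc = _rate(cm.n_uu + cm.n_gg + cm.n_ee, cm.total)
    return {
        "SE_t_u": se_u,
        "SE_t_g": se_g,
        "SE_t_e": se_e,
        "PP_t_u": pp_u,
        "PP_t_g": pp_g,
        "PP_t_e": pp_e,
        "ACC_t": acc,
        "OR_t": float(np.mean([se_u, se_g, se_e, pp_u, pp_g, pp_e])),
    }


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def _fit_eval_once(X, y, train_idx, test_idx, scheme: str, C: float, gamma):
    if scheme == "binary":
        model = train_binary(X[train_idx], y[train_idx], C, gamma)
        cm = ConfusionMatrixBinary.from_predictions(y[test_idx], model.predict(X[test_idx]))
        return evaluate_binary(cm)
    model = train_triple(X[train_idx], y[train_idx], C, gamma)
    cm = ConfusionMatrixTriple.from_predictions(y[test_idx], model.predict(X[test_idx]))
    return evaluate_triple(cm)


def split_and_repeat(
    features,
    labels,
    train_fraction: float,
    repeats: int = 100,
    seed: int = 0,
    scheme: str = "binary",
    C: float = 1.0,
    gamma="scale",
) -> dict[str, tuple[float, float]]:
    """Repeated random non-overlapping train/test splits (no stratification).

    Each repeat draws a fresh permutation split with ``train_fraction`` of the
    recordings for training, evaluates on the rest, and the per-repeat metrics
    are aggregated to (mean, std).  A split missing a class in the training
    set is redrawn with a logged warning.
    """
    if not (0.0 < train_fraction < 1.0):
        raise PCGQAError("train_fraction must lie strictly between 0 and 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise PCGQAError("split leaves too few recordings on one side")
    required = set(BINARY_CLASSES if scheme == "binary" else TRIPLE_CLASSES)
    rng = np.random.default_rng(seed)
    per_metric: dict[str, list[float]] = {}
    for _ in range(repeats):
        for _attempt in range(100):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if required.issubset(set(y[train_idx])):
                break
            warnings.warn("degenerate split (missing class in training set); resampling")
        else:
            raise PCGQAError("could not draw a split containing every class")
        metrics = _fit_eval_once(X, y, train_idx, test_idx, scheme, C, gamma)
        for k, v in metrics.items():
            per_metric.setdefault(k, []).append(v)
    return {
        k: (float(np.mean(v)), float(np.std(v))) for k, v in per_metric.items()
    }


@dataclass
class SFSResult:
    """Greedy forward-selection trace: 1-based feature indices and scores (%)."""

    order: list[int]
    scores: list[float]


def _cv_overall_rate(X, y, folds: int, seed: int, C: float, gamma) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rates = []
    for train_idx, test_idx in skf.split(X, y):
        rates.append(_fit_eval_once(X, y, train_idx, test_idx, "binary", C, gamma)["OR_b"])
    return float(np.mean(rates))


def sequential_forward_selection(
    features,
    labels,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
) -> SFSResult:
    """Greedy add-one-feature-at-a-time search on binary classification.

    At each step the feature whose addition maximises the ``folds``-fold
    cross-validated overall rate is appended (ties broken by lowest index);
    the full order and score trace are returned.  Indices are 1-based,
    matching the canonical feature numbering.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_features = X.shape[1]
    remaining = list(range(n_features))
    order: list[int] = []
    scores: list[float] = []
    selected: list[int] = []
    while remaining:
        best_score, best_j = -np.inf, None
        for j in remaining:
            score = _cv_overall_rate(X[:, selected + [j]], y, folds, seed, C, gamma)
            if score > best_score + 1e-12:
                best_score, best_j = score, j
        selected.append(best_j)
        remaining.remove(best_j)
        order.append(best_j + 1)
        scores.append(best_score)
    return SFSResult(order=order, scores=scores)
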