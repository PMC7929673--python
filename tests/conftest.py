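import numpy as np
import pytest
from hypothesis import settings

import pcgqa as q

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def grade_to_binary(grades):
    return np.where(np.asarray(grades) <= 3, "unacceptable", "acceptable")


def grade_to_triple(grades):
    g = np.asarray(grades)
    return np.where(g <= 3, "unacceptable", np.where(g == 4, "good", "excellent"))


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature table for a 10-per-grade synthetic cohort (seed 42)."""
    cohort = q.generate_cohort(10, seed=42)
    return q.extract_feature_table(cohort)


@pytest.fixture(scope="session")
def cohort_features_200():
    """Feature table for the 200-per-grade balanced cohort (seed 1234)."""
    cohort = q.generate_cohort(200, seed=1234)
    return q.extract_feature_table(cohort)


@pytest.fixture
def clean_recording():
    """A preprocessed near-noise-free synthetic recording at 75 bpm."""
    rec, _ = q.generate(q.params_for_grade(5, seed=11, heart_rate_bpm=75.0,
                                           hrv_frac=0.0))
    return q.preprocess_recording(rec)


@pytest.fixture
def noisy_recording():
    """A preprocessed very-low-quality synthetic recording."""
    rec, _ = q.generate(q.params_for_grade(1, seed=11, heart_rate_bpm=75.0))
    return q.preprocess_recording(rec)
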