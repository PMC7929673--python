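"""Feature assembly, SVM schemes, metrics and forward selection."""

import json
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcgqa as q
from pcgqa import Recording
from pcgqa.classify_evaluate import (
    ConfusionMatrixBinary,
    ConfusionMatrixTriple,
    TRIPLE_CLASSES,
)
from pcgqa.errors import PCGQAError


class TestExtractFeatures:
    def test_clean_recording_is_periodic(self, clean_recording):
        fv = q.extract_features(clean_recording)
        assert fv.autocorr_max_peak > 0.5
        assert fv.degree_of_periodicity > 3

    def test_white_noise_profile(self):
        rng = np.random.default_rng(0)
        rec = q.preprocess_recording(Recording(rng.standard_normal(32000), fs=2000))
        fv = q.extract_features(rec)
        assert fv.kurtosis_signal == pytest.approx(3.0, abs=0.2)
        assert fv.autocorr_max_peak < 0.3

    def test_deterministic(self, clean_recording):
        fv1 = q.extract_features(clean_recording)
        fv2 = q.extract_features(clean_recording)
        np.testing.assert_array_equal(fv1.as_array(), fv2.as_array())

    def test_bounded_features(self, small_cohort_features):
        df = small_cohort_features
        for col in ("energy_ratio_low", "energy_ratio_mid", "energy_ratio_high"):
            assert df[col].between(0, 1).all()
        assert df["autocorr_max_peak"].between(-1, 1).all()
        assert (df["degree_of_periodicity"] >= 1).all()
        assert np.isfinite(df[list(q.FEATURE_NAMES)].to_numpy()).all()

    def test_invariant_to_recording_scale(self):
        rec, _ = q.generate(q.params_for_grade(4, seed=3, duration_s=8.0))
        scaled = Recording(37.0 * rec.samples, fs=rec.fs)
        f1 = q.extract_features(q.preprocess_recording(rec)).as_array()
        f2 = q.extract_features(q.preprocess_recording(scaled)).as_array()
        np.testing.assert_allclose(f1, f2, rtol=1e-9)


def separable_features(n=40, n_features=3, seed=0, informative=0, margin=5.0):
    """Two classes separated along one feature; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n, n_features))
    y = np.array(["unacceptable"] * n + ["acceptable"] * n)
    X[:n, informative] -= margin
    X[n:, informative] += margin
    return X, y


class TestBinarySVM:
    def test_separable_training_accuracy(self):
        X, y = separable_features()
        model = q.train_binary(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_label_swap_symmetry(self):
        X, y = separable_features()
        swapped = np.where(y == "acceptable", "unacceptable", "acceptable")
        m1 = q.train_binary(X, y)
        m2 = q.train_binary(X, swapped)
        p1, p2 = m1.predict(X), m2.predict(X)
        assert np.all((p1 == "acceptable") == (p2 == "unacceptable"))

    def test_scaling_absorbed_by_standardisation(self):
        X, y = separable_features()
        m1 = q.train_binary(X, y)
        m2 = q.train_binary(X * 1000.0, y)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X * 1000.0))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(PCGQAError):
            q.train_binary(X, ["acceptable"] * 10)


class TestTripleSVM:
    def make_triple(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((3 * n, 2))
        X[:n, 0] -= 4.0
        X[2 * n:, 0] += 4.0
        y = np.array(["unacceptable"] * n + ["good"] * n + ["excellent"] * n)
        return X, y

    def test_pairwise_models_and_prediction(self):
        X, y = self.make_triple()
        model = q.train_triple(X, y)
        assert len(model.models_) == 3
        assert (model.predict(X) == y).mean() > 0.95

    def test_missing_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        y = ["unacceptable"] * 10 + ["good"] * 10
        with pytest.raises(PCGQAError):
            q.train_triple(X, y)


class TestDecodeVotes:
    @pytest.mark.parametrize("votes, expected", [
        (("unacceptable", "unacceptable", "good"), "unacceptable"),
        (("unacceptable", "excellent", "good"), "unacceptable"),
        (("good", "good", "excellent"), "good"),
        (("excellent", "excellent", "excellent"), "excellent"),
    ])
    def test_decoding_rule(self, votes, expected):
        assert q.decode_votes(votes) == expected

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(PCGQAError):
            q.decode_votes(("good", "good"))

    @given(st.tuples(*[st.sampled_from(TRIPLE_CLASSES)] * 3))
    def test_result_in_votes_or_ambiguity_fallback(self, votes):
        out = q.decode_votes(votes)
        if len(set(votes)) == 3:
            assert out == "unacceptable"
        else:
            assert out in votes


class TestBinaryMetrics:
    def test_worked_example(self):
        cm = ConfusionMatrixBinary(n_uu=90, n_ua=10, n_au=20, n_aa=80)
        m = q.evaluate_binary(cm)
        # independent arithmetic with exact fractions
        assert m["SP_b_u"] == pytest.approx(100 * Fraction(90, 100), abs=1e-12)
        assert m["TP_b_a"] == pytest.approx(100 * Fraction(80, 100), abs=1e-12)
        assert m["TN_b_u"] == pytest.approx(float(100 * Fraction(90, 110)), abs=1e-12)
        assert m["SE_b_a"] == pytest.approx(float(100 * Fraction(80, 90)), abs=1e-12)
        assert m["ACC_b"] == pytest.approx(85.0, abs=1e-12)
        or_ref = (Fraction(90, 100) + Fraction(80, 100) + Fraction(90, 110)
                  + Fraction(80, 90)) / 4
        assert m["OR_b"] == pytest.approx(float(100 * or_ref), abs=1e-12)
        assert round(m["TN_b_u"], 1) == 81.8
        assert round(m["OR_b"], 1) == 85.2

    def test_perfect_diagonal(self):
        m = q.evaluate_binary(ConfusionMatrixBinary(50, 0, 0, 70))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_all_unacceptable_predictions(self):
        m = q.evaluate_binary(ConfusionMatrixBinary(50, 0, 50, 0))
        assert m["ACC_b"] == pytest.approx(50.0)
        assert m["TP_b_a"] == pytest.approx(0.0)

    def test_zero_denominator_sentinel(self):
        m = q.evaluate_binary(ConfusionMatrixBinary(0, 0, 10, 10))
        assert np.isnan(m["SP_b_u"])

    def test_total_matches_test_set_size(self):
        cm = ConfusionMatrixBinary.from_predictions(
            ["unacceptable", "acceptable", "acceptable"],
            ["unacceptable", "unacceptable", "acceptable"])
        assert cm.total == 3

    def test_serialisation_roundtrip(self):
        cm = ConfusionMatrixBinary(90, 10, 20, 80)
        blob = json.dumps(cm.__dict__)
        cm2 = ConfusionMatrixBinary(**json.loads(blob))
        m1, m2 = q.evaluate_binary(cm), q.evaluate_binary(cm2)
        assert all(abs(m1[k] - m2[k]) < 1e-12 for k in m1)


class TestTripleMetrics:
    def test_identity_confusion(self):
        m = q.evaluate_triple(ConfusionMatrixTriple(10, 0, 0, 0, 20, 0, 0, 0, 30))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_uniform_confusion(self):
        m = q.evaluate_triple(ConfusionMatrixTriple(*[7] * 9))
        third = 100.0 / 3.0
        for k in ("SE_t_u", "SE_t_g", "SE_t_e", "PP_t_u", "PP_t_g", "PP_t_e",
                  "ACC_t", "OR_t"):
            assert m[k] == pytest.approx(third, abs=1e-12)

    def test_hand_built_cross_check(self):
        cm = ConfusionMatrixTriple(n_uu=50, n_ug=6, n_ue=4, n_gu=8, n_gg=30,
                                   n_ge=12, n_eu=2, n_eg=10, n_ee=28)
        m = q.evaluate_triple(cm)
        ref = {
            "SE_t_u": Fraction(50, 60), "SE_t_g": Fraction(30, 50),
            "SE_t_e": Fraction(28, 40), "PP_t_u": Fraction(50, 60),
            "PP_t_g": Fraction(30, 46), "PP_t_e": Fraction(28, 44),
            "ACC_t": Fraction(108, 150),
        }
        for k, v in ref.items():
            assert m[k] == pytest.approx(float(100 * v), abs=1e-12)
        or_ref = sum(ref[k] for k in ("SE_t_u", "SE_t_g", "SE_t_e", "PP_t_u",
                                      "PP_t_g", "PP_t_e")) / 6
        assert m["OR_t"] == pytest.approx(float(100 * or_ref), abs=1e-12)
        assert cm.total == 150


class TestSplitAndRepeat:
    def test_aggregates_mean_and_std(self):
        X, y = separable_features(n=30)
        out = q.split_and_repeat(X, y, train_fraction=0.5, repeats=5, seed=0)
        assert set(out) == {"SP_b_u", "TP_b_a", "TN_b_u", "SE_b_a", "ACC_b", "OR_b"}
        mean, std = out["ACC_b"]
        assert mean >= 95.0
        assert 0.0 <= std <= 5.0

    def test_reproducible_given_seed(self):
        X, y = separable_features(n=20, seed=1)
        a = q.split_and_repeat(X, y, 0.6, repeats=3, seed=5)
        b = q.split_and_repeat(X, y, 0.6, repeats=3, seed=5)
        assert a == b

    def test_degenerate_split_resampled(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 2))
        y = np.array(["acceptable"] * 18 + ["unacceptable"] * 2)
        X[y == "unacceptable"] += 5
        out = q.split_and_repeat(X, y, train_fraction=0.5, repeats=10, seed=0)
        assert np.isfinite(out["ACC_b"][0])

    def test_invalid_fraction(self):
        X, y = separable_features(n=10)
        with pytest.raises(PCGQAError):
            q.split_and_repeat(X, y, train_fraction=1.5, repeats=1)


class TestSequentialForwardSelection:
    def test_informative_feature_selected_first(self):
        X, y = separable_features(n=30, n_features=3, informative=2, seed=4)
        res = q.sequential_forward_selection(X, y, folds=5, seed=0)
        assert res.order[0] == 3  # 1-based index of the informative feature
        assert len(res.order) == len(res.scores) == 3

    def test_duplicate_columns_tie_broken_by_lowest_index(self):
        X, y = separable_features(n=30, n_features=1, informative=0, seed=5)
        X = np.hstack([X, X])
        res = q.sequential_forward_selection(X, y, folds=5, seed=0)
        assert res.order[0] == 1

    def test_full_trace_on_cohort(self, small_cohort_features):
        df = small_cohort_features
        X = df[list(q.FEATURE_NAMES)].to_numpy()
        y = np.where(df["grade"] <= 3, "unacceptable", "acceptable")
        res = q.sequential_forward_selection(X, y, folds=5, seed=0)
        assert sorted(res.order) == list(range(1, 11))
        assert len(res.scores) == 10
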