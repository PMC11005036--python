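import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarkit import ConfusionMatrix, EvalPairs, classification_metrics, r_squared, rmse
from qsarkit.metrics import MetricError


# --- independent brute-force oracles (explicit loops, no numpy vector math) ---

def brute_rmse(obs, pred):
    total = 0.0
    for o, p in zip(obs, pred):
        total += (o - p) ** 2
    return math.sqrt(total / len(obs))


def brute_r2(obs, pred):
    mean = sum(obs) / len(obs)
    ss_res = sum((o - p) ** 2 for o, p in zip(obs, pred))
    ss_tot = sum((o - mean) ** 2 for o in obs)
    return 1.0 - ss_res / ss_tot


def brute_classification(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return acc, prec, rec, f1, mcc


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        pairs = EvalPairs.from_sequences([1, 2, 3], [1, 2, 3])
        assert rmse(pairs) == 0.0
        assert r_squared(pairs) == 1.0

    def test_unit_offset(self):
        assert rmse(EvalPairs.from_sequences([0, 0], [1, 1])) == 1.0

    def test_hand_computed_rmse(self):
        assert rmse(EvalPairs.from_sequences([1, 2], [2, 4])) == pytest.approx(
            math.sqrt(2.5)
        )

    def test_hand_computed_r2(self):
        pairs = EvalPairs.from_sequences([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        assert r_squared(pairs) == pytest.approx(1 - 0.10 / 5.0)

    def test_constant_prediction_gives_zero_r2(self):
        obs = [1.0, 2.0, 3.0]
        pairs = EvalPairs.from_sequences(obs, [2.0, 2.0, 2.0])
        assert r_squared(pairs) == pytest.approx(0.0)

    def test_constant_observations_undefined_r2(self):
        with pytest.raises(MetricError):
            r_squared(EvalPairs.from_sequences([2.0, 2.0], [1.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            EvalPairs.from_sequences([1, 2], [1, 2, 3])

    def test_rmse_of_constant_shift_is_abs_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        for c in (-2.5, 0.3, 4.0):
            assert rmse(EvalPairs.from_sequences(x, x + c)) == pytest.approx(abs(c))


class TestClassificationMetrics:
    def test_perfect_agreement(self):
        m = classification_metrics(ConfusionMatrix(TP=5, TN=5, FP=0, FN=0))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_total_disagreement(self):
        m = classification_metrics(ConfusionMatrix(TP=0, TN=0, FP=5, FN=5))
        assert m.accuracy == 0.0
        assert m.mcc == -1.0

    def test_hand_computed_mixed_matrix(self):
        m = classification_metrics(ConfusionMatrix(TP=3, FP=1, FN=2, TN=4))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m.accuracy == pytest.approx(0.7)
        assert m.mcc == pytest.approx(10 / math.sqrt(600))

    def test_degenerate_denominators_flagged(self):
        m = classification_metrics(ConfusionMatrix(TP=0, TN=4, FP=0, FN=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0 and m.mcc == 0.0
        assert m.degenerate

    def test_f1_is_harmonic_mean_when_defined(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + fp == 0 or tp + fn == 0 or tp == 0 or tp+tn+fp+fn == 0:
                continue
            m = classification_metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            assert m.f1 == pytest.approx(
                2 / (1 / m.precision + 1 / m.recall), rel=1e-12
            )

    def test_mcc_invariant_under_class_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            a = classification_metrics(ConfusionMatrix(tp, tn, fp, fn)).mcc
            b = classification_metrics(ConfusionMatrix(tn, tp, fn, fp)).mcc
            assert a == pytest.approx(b, abs=1e-15)

    def test_negative_counts_rejected(self):
        with pytest.raises(MetricError):
            ConfusionMatrix(TP=-1, TN=1, FP=0, FN=0)


@settings(derandomize=True, max_examples=200)
@given(
    tp=st.integers(0, 100), tn=st.integers(0, 100),
    fp=st.integers(0, 100), fn=st.integers(0, 100),
)
def test_confusion_metric_ranges_hold_for_any_matrix(tp, tn, fp, fn):
    """Accuracy/precision/recall/F1 stay in [0,1] and MCC in [-1,1]
    for every confusion matrix, including degenerate margins."""
    if tp + tn + fp + fn == 0:
        return
    m = classification_metrics(ConfusionMatrix(tp, tn, fp, fn))
    for value in (m.accuracy, m.precision, m.recall, m.f1):
        assert 0.0 <= value <= 1.0
    assert -1.0 <= m.mcc <= 1.0


@settings(derandomize=True, max_examples=100)
@given(
    obs=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    shift=st.floats(-10, 10),
)
def test_rmse_shift_property_holds_generally(obs, shift):
    """rmse(x, x + c) = |c| for any data vector and constant shift."""
    obs = np.asarray(obs)
    pairs = EvalPairs.from_sequences(obs, obs + shift)
    assert rmse(pairs) == pytest.approx(abs(shift), abs=1e-9)


def test_brute_force_equivalence_on_random_inputs():
    """Vectorized metric implementations agree with explicit-loop
    recomputation to 1e-12 relative on 1,000 random inputs each."""
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        n = int(rng.integers(2, 40))
        obs = rng.normal(size=n) * 3 + 7
        pred = obs + rng.normal(size=n)
        pairs = EvalPairs.from_sequences(obs, pred)
        assert rmse(pairs) == pytest.approx(brute_rmse(obs, pred), rel=1e-12)
        assert r_squared(pairs) == pytest.approx(brute_r2(obs, pred), rel=1e-12)

    for _ in range(1000):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
        if tp + tn + fp + fn == 0:
            tp = 1
        got = classification_metrics(ConfusionMatrix(tp, tn, fp, fn))
        acc, prec, rec, f1, mcc = brute_classification(tp, tn, fp, fn)
        assert got.accuracy == pytest.approx(acc, rel=1e-12, abs=1e-15)
        assert got.precision == pytest.approx(prec, rel=1e-12, abs=1e-15)
        assert got.recall == pytest.approx(rec, rel=1e-12, abs=1e-15)
        assert got.f1 == pytest.approx(f1, rel=1e-12, abs=1e-15)
        assert got.mcc == pytest.approx(mcc, rel=1e-12, abs=1e-15)


def test_agreement_with_sklearn_on_label_vectors():
    """Cross-check against an independent library implementation."""
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    rng = np.random.default_rng(7)
    obs = rng.integers(0, 2, size=200)
    pred = np.where(rng.random(200) < 0.8, obs, 1 - obs)
    m = classification_metrics(ConfusionMatrix.from_labels(obs, pred))
    assert m.accuracy == pytest.approx(accuracy_score(obs, pred))
    assert m.precision == pytest.approx(precision_score(obs, pred))
    assert m.recall == pytest.approx(recall_score(obs, pred))
    assert m.f1 == pytest.approx(f1_score(obs, pred))
    assert m.mcc == pytest.approx(matthews_corrcoef(obs, pred))
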