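import itertools

import numpy as np
import pytest

from qsarkit import (
    ADReference,
    build_ad_reference,
    check_ad,
    shapley_rank,
)
from qsarkit.applicability_domain import (
    AD_N_DESCRIPTORS,
    AD_REQUIRED_IN_RANGE,
    ADError,
    local_accuracy_gap,
)
from qsarkit.modeling import LGBLearner, EnsembleModel, TrainingConfig, train
from qsarkit.descriptors import DescriptorMatrix


def unit_reference():
    return ADReference(
        descriptors=[f"d{i}" for i in range(10)],
        min_values=np.zeros(10),
        max_values=np.ones(10),
    )


class TestMembershipRule:
    def test_all_patterns_match_popcount_rule(self):
        """Exhaustive brute-force oracle: for all 2^10 in/out patterns the
        verdict equals (number in range >= 7)."""
        ref = unit_reference()
        for pattern in itertools.product([0, 1], repeat=10):
            # value 0.5 is inside [0,1]; 2.0 is outside
            values = [0.5 if bit else 2.0 for bit in pattern]
            verdict = check_ad(values, ref)
            popcount = sum(pattern)
            assert verdict.n_in_range == popcount
            assert verdict.in_domain == (popcount >= AD_REQUIRED_IN_RANGE)

    def test_exactly_seven_in_range_is_in_domain(self):
        values = [0.5] * 7 + [2.0] * 3
        assert check_ad(values, unit_reference()).in_domain is True

    def test_exactly_six_in_range_is_out_of_domain(self):
        values = [0.5] * 6 + [2.0] * 4
        assert check_ad(values, unit_reference()).in_domain is False

    def test_bounds_are_inclusive(self):
        values = [0.0] * 5 + [1.0] * 5  # all on the training extrema
        verdict = check_ad(values, unit_reference())
        assert verdict.n_in_range == 10 and verdict.in_domain

    def test_missing_values_count_as_out_of_range(self):
        mapping = {f"d{i}": 0.5 for i in range(6)}  # d6..d9 missing
        verdict = check_ad(mapping, unit_reference())
        assert verdict.n_in_range == 6 and not verdict.in_domain

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(-1, 2, size=10)
        ref = unit_reference()
        base = check_ad(values, ref)
        scaled_ref = ADReference(
            descriptors=ref.descriptors,
            min_values=3.0 * ref.min_values + 2.0,
            max_values=3.0 * ref.max_values + 2.0,
        )
        scaled = check_ad(3.0 * values + 2.0, scaled_ref)
        assert scaled.n_in_range == base.n_in_range
        assert scaled.in_domain == base.in_domain


class TestReferenceConstruction:
    def test_training_column_range_and_normalization(self):
        matrix = DescriptorMatrix(
            molecule_ids=["a", "b", "c"],
            descriptor_names=[f"d{i}" for i in range(10)],
            values=np.column_stack(
                [np.array([2.0, 5.0, 8.0])] + [np.arange(3.0) + i for i in range(9)]
            ),
            failure_mask=np.zeros((3, 10), dtype=bool),
        )
        ranking = [(f"d{i}", 10.0 - i) for i in range(10)]
        ref = build_ad_reference(ranking, matrix)
        assert ref.min_values[0] == 2.0 and ref.max_values[0] == 8.0
        norm = ref.normalize([2.0] + [0.0] * 9)
        assert norm[0] == 0.0
        assert ref.normalize([8.0] + [0.0] * 9)[0] == 1.0

    def test_degenerate_constant_column(self):
        matrix = DescriptorMatrix(
            molecule_ids=["a", "b"],
            descriptor_names=[f"d{i}" for i in range(10)],
            values=np.column_stack(
                [np.array([4.0, 4.0])] + [np.arange(2.0) + i for i in range(9)]
            ),
            failure_mask=np.zeros((2, 10), dtype=bool),
        )
        ref = build_ad_reference([(f"d{i}", 1.0) for i in range(10)], matrix)
        assert ref.min_values[0] == ref.max_values[0] == 4.0
        assert check_ad([4.0] + [0.5 + i for i in range(9)], ref).per_descriptor[0][2]
        assert not check_ad([4.01] + [0.5 + i for i in range(9)], ref).per_descriptor[0][2]

    def test_reference_deterministic(self, tiny_bundle, small_filtered):
        ranking = shapley_rank(tiny_bundle, small_filtered)
        a = build_ad_reference(ranking, small_filtered)
        b = build_ad_reference(ranking, small_filtered)
        assert a.descriptors == b.descriptors
        assert np.array_equal(a.min_values, b.min_values)

    def test_too_few_descriptors_rejected(self, small_filtered):
        with pytest.raises(ADError):
            build_ad_reference([("a", 1.0)] * 5, small_filtered)


class TestShapleyRanking:
    def make_matrix(self, X, names):
        return DescriptorMatrix(
            molecule_ids=[f"m{i}" for i in range(X.shape[0])],
            descriptor_names=list(names),
            values=X,
            failure_mask=np.zeros_like(X, dtype=bool),
        )

    def fit_learner(self, X, y):
        learner = LGBLearner(
            {"n_estimators": 150, "learning_rate": 0.1, "num_leaves": 31,
             "min_child_samples": 5},
            "regression",
            seed=0,
        )
        return EnsembleModel([(1.0, learner.fit(X, y))], "regression")

    def test_single_active_descriptor_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 12))
        y = 2.0 * X[:, 3]
        model = self.fit_learner(X, y)
        ranking = shapley_rank(model, self.make_matrix(X, [f"f{i}" for i in range(12)]))
        names = [n for n, _ in ranking]
        importances = dict(ranking)
        assert names[0] == "f3"
        assert importances["f3"] > 10 * max(v for n, v in ranking if n != "f3")

    def test_additive_model_orders_by_coefficient(self):
        # y = 3a + b on equal-variance features: for an additive model the
        # exact Shapley value of each feature is its own centered term, so
        # mean |phi_a| ~ 3 x mean |phi_b|
        rng = np.random.default_rng(1)
        X = rng.normal(size=(600, 2))
        y = 3.0 * X[:, 0] + 1.0 * X[:, 1]
        model = self.fit_learner(X, y)
        ranking = shapley_rank(model, self.make_matrix(X, ["a", "b"]))
        assert [n for n, _ in ranking] == ["a", "b"]
        importances = dict(ranking)
        assert importances["a"] / importances["b"] == pytest.approx(3.0, rel=0.25)

    def test_local_accuracy_axiom(self, tiny_bundle, small_filtered):
        gap = local_accuracy_gap(tiny_bundle.estimator, small_filtered.values)
        scale = np.max(np.abs(tiny_bundle.estimator.predict_margin(small_filtered.values)))
        assert gap / scale <= 1e-6

    def test_local_accuracy_axiom_classification(self, cls_bundle, small_filtered):
        gap = local_accuracy_gap(cls_bundle.estimator, small_filtered.values)
        scale = max(1.0, np.max(np.abs(cls_bundle.estimator.predict_margin(small_filtered.values))))
        assert gap / scale <= 1e-6

    def test_unsupported_estimator_names_fallback(self, small_filtered):
        with pytest.raises(ADError, match="permutation"):
            shapley_rank(object(), small_filtered)


def test_every_training_molecule_in_domain_of_own_reference(tiny_bundle, small_filtered):
    """By construction the training extrema bound every training value, so
    each training molecule scores 10/10."""
    ref = tiny_bundle.ad_reference
    idx = {n: j for j, n in enumerate(small_filtered.descriptor_names)}
    cols = [idx[n] for n in ref.descriptors]
    for i in range(small_filtered.n_molecules):
        verdict = check_ad(small_filtered.values[i, cols], ref)
        assert verdict.n_in_range == AD_N_DESCRIPTORS
        assert verdict.in_domain
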