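import numpy as np
import pytest

from qsarkit import (
    FixtureSpec,
    TrainingConfig,
    apply_filter,
    attach_ad,
    compute_descriptors,
    filter_features,
    generate_labels,
    generate_molecules,
    train,
)


@pytest.fixture(scope="session")
def small_molecules():
    return generate_molecules(120, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_molecules):
    return compute_descriptors(small_molecules)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(n_molecules=120, seed=7, noise_sigma=0.3)


@pytest.fixture(scope="session")
def small_labels(small_molecules, small_matrix, small_spec):
    labels, info = generate_labels(small_molecules, small_spec, matrix=small_matrix)
    return labels, info


@pytest.fixture(scope="session")
def small_report(small_matrix):
    return filter_features(small_matrix)


@pytest.fixture(scope="session")
def small_filtered(small_matrix, small_report):
    return apply_filter(small_matrix, small_report)


@pytest.fixture(scope="session")
def tiny_bundle(small_filtered, small_labels, small_report):
    """A small trained regression bundle with AD reference attached."""
    labels, _ = small_labels
    config = TrainingConfig(task="regression", n_folds=5, search_budget=4, seed=11)
    bundle = train(small_filtered, labels, config, filter_report=small_report, target="SERT")
    return attach_ad(bundle, small_filtered)


@pytest.fixture(scope="session")
def cls_bundle(small_molecules, small_matrix, small_report, small_filtered):
    """A small trained classification bundle (permeability-style labels)."""
    spec = FixtureSpec(n_molecules=120, seed=7, task="classification", class_balance=0.5)
    labels, _ = generate_labels(small_molecules, spec, matrix=small_matrix)
    config = TrainingConfig(task="classification", n_folds=5, search_budget=4, seed=11)
    bundle = train(small_filtered, labels, config, filter_report=small_report, target="BBB")
    return attach_ad(bundle, small_filtered)
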