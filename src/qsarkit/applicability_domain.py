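"""Applicability-domain (AD) checking via descriptor-range membership.

A model's AD is defined by its ten most influential descriptors, ranked
by mean absolute Shapley attribution over the training set.  For each
of the ten, the training-set minimum and maximum are stored; a query
molecule is *in domain* when at least seven of the ten descriptor
values fall inside their training range (bounds inclusive — the extrema
are observed values).  Min–max normalization of the ranges is provided
for reporting; membership itself is tested on the raw bounds, which is
mathematically identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .modeling import EnsembleModel, ModelBundle

#: Number of top-ranked descriptors defining the domain.
AD_N_DESCRIPTORS = 10

#: Minimum number of in-range descriptors for an in-domain verdict.
AD_REQUIRED_IN_RANGE = 7


class ADError(ValueError):
    pass


@dataclass
class ADReference:
    """Training-set ranges of the importance-ranked top-10 descriptors."""

    descriptors: List[str]
    min_values: np.ndarray
    max_values: np.ndarray
    required_in_range: int = AD_REQUIRED_IN_RANGE

    def __post_init__(self) -> None:
        if len(self.descriptors) != AD_N_DESCRIPTORS:
            raise ADError(
                f"AD reference needs exactly {AD_N_DESCRIPTORS} descriptors, "
                f"got {len(self.descriptors)}"
            )
        self.min_values = np.asarray(self.min_values, dtype=float)
        self.max_values = np.asarray(self.max_values, dtype=float)
        if np.any(self.min_values > self.max_values):
            raise ADError("per-descriptor min must not exceed max")
        if not 0 <= self.required_in_range <= AD_N_DESCRIPTORS:
            raise ADError("required_in_range must lie in [0, 10]")

    def normalize(self, values: Sequence[float]) -> np.ndarray:
        """Min–max transform (x - min) / (max - min) for reporting;
        degenerate ranges map their single value to 0."""
        values = np.asarray(values, dtype=float)
        span = self.max_values - self.min_values
        out = np.zeros_like(values)
        nz = span > 0
        out[nz] = (values[nz] - self.min_values[nz]) / span[nz]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptors,
                "train_min": self.min_values,
                "train_max": self.max_values,
            }
        )


@dataclass
class ADVerdict:
    in_domain: bool
    n_in_range: int
    per_descriptor: List[Tuple[str, float, bool]]  # (name, value, in_range)


def shapley_rank(
    bundle_or_estimator, train_matrix: DescriptorMatrix
) -> List[Tuple[str, float]]:
    """Rank descriptors by mean |Shapley attribution| over the training set.

    Attributions come from exact TreeSHAP on each ensemble member,
    combined by ensemble weight (valid because the ensemble margin is
    additive in its members).  Returns ``(name, mean_abs_shap)`` pairs
    in decreasing importance, with ties broken by descriptor name so
    the ranking is deterministic.
    """
    estimator = (
        bundle_or_estimator.estimator
        if isinstance(bundle_or_estimator, ModelBundle)
        else bundle_or_estimator
    )
    if not isinstance(estimator, EnsembleModel):
        raise ADError(
            f"no Shapley attribution backend for {type(estimator).__name__}; "
            "use permutation_rank as a fallback importance measure"
        )
    contribs = estimator.shap_contributions(train_matrix.values)
    # Last column is the expected value; feature columns precede it.
    feature_contribs = contribs[:, :-1]
    if feature_contribs.shape[1] != len(train_matrix.descriptor_names):
        raise ADError("attribution width does not match descriptor count")
    importance = np.mean(np.abs(feature_contribs), axis=0)
    ranked = sorted(
        zip(train_matrix.descriptor_names, importance.tolist()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked


def permutation_rank(
    estimator: EnsembleModel,
    matrix: DescriptorMatrix,
    labels: Sequence[float],
    seed: int = 0,
) -> List[Tuple[str, float]]:
    """Fallback importance: mean increase in squared error when one
    column is permuted.  Used only for estimator types without a
    TreeSHAP backend."""
    rng = np.random.default_rng(seed)
    X = np.asarray(matrix.values, dtype=float)
    y = np.asarray(labels, dtype=float)
    base = float(np.mean((estimator.predict(X) - y) ** 2))
    scores = []
    for j, name in enumerate(matrix.descriptor_names):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        scores.append((name, float(np.mean((estimator.predict(Xp) - y) ** 2)) - base))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def local_accuracy_gap(estimator: EnsembleModel, X: np.ndarray) -> float:
    """Max |sum(attributions) + base − margin| over rows; the Shapley
    local-accuracy axiom makes this ~0 for exact TreeSHAP."""
    contribs = estimator.shap_contributions(X)
    margin = estimator.predict_margin(X)
    return float(np.max(np.abs(contribs.sum(axis=1) - margin)))


def build_ad_reference(
    ranking: Sequence[Tuple[str, float]],
    train_matrix: DescriptorMatrix,
    required_in_range: int = AD_REQUIRED_IN_RANGE,
) -> ADReference:
    """Store training min/max for the top-10 ranked descriptors."""
    if len(ranking) < AD_N_DESCRIPTORS:
        raise ADError(
            f"need at least {AD_N_DESCRIPTORS} ranked descriptors, got {len(ranking)}"
        )
    if train_matrix.n_molecules < 1:
        raise ADError("training matrix is empty")
    top = [name for name, _ in ranking[:AD_N_DESCRIPTORS]]
    col_index = {n: j for j, n in enumerate(train_matrix.descriptor_names)}
    missing = [n for n in top if n not in col_index]
    if missing:
        raise ADError(f"training matrix lacks ranked descriptors: {missing}")
    cols = [col_index[n] for n in top]
    values = train_matrix.values[:, cols]
    return ADReference(
        descriptors=top,
        min_values=np.nanmin(values, axis=0),
        max_values=np.nanmax(values, axis=0),
        required_in_range=required_in_range,
    )


def check_ad(
    molecule_descriptors: Dict[str, float] | Sequence[float],
    ref: ADReference,
) -> ADVerdict:
    """Classify one molecule against the AD reference.

    ``molecule_descriptors`` is either a name→value mapping or a value
    sequence aligned with ``ref.descriptors``.  Missing or non-finite
    values count as out of range (conservative).  Bounds are inclusive;
    the verdict is in-domain iff at least ``ref.required_in_range`` of
    the ten descriptors fall inside their training range.
    """
    if isinstance(molecule_descriptors, dict):
        values = [molecule_descriptors.get(n, float("nan")) for n in ref.descriptors]
    else:
        values = list(molecule_descriptors)
        if len(values) != len(ref.descriptors):
            raise ADError(
                f"expected {len(ref.descriptors)} descriptor values, got {len(values)}"
            )
    per: List[Tuple[str, float, bool]] = []
    n_in = 0
    for name, value, lo, hi in zip(
        ref.descriptors, values, ref.min_values, ref.max_values
    ):
        value = float(value)
        in_range = bool(np.isfinite(value) and lo <= value <= hi)
        n_in += in_range
        per.append((name, value, in_range))
    return ADVerdict(
        in_domain=n_in >= ref.required_in_range, n_in_range=n_in, per_descriptor=per
    )


def attach_ad(bundle: ModelBundle, train_matrix: DescriptorMatrix) -> ModelBundle:
    """Compute the Shapley ranking on the (filtered) training matrix and
    attach the resulting AD reference to the bundle."""
    ranking = shapley_rank(bundle, train_matrix)
    bundle.ad_reference = build_ad_reference(ranking, train_matrix)
    return bundle
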