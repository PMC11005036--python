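"""Prediction engine: single-molecule and batch modes over trained
bundles, plus the end-to-end training pipeline helper.

Descriptors are computed once per molecule and reused across all
requested endpoints.  Batch output preserves input row order; rows with
unparseable SMILES carry an explicit failure marker instead of being
dropped.  Applicability-domain verdicts appear in batch files as the
literal strings "True" / "False".
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .applicability_domain import ADVerdict, attach_ad, check_ad
from .chem_io import (
    BUNDLE_FORMAT_VERSION,
    BatchTable,
    MoleculeInput,
    load_bundle,
    read_batch_csv,
    validate_smiles,
)
from .curation import CLASSIFICATION_TARGETS
from .descriptors import DescriptorMatrix, apply_filter, compute_descriptors, filter_features
from .modeling import (
    CLASSIFICATION,
    REGRESSION,
    ModelBundle,
    TrainingConfig,
    evaluate_test,
    train,
)

#: Marker written into batch cells for rows whose SMILES does not parse.
INVALID_MARKER = "INVALID_SMILES"

#: Decimal places used for pKi values and probabilities in output files.
OUTPUT_DECIMALS = 3


class PredictionError(ValueError):
    pass


@dataclass
class PredictionResult:
    """One molecule × endpoint prediction with its AD verdict."""

    canonical_smiles: str
    target: str
    predicted_value: Optional[float] = None   # pKi (regression endpoints)
    predicted_class: Optional[int] = None     # classification endpoints
    probability: Optional[float] = None
    ad_flag: bool = False
    ad_verdict: Optional[ADVerdict] = None
    bundle_version: str = ""

    def formatted_value(self) -> str:
        if self.predicted_value is not None:
            return f"{self.predicted_value:.{OUTPUT_DECIMALS}f}"
        return str(self.predicted_class)


def _bundle_version(bundle: ModelBundle) -> str:
    return f"{bundle.target or 'model'}/fmt{BUNDLE_FORMAT_VERSION}/{bundle.descriptor_set}"


def _predict_one_target(
    matrix: DescriptorMatrix, bundle: ModelBundle, target: str
) -> List[PredictionResult]:
    filtered = apply_filter(matrix, bundle.filter_report)
    if list(filtered.descriptor_names) != list(bundle.descriptor_names):
        raise PredictionError(
            f"bundle for {target!r} expects descriptors not present in this matrix"
        )
    outputs = bundle.estimator.predict(filtered.values)
    results = []
    for i in range(filtered.n_molecules):
        row = dict(zip(filtered.descriptor_names, filtered.values[i]))
        verdict = (
            check_ad(row, bundle.ad_reference) if bundle.ad_reference is not None else None
        )
        result = PredictionResult(
            canonical_smiles=filtered.molecule_ids[i],
            target=target,
            ad_flag=bool(verdict.in_domain) if verdict is not None else False,
            ad_verdict=verdict,
            bundle_version=_bundle_version(bundle),
        )
        if bundle.config.task == REGRESSION:
            result.predicted_value = float(outputs[i])
        else:
            result.probability = float(outputs[i])
            result.predicted_class = int(outputs[i] >= 0.5)
        results.append(result)
    return results


def predict_single(
    smiles: str, bundles: Mapping[str, ModelBundle], targets: Optional[Sequence[str]] = None
) -> List[PredictionResult]:
    """Predict one molecule against the requested endpoints.

    Descriptors are computed once and shared across targets.  Raises on
    invalid SMILES (single mode is interactive; silence would hide the
    problem) and on unknown target names.
    """
    molecule = validate_smiles(smiles)
    if not molecule.valid:
        raise PredictionError(f"SMILES does not parse: {smiles!r}")
    chosen = list(targets) if targets is not None else list(bundles.keys())
    unknown = [t for t in chosen if t not in bundles]
    if unknown:
        raise PredictionError(
            f"no trained bundle for {unknown}; available endpoints: {sorted(bundles)}"
        )
    matrix = compute_descriptors([molecule])
    results: List[PredictionResult] = []
    for target in chosen:
        results.extend(_predict_one_target(matrix, bundles[target], target))
    return results


def predict_batch(
    csv_path: str,
    bundles: Mapping[str, ModelBundle],
    out_path: Optional[str] = None,
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Predict every row of a batch CSV against the requested endpoints.

    The output frame preserves input row order and pass-through columns,
    and adds per-target value and AD columns ("<target>_pKi" /
    "<target>_class" + "<target>_probability", and "<target>_AD" holding
    literal "True"/"False").  Invalid SMILES rows are flagged with
    ``INVALID_SMILES`` in every added column.
    """
    table = read_batch_csv(csv_path)
    chosen = list(targets) if targets is not None else list(bundles.keys())
    unknown = [t for t in chosen if t not in bundles]
    if unknown:
        raise PredictionError(
            f"no trained bundle for {unknown}; available endpoints: {sorted(bundles)}"
        )

    valid_idx = [i for i, m in enumerate(table.rows) if m.valid]
    frame = pd.DataFrame(
        {
            "smiles": [m.raw_smiles for m in table.rows],
            "canonical_smiles": [
                m.canonical_smiles if m.valid else INVALID_MARKER for m in table.rows
            ],
        }
    )
    for col in table.extra_columns.columns:
        frame[col] = table.extra_columns[col].to_numpy()

    matrix = (
        compute_descriptors([table.rows[i] for i in valid_idx]) if valid_idx else None
    )
    for target in chosen:
        bundle = bundles[target]
        is_classification = bundle.config.task == CLASSIFICATION
        value_col = f"{target}_class" if is_classification else f"{target}_pKi"
        prob_col = f"{target}_probability"
        ad_col = f"{target}_AD"
        values = [INVALID_MARKER] * len(table.rows)
        probs = [INVALID_MARKER] * len(table.rows)
        ads = [INVALID_MARKER] * len(table.rows)
        if matrix is not None:
            for row_i, result in zip(valid_idx, _predict_one_target(matrix, bundle, target)):
                values[row_i] = result.formatted_value()
                ads[row_i] = str(bool(result.ad_flag))
                if is_classification:
                    probs[row_i] = f"{result.probability:.{OUTPUT_DECIMALS}f}"
        frame[value_col] = values
        if is_classification:
            frame[prob_col] = probs
        frame[ad_col] = ads

    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame


def load_bundles(model_dir: str, targets: Optional[Sequence[str]] = None) -> Dict[str, ModelBundle]:
    """Load every ``<target>.bundle`` file under ``model_dir``."""
    found: Dict[str, ModelBundle] = {}
    for name in sorted(os.listdir(model_dir)):
        if name.endswith(".bundle"):
            target = name[: -len(".bundle")]
            if targets is None or target in targets:
                found[target] = load_bundle(os.path.join(model_dir, name))
    missing = [t for t in (targets or []) if t not in found]
    if missing:
        raise PredictionError(f"no bundle file for endpoints {missing} in {model_dir!r}")
    return found


def train_endpoint(
    frame: pd.DataFrame,
    target: str,
    config: TrainingConfig,
    correlation_threshold: float = 0.95,
) -> ModelBundle:
    """End-to-end training from an endpoint CSV frame.

    Validates SMILES, computes 2D descriptors, fits the feature filter
    on the training data, runs the cross-validated model search, and
    attaches the Shapley-ranked applicability-domain reference.
    The frame needs ``smiles`` plus ``pKi`` (regression) or ``label``
    (classification) columns.
    """
    value_col = "label" if config.task == CLASSIFICATION else "pKi"
    if "smiles" not in frame.columns or value_col not in frame.columns:
        raise PredictionError(
            f"training table needs 'smiles' and {value_col!r} columns"
        )
    molecules, labels = [], []
    for raw, value in zip(frame["smiles"], frame[value_col]):
        parsed = validate_smiles(raw)
        if parsed.valid:
            molecules.append(parsed)
            labels.append(float(value))
    if len(molecules) < config.n_folds:
        raise PredictionError(
            f"only {len(molecules)} valid molecules; need at least {config.n_folds}"
        )
    matrix = compute_descriptors(molecules)
    report = filter_features(matrix, threshold=correlation_threshold)
    filtered = apply_filter(matrix, report)
    bundle = train(filtered, labels, config, filter_report=report, target=target)
    return attach_ad(bundle, filtered)


def evaluate_endpoint(bundle: ModelBundle, frame: pd.DataFrame):
    """Evaluate a bundle on an endpoint test CSV frame."""
    value_col = "label" if bundle.config.task == CLASSIFICATION else "pKi"
    molecules, labels = [], []
    for raw, value in zip(frame["smiles"], frame[value_col]):
        parsed = validate_smiles(raw)
        if parsed.valid:
            molecules.append(parsed)
            labels.append(float(value))
    matrix = apply_filter(compute_descriptors(molecules), bundle.filter_report)
    return evaluate_test(bundle, matrix, labels)
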