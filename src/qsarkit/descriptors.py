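"""2D molecular descriptors and the constant/correlated feature filter.

Molecules are represented by RDKit's full 2D descriptor set (~210
descriptors: constitutional counts, topological indices, logP/TPSA
estimates, fragment counts, ...).  Only graph-derived descriptors are
used — no conformer generation — so the representation is deterministic
for a given canonical SMILES.

Feature filtering is fit on training data only: constant (and
majority-failed) columns are removed first, then one member of every
highly correlated pair.  The resulting report is a frozen function that
can be applied to any later matrix (test set, prediction batch) without
recomputation, which is what keeps test-set information out of the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors as _RD

from .chem_io import MoleculeInput, mol_from_input

#: Default |Pearson r| above which one column of a pair is pruned.
DEFAULT_CORRELATION_THRESHOLD = 0.95

#: Columns with more than this fraction of failed cells are treated as
#: constant-like and dropped.
MAX_FAILURE_FRACTION = 0.5


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Molecules × descriptors, with per-cell failure flags.

    ``values`` holds NaN where ``failure_mask`` is True; failures are
    imputed only when a filter report (carrying training medians) is
    applied.
    """

    molecule_ids: List[str]
    descriptor_names: List[str]
    values: np.ndarray
    failure_mask: np.ndarray

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if n != len(self.molecule_ids) or p != len(self.descriptor_names):
            raise DescriptorError("matrix dimensions inconsistent with id/name lists")
        if len(set(self.descriptor_names)) != p:
            raise DescriptorError("descriptor names must be unique")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, columns=self.descriptor_names, index=self.molecule_ids
        )
        frame.index.name = "molecule_id"
        return frame

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorMatrix":
        values = frame.to_numpy(dtype=float)
        return cls(
            molecule_ids=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=values,
            failure_mask=~np.isfinite(values),
        )


@dataclass
class FeatureFilterReport:
    """Frozen outcome of training-set feature filtering.

    Every input descriptor is accounted for in exactly one of ``kept``,
    ``dropped_constant`` or ``dropped_correlated``.  ``medians`` holds
    training-set medians of the kept columns, used to impute failed
    cells at application time.
    """

    kept: List[str]
    dropped_constant: List[str]
    dropped_correlated: List[Tuple[str, str, float]]  # (dropped, kept_partner, |r|)
    correlation_threshold: float
    medians: Dict[str, float] = field(default_factory=dict)

    def surrogate_for(self, name: str) -> Optional[str]:
        """The kept column that represents ``name`` after filtering: the
        name itself if kept, its recorded kept partner if it was pruned
        for correlation, or None if it was dropped as constant.  The
        partner is always a kept column (the greedy scan never drops a
        column that has already absorbed another)."""
        if name in set(self.kept):
            return name
        for dropped, partner, _ in self.dropped_correlated:
            if dropped == name:
                return partner
        return None

    def accounts_for(self, names: Sequence[str]) -> bool:
        covered = set(self.kept) | set(self.dropped_constant) | {
            d for d, _, _ in self.dropped_correlated
        }
        return covered == set(names)

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, "kept", "", np.nan) for n in self.kept]
        rows += [(n, "dropped_constant", "", np.nan) for n in self.dropped_constant]
        rows += [(d, "dropped_correlated", partner, r)
                 for d, partner, r in self.dropped_correlated]
        return pd.DataFrame(rows, columns=["descriptor", "status", "partner", "abs_r"])


def descriptor_names() -> List[str]:
    """Names of all computed 2D descriptors, in RDKit registry order."""
    return [name for name, _ in _RD._descList]


def compute_descriptors(molecules: Sequence[MoleculeInput]) -> DescriptorMatrix:
    """Compute the 2D descriptor matrix, one row per molecule in order.

    All inputs must be valid; a cell whose descriptor raises or returns a
    non-finite value is flagged as failed (NaN), never silently zeroed.
    """
    invalid = [i for i, m in enumerate(molecules) if not m.valid]
    if invalid:
        raise DescriptorError(
            f"cannot compute descriptors for invalid SMILES at rows {invalid}"
        )
    names = descriptor_names()
    rows = np.empty((len(molecules), len(names)), dtype=float)
    for i, molecule in enumerate(molecules):
        mol = mol_from_input(molecule)
        computed = _RD.CalcMolDescriptors(mol, missingVal=np.nan)
        rows[i, :] = [computed[name] for name in names]
    with np.errstate(invalid="ignore"):
        failure = ~np.isfinite(rows)
    rows = np.where(failure, np.nan, rows)
    return DescriptorMatrix(
        molecule_ids=[m.canonical_smiles for m in molecules],
        descriptor_names=list(names),
        values=rows,
        failure_mask=failure,
    )


def _is_constant_like(column: np.ndarray, failed: np.ndarray) -> bool:
    if failed.mean() > MAX_FAILURE_FRACTION:
        return True
    observed = column[~failed]
    if observed.size == 0:
        return True
    return bool(np.all(observed == observed[0]))


def filter_features(
    matrix: DescriptorMatrix,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> FeatureFilterReport:
    """Fit the constant/correlated filter on a *training* matrix.

    Constant-like columns go first; then pairs with |Pearson r| above
    ``threshold`` (computed on median-imputed training values) are
    pruned greedily in alphabetical descriptor-name order, always
    dropping the later-named column of a violating pair so the outcome
    is deterministic.
    """
    if matrix.n_molecules < 2:
        raise DescriptorError("feature filtering needs at least 2 molecules")

    names = matrix.descriptor_names
    dropped_constant = [
        name
        for j, name in enumerate(names)
        if _is_constant_like(matrix.values[:, j], matrix.failure_mask[:, j])
    ]
    survivors = [n for n in names if n not in set(dropped_constant)]

    # Median-impute failures before computing correlations.
    col_index = {n: j for j, n in enumerate(names)}
    imputed = {}
    medians = {}
    for name in survivors:
        col = matrix.values[:, col_index[name]].copy()
        failed = matrix.failure_mask[:, col_index[name]]
        med = float(np.median(col[~failed]))
        col[failed] = med
        imputed[name] = col
        medians[name] = med

    ordered = sorted(survivors)
    data = np.column_stack([imputed[n] for n in ordered]) if ordered else np.empty((0, 0))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data, rowvar=False) if len(ordered) > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)

    alive = dict.fromkeys(ordered, True)
    dropped_correlated: List[Tuple[str, str, float]] = []
    for i, name_i in enumerate(ordered):
        if not alive[name_i]:
            continue
        for j in range(i + 1, len(ordered)):
            name_j = ordered[j]
            if not alive[name_j]:
                continue
            r = abs(float(corr[i, j]))
            if r > threshold:
                alive[name_j] = False
                dropped_correlated.append((name_j, name_i, r))

    kept = [n for n in names if alive.get(n, False)]
    return FeatureFilterReport(
        kept=kept,
        dropped_constant=dropped_constant,
        dropped_correlated=dropped_correlated,
        correlation_threshold=threshold,
        medians={n: medians[n] for n in kept},
    )


def apply_filter(
    matrix: DescriptorMatrix, report: FeatureFilterReport
) -> DescriptorMatrix:
    """Restrict a matrix to the report's kept columns, in report order.

    Failed cells in kept columns are imputed with the training medians
    recorded in the report, so downstream models always see finite
    values computed from training data only.
    """
    missing = [n for n in report.kept if n not in set(matrix.descriptor_names)]
    if missing:
        raise DescriptorError(f"matrix lacks kept descriptors: {missing[:5]}")
    col_index = {n: j for j, n in enumerate(matrix.descriptor_names)}
    cols = [col_index[n] for n in report.kept]
    values = matrix.values[:, cols].copy()
    failure = matrix.failure_mask[:, cols].copy()
    for k, name in enumerate(report.kept):
        if failure[:, k].any():
            values[failure[:, k], k] = report.medians[name]
    return DescriptorMatrix(
        molecule_ids=list(matrix.molecule_ids),
        descriptor_names=list(report.kept),
        values=values,
        failure_mask=failure,
    )
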