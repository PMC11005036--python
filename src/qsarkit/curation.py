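"""Bioactivity-table curation: deduplication, cross-database reconciliation
and the reproducible 80:20 train/test split.

The curation model assumes two record sources, a reference database
("ZINC") and a secondary one ("ChEMBL").  Within each source duplicates
are resolved first; the sources are then merged, and molecules present
in both are reconciled: if the two pKi values differ by more than 0.1
log units both measurements are considered unreliable and dropped,
otherwise the reference-database value is kept.  Every input record is
accounted for in an audit log, so curation is conservative and fully
traceable.
"""

from __future__ import annotations

import math
import os
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_io import validate_smiles

SOURCE_ZINC = "ZINC"
SOURCE_CHEMBL = "ChEMBL"
SOURCE_OTHER = "OTHER"

#: Maximum tolerated |ΔpKi| between databases for the same molecule;
#: pairs differing by more than this are removed entirely.
CROSS_DB_TOLERANCE = 0.1

#: Affinity endpoints (pKi regression) plus the permeability endpoint.
AFFINITY_TARGETS = (
    "5-HT1A", "5-HT1B", "5-HT1D", "5-HT2A", "5-HT2B", "5-HT2C",
    "5-HT3", "5-HT4", "5-HT5A", "5-HT6", "5-HT7", "SERT",
)
CLASSIFICATION_TARGETS = ("BBB",)
ALL_TARGETS = AFFINITY_TARGETS + CLASSIFICATION_TARGETS


@dataclass(frozen=True)
class AffinityRecord:
    """One molecule–endpoint measurement.

    Exactly one of ``pKi`` (regression endpoints) or ``class_label``
    (binary permeability endpoints: 1 = penetrates, 0 = does not) is set.
    """

    canonical_smiles: str
    source: str
    target: str
    pKi: Optional[float] = None
    class_label: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.pKi is None) == (self.class_label is None):
            raise ValueError("exactly one of pKi / class_label must be set")
        if self.pKi is not None and not math.isfinite(self.pKi):
            raise ValueError(f"pKi must be finite, got {self.pKi}")
        if self.class_label is not None and self.class_label not in (0, 1):
            raise ValueError(f"class_label must be 0 or 1, got {self.class_label}")

    @property
    def value(self) -> float:
        return self.pKi if self.pKi is not None else float(self.class_label)


@dataclass(frozen=True)
class AuditEntry:
    smiles: str
    action: str  # kept | merged | dropped
    reason: str


@dataclass
class CuratedDataset:
    """Reconciled records (unique canonical SMILES) plus the full audit trail."""

    records: List[AffinityRecord]
    audit_log: List[AuditEntry] = field(default_factory=list)
    split_seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.smiles, e.action, e.reason) for e in self.audit_log],
            columns=["smiles", "action", "reason"],
        )


@dataclass
class SplitDataset:
    train: List[AffinityRecord]
    test: List[AffinityRecord]
    ratio: float = 0.8
    seed: Optional[int] = None


class CurationError(ValueError):
    pass


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def deduplicate_within_source(
    records: Sequence[AffinityRecord],
) -> Tuple[List[AffinityRecord], List[AuditEntry]]:
    """Collapse duplicate canonical SMILES within one source.

    Identical measurements collapse silently to one kept record; a SMILES
    measured several times with differing pKi is merged to the median
    value (order-independent and robust to a single outlier entry).  For
    classification endpoints, agreeing labels collapse to one record and
    conflicting labels drop the molecule altogether.
    """
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise CurationError(f"records span multiple sources: {sorted(sources)}")

    groups: "OrderedDict[str, List[AffinityRecord]]" = OrderedDict()
    for rec in records:
        groups.setdefault(rec.canonical_smiles, []).append(rec)

    kept: List[AffinityRecord] = []
    audit: List[AuditEntry] = []
    for smiles, group in groups.items():
        first = group[0]
        if len(group) == 1:
            kept.append(first)
            audit.append(AuditEntry(smiles, "kept", "unique within source"))
            continue
        if first.pKi is not None:
            values = [r.pKi for r in group]
            merged = _median(values)
            kept.append(AffinityRecord(smiles, first.source, first.target, pKi=merged))
            if len(set(values)) == 1:
                reason = f"{len(group)} identical measurements collapsed"
            else:
                reason = f"median of {len(group)} measurements {sorted(values)} -> {merged:g}"
            audit.append(AuditEntry(smiles, "merged", reason))
        else:
            labels = {r.class_label for r in group}
            if len(labels) == 1:
                kept.append(first)
                audit.append(
                    AuditEntry(smiles, "merged", f"{len(group)} identical labels collapsed")
                )
            else:
                audit.append(
                    AuditEntry(smiles, "dropped", "conflicting class labels within source")
                )
    return kept, audit


def reconcile_cross_db(
    zinc_rec: AffinityRecord, chembl_rec: AffinityRecord
) -> Tuple[Optional[AffinityRecord], AuditEntry]:
    """Reconcile one molecule measured in both databases.

    |ΔpKi| ≤ 0.1 keeps a single record carrying the ZINC (reference)
    value; a larger disagreement drops the molecule from the dataset.
    Returns ``(record_or_None, audit_entry)``.
    """
    if zinc_rec.canonical_smiles != chembl_rec.canonical_smiles:
        raise CurationError("cross-database pair does not share a canonical SMILES")
    if zinc_rec.target != chembl_rec.target:
        raise CurationError("cross-database pair does not share a target")
    if zinc_rec.pKi is None or chembl_rec.pKi is None:
        raise CurationError("cross-database reconciliation applies to pKi records only")

    delta = abs(zinc_rec.pKi - chembl_rec.pKi)
    smiles = zinc_rec.canonical_smiles
    # Strict comparison on the rounded log unit: 0.1 itself is tolerated.
    if delta > CROSS_DB_TOLERANCE + 1e-12:
        return None, AuditEntry(
            smiles, "dropped", f"cross-database pKi difference {delta:g} > {CROSS_DB_TOLERANCE}"
        )
    merged = AffinityRecord(smiles, SOURCE_ZINC, zinc_rec.target, pKi=zinc_rec.pKi)
    return merged, AuditEntry(
        smiles,
        "merged",
        f"cross-database pKi difference {delta:g} <= {CROSS_DB_TOLERANCE}; ZINC value kept",
    )


def curate(
    zinc_records: Sequence[AffinityRecord],
    chembl_records: Sequence[AffinityRecord],
) -> CuratedDataset:
    """Run the full curation pipeline on two per-source record lists.

    Order of operations: per-source deduplication, then cross-database
    reconciliation of molecules present in both sources.  Molecules in a
    single source pass through unchanged.
    """
    zinc_dedup, audit = deduplicate_within_source(zinc_records)
    chembl_dedup, chembl_audit = deduplicate_within_source(chembl_records)
    audit = list(audit) + list(chembl_audit)

    zinc_map = {r.canonical_smiles: r for r in zinc_dedup}
    chembl_map = {r.canonical_smiles: r for r in chembl_dedup}

    curated: List[AffinityRecord] = []
    for smiles, zrec in zinc_map.items():
        if smiles in chembl_map:
            merged, entry = reconcile_cross_db(zrec, chembl_map[smiles])
            audit.append(entry)
            if merged is not None:
                curated.append(merged)
        else:
            curated.append(zrec)
            audit.append(AuditEntry(smiles, "kept", "ZINC only"))
    for smiles, crec in chembl_map.items():
        if smiles not in zinc_map:
            curated.append(crec)
            audit.append(AuditEntry(smiles, "kept", "ChEMBL only"))
    return CuratedDataset(records=curated, audit_log=audit)


def curate_single_source(records: Sequence[AffinityRecord]) -> CuratedDataset:
    """Curation for single-source (typically classification) tables:
    within-source deduplication only, no cross-database step."""
    kept, audit = deduplicate_within_source(records)
    return CuratedDataset(records=kept, audit_log=audit)


def train_size(n_records: int, ratio: float = 0.8) -> int:
    """Half-up rounding of ``ratio * n``; the remainder goes to test."""
    return int(math.floor(ratio * n_records + 0.5))


def split_train_test(
    curated: CuratedDataset, ratio: float = 0.8, seed: int = 0
) -> SplitDataset:
    """Uniform random, unstratified partition into train and test.

    Deterministic for a given seed; the seed is recorded on both the
    curated dataset and the split for provenance.
    """
    n = len(curated.records)
    if n < 5:
        raise CurationError(f"need at least 5 records to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise CurationError(f"split ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = train_size(n, ratio)
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(curated.records) if i in train_idx]
    test = [r for i, r in enumerate(curated.records) if i not in train_idx]
    curated.split_seed = seed
    return SplitDataset(train=train, test=test, ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# CSV interchange in the per-endpoint train/test layout
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "smiles": r.canonical_smiles,
                "source": r.source,
                "target": r.target,
                "pKi": r.pKi if r.pKi is not None else "",
                "label": r.class_label if r.class_label is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=["smiles", "source", "target", "pKi", "label"])


def records_from_frame(
    frame: pd.DataFrame, target: str, source: str = SOURCE_OTHER
) -> Tuple[List[AffinityRecord], List[AuditEntry]]:
    """Build records from a CSV frame, validating SMILES.

    Invalid SMILES rows are dropped with an audit entry rather than
    raising: unparseable structures are expected dirt in bioactivity
    exports.  The value column is ``pKi`` for affinity endpoints and
    ``label`` for classification endpoints.
    """
    if "smiles" not in frame.columns:
        raise CurationError("record table must have a 'smiles' column")
    is_classification = target in CLASSIFICATION_TARGETS
    value_col = "label" if is_classification else "pKi"
    if value_col not in frame.columns:
        raise CurationError(f"record table for {target} must have a {value_col!r} column")

    has_source = "source" in frame.columns
    records: List[AffinityRecord] = []
    audit: List[AuditEntry] = []
    for i, (raw, value) in enumerate(zip(frame["smiles"].tolist(), frame[value_col].tolist())):
        parsed = validate_smiles(raw)
        if not parsed.valid:
            audit.append(AuditEntry(str(raw), "dropped", "invalid SMILES"))
            continue
        row_source = str(frame["source"].iloc[i]) if has_source else source
        if is_classification:
            records.append(
                AffinityRecord(parsed.canonical_smiles, row_source, target,
                               class_label=int(value))
            )
        else:
            records.append(
                AffinityRecord(parsed.canonical_smiles, row_source, target, pKi=float(value))
            )
    return records, audit


def write_split_csvs(split: SplitDataset, target: str, out_dir: str) -> Tuple[str, str]:
    """Write ``<target>_train.csv`` / ``<target>_test.csv`` under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    safe = target.replace("/", "_")
    train_path = os.path.join(out_dir, f"{safe}_train.csv")
    test_path = os.path.join(out_dir, f"{safe}_test.csv")
    records_to_frame(split.train).to_csv(train_path, index=False)
    records_to_frame(split.test).to_csv(test_path, index=False)
    return train_path, test_path


def load_endpoint_csvs(data_dir: str, target: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Load a per-endpoint train/test CSV pair from ``data_dir``.

    Accepts either this package's ``<target>_train.csv`` naming or the
    common ``<target>_training.csv`` variant.
    """
    candidates_train = [f"{target}_train.csv", f"{target}_training.csv"]
    candidates_test = [f"{target}_test.csv"]
    train_path = next(
        (os.path.join(data_dir, c) for c in candidates_train
         if os.path.exists(os.path.join(data_dir, c))),
        None,
    )
    test_path = next(
        (os.path.join(data_dir, c) for c in candidates_test
         if os.path.exists(os.path.join(data_dir, c))),
        None,
    )
    if train_path is None or test_path is None:
        raise FileNotFoundError(
            f"no train/test CSV pair for endpoint {target!r} under {data_dir!r}"
        )
    return pd.read_csv(train_path), pd.read_csv(test_path)
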