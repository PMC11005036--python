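"""Chemical structure parsing, CSV I/O and model-bundle persistence.

SMILES handling is deliberately minimal: a structure is either parseable
or it is not, and parseable structures are canonicalized.  No salt
stripping, neutralization or tautomer normalization is performed — the
validity check and canonical form are the only curation applied to
structures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, List, Optional

import joblib
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

# RDKit logs every parse failure to stderr; invalidity is data here, not noise.
RDLogger.DisableLog("rdApp.error")

#: Required batch-input column, matched case-sensitively.
SMILES_COLUMN = "smiles"

#: Bundle archive format; bumped on any incompatible layout change.
BUNDLE_FORMAT_VERSION = 1


class ColumnContractError(ValueError):
    """The batch CSV does not satisfy the required column contract."""


class BundleLoadError(RuntimeError):
    """A model bundle could not be restored from disk."""


@dataclass(frozen=True)
class MoleculeInput:
    """One parsed (or unparseable) structure from user input.

    ``valid`` is True iff ``raw_smiles`` parses to a molecular graph;
    ``canonical_smiles`` is non-empty iff valid.
    """

    raw_smiles: str
    canonical_smiles: str
    valid: bool


@dataclass
class BatchTable:
    """Rows of a batch CSV, in file order, with validity annotations."""

    rows: List[MoleculeInput]
    source_path: str
    extra_columns: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.rows)


def validate_smiles(raw: Any) -> MoleculeInput:
    """Parse ``raw`` as SMILES and return its validation record.

    Never raises on unparseable input: invalidity is reported through the
    ``valid`` flag.  Canonicalization is idempotent — canonicalizing the
    returned ``canonical_smiles`` reproduces it exactly.
    """
    text = raw if isinstance(raw, str) else ("" if raw is None or raw != raw else str(raw))
    mol = Chem.MolFromSmiles(text) if text else None
    if mol is None:
        return MoleculeInput(raw_smiles=text, canonical_smiles="", valid=False)
    return MoleculeInput(raw_smiles=text, canonical_smiles=Chem.MolToSmiles(mol), valid=True)


def mol_from_input(molecule: MoleculeInput) -> Chem.Mol:
    """Return the RDKit molecule for a validated input."""
    if not molecule.valid:
        raise ValueError(f"cannot build a molecule from invalid SMILES {molecule.raw_smiles!r}")
    return Chem.MolFromSmiles(molecule.canonical_smiles)


def read_batch_csv(path: str) -> BatchTable:
    """Read a prediction batch CSV.

    The file must contain a column named exactly ``smiles`` (lowercase).
    Row order is preserved; all other columns are carried through
    untouched in ``extra_columns``.
    """
    frame = pd.read_csv(path)
    if SMILES_COLUMN not in frame.columns:
        near = [c for c in frame.columns if c.strip().lower() == SMILES_COLUMN]
        hint = (
            f" (found {near[0]!r}; rename it to {SMILES_COLUMN!r})"
            if near
            else f" (columns present: {list(frame.columns)})"
        )
        raise ColumnContractError(
            f"batch CSV {path!r} must contain a column named {SMILES_COLUMN!r}{hint}"
        )
    rows = [validate_smiles(value) for value in frame[SMILES_COLUMN].tolist()]
    extra = frame.drop(columns=[SMILES_COLUMN])
    return BatchTable(rows=rows, source_path=str(path), extra_columns=extra)


def write_batch_csv(table: BatchTable, path: str) -> None:
    """Write a batch table back to CSV, preserving row order and extras."""
    frame = table.extra_columns.copy()
    frame.insert(0, SMILES_COLUMN, [m.raw_smiles for m in table.rows])
    frame["canonical_smiles"] = [m.canonical_smiles for m in table.rows]
    frame["valid_smiles"] = [m.valid for m in table.rows]
    frame.to_csv(path, index=False)


def save_bundle(bundle: Any, path: str) -> None:
    """Persist a trained model bundle as a versioned joblib archive."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "kind": "qsarkit-model-bundle",
        "bundle": bundle,
    }
    joblib.dump(payload, path, compress=3)


def load_bundle(path: str) -> Any:
    """Restore a bundle written by :func:`save_bundle`.

    Raises :class:`BundleLoadError` on missing files, truncated archives
    or format-version mismatch, so stale artifacts fail loudly instead of
    predicting garbage.
    """
    if not os.path.exists(path):
        raise BundleLoadError(f"no bundle at {path!r}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / truncated archive
        raise BundleLoadError(f"could not read bundle {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "qsarkit-model-bundle":
        raise BundleLoadError(f"{path!r} is not a qsarkit model bundle")
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleLoadError(
            f"bundle {path!r} has format version {version}, "
            f"this build reads version {BUNDLE_FORMAT_VERSION}"
        )
    return payload["bundle"]
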