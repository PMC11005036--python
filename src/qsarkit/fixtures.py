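"""Synthetic structure–activity datasets with known ground truth.

Molecules come from a deterministic combinatorial enumeration of
drug-like aryl-alkyl amines/alcohols — five aromatic cores, fourteen
ring substituents, variable chain length and branching, five chain
heads — so every structure is valid and canonically unique without a
rejection loop.  Varying the ring substitution, chain length and head
group independently makes lipophilicity (MolLogP), polar surface area
(TPSA) and flexibility (NumRotatableBonds) vary quasi-independently,
which is exactly where the activity signal is planted.

Labels are generated from *real computed descriptors*, so descriptor
filtering and Shapley ranking have a known ground truth: the planted
descriptors must carry the signal.  Regression labels emulate a
receptor-affinity table — pKi centered at 7 with spread ≈1.5 log units,
kept inside [3, 12] by a bounded (tanh) link — plus Gaussian
measurement noise.  Classification labels emulate a binary permeability
endpoint via a logistic model on the same score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_io import MoleculeInput, validate_smiles
from .curation import (
    SOURCE_CHEMBL,
    SOURCE_ZINC,
    AffinityRecord,
    CuratedDataset,
    SplitDataset,
    records_to_frame,
    split_train_test,
)
from .descriptors import DescriptorMatrix, compute_descriptors

#: Descriptors that carry the planted signal, in order of use.
SIGNAL_DESCRIPTOR_POOL = ("MolLogP", "TPSA", "NumRotatableBonds", "NumHDonors", "RingCount")

#: Generative coefficients applied to the standardized signal descriptors.
SIGNAL_COEFFICIENTS = (1.0, -0.7, 0.5, 0.4, -0.3)

_ARYL_TEMPLATES = (
    "c1ccc({s})cc1",   # para-substituted benzene
    "c1cccc({s})c1",   # meta-substituted benzene
    "c1cc({s})cs1",    # thiophene
    "c1cc({s})co1",    # furan
    "c1ccc({s})cn1",   # pyridine
)
_RING_SUBSTITUENTS = (
    "", "F", "Cl", "Br", "C", "CC", "O", "OC", "C#N",
    "C(F)(F)F", "[N+](=O)[O-]", "C(C)C", "S(C)(=O)=O", "OC(F)(F)F",
)
_CHAIN_HEADS = ("N", "CN", "CN(C)", "O", "CO")  # primary/secondary/tertiary amine, alcohol, ether
_CHAIN_LENGTHS = (2, 3, 4, 5, 6, 7)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic endpoint table."""

    n_molecules: int = 2000
    seed: int = 0
    task: str = "regression"
    noise_sigma: float = 0.3          # pKi log units
    signal_descriptors: int = 3
    class_balance: float = 0.5
    # dual-source composition for curation exercises
    frac_disagree: float = 0.2
    agree_delta: float = 0.05          # |ΔpKi| within the reconciliation tolerance
    disagree_delta: float = 0.2        # |ΔpKi| beyond it

    def __post_init__(self) -> None:
        if self.n_molecules < 20:
            raise FixtureError("fixtures need at least 20 molecules")
        if self.noise_sigma < 0:
            raise FixtureError("noise sigma must be non-negative")
        if not 0.0 < self.class_balance < 1.0:
            raise FixtureError("class balance must lie in (0, 1)")
        if not 0.0 <= self.frac_disagree <= 1.0:
            raise FixtureError("disagreement fraction must lie in [0, 1]")
        if not 1 <= self.signal_descriptors <= len(SIGNAL_DESCRIPTOR_POOL):
            raise FixtureError(
                f"signal_descriptors must be in [1, {len(SIGNAL_DESCRIPTOR_POOL)}]"
            )


@dataclass
class GenerativeInfo:
    """Ground truth behind a generated label set, for recovery tests."""

    signal_names: List[str]
    coefficients: List[float]
    clean_values: np.ndarray           # noiseless pKi, or latent score for classification
    noise_sigma: float
    threshold: Optional[float] = None  # classification cut on the latent score


def _enumerate_family() -> List[str]:
    """The full combinatorial SMILES family, in fixed enumeration order,
    canonically deduplicated (keep-first)."""
    seen = {}
    for head in _CHAIN_HEADS:
        for k in _CHAIN_LENGTHS:
            for branched in (False, True):
                chain = ("C(C)" + "C" * (k - 1)) if branched else "C" * k
                for aryl in _ARYL_TEMPLATES:
                    for sub in _RING_SUBSTITUENTS:
                        ring = aryl.replace("({s})", "") if sub == "" else aryl.format(s=sub)
                        smiles = head + chain + ring
                        parsed = validate_smiles(smiles)
                        if parsed.valid and parsed.canonical_smiles not in seen:
                            seen[parsed.canonical_smiles] = parsed
    return list(seen.keys())


_FAMILY_CACHE: Optional[List[str]] = None


def family_size() -> int:
    global _FAMILY_CACHE
    if _FAMILY_CACHE is None:
        _FAMILY_CACHE = _enumerate_family()
    return len(_FAMILY_CACHE)


def generate_molecules(n: int, seed: int = 0) -> List[MoleculeInput]:
    """``n`` unique, valid molecules, deterministically chosen by seed."""
    if n < 1:
        raise FixtureError("need n >= 1")
    size = family_size()
    if n > size:
        raise FixtureError(f"requested {n} molecules but the family holds {size}")
    pool = list(_FAMILY_CACHE)  # type: ignore[arg-type]
    rng = np.random.default_rng(seed)
    order = rng.permutation(size)[:n]
    return [validate_smiles(pool[i]) for i in order]


def _signal_matrix(
    matrix: DescriptorMatrix, spec: FixtureSpec
) -> Tuple[np.ndarray, List[str]]:
    names = list(SIGNAL_DESCRIPTOR_POOL[: spec.signal_descriptors])
    col_index = {n: j for j, n in enumerate(matrix.descriptor_names)}
    cols = []
    for name in names:
        col = matrix.values[:, col_index[name]]
        std = float(np.std(col))
        if not np.isfinite(std) or std == 0.0:
            raise FixtureError(f"signal descriptor {name} is degenerate on this set")
        cols.append((col - col.mean()) / std)
    return np.column_stack(cols), names


def generate_labels(
    molecules: Sequence[MoleculeInput],
    spec: FixtureSpec,
    matrix: Optional[DescriptorMatrix] = None,
) -> Tuple[np.ndarray, GenerativeInfo]:
    """Labels from a linear model on standardized planted descriptors.

    Regression: pKi = 7 + 3.2·tanh(score/2) + N(0, σ), clipped to the
    [3, 12] envelope (the clip is part of the generative function and is
    essentially never active).  Classification: Bernoulli draws from a
    logistic model on the score, thresholded at the quantile matching
    ``class_balance``.
    """
    if matrix is None:
        matrix = compute_descriptors(molecules)
    Z, names = _signal_matrix(matrix, spec)
    coefs = list(SIGNAL_COEFFICIENTS[: spec.signal_descriptors])
    score = Z @ np.asarray(coefs)
    score = (score - score.mean()) / np.std(score)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))

    if spec.task == "regression":
        clean = 7.0 + 3.2 * np.tanh(score / 2.0)
        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=len(score))
        labels = np.clip(noisy, 3.0, 12.0)
        return labels, GenerativeInfo(names, coefs, clean, spec.noise_sigma)

    threshold = float(np.quantile(score, 1.0 - spec.class_balance))
    prob = 1.0 / (1.0 + np.exp(-(score - threshold) / 0.5))
    labels = (rng.random(len(score)) < prob).astype(int)
    return labels, GenerativeInfo(names, coefs, score, 0.0, threshold=threshold)


def generate_dual_source(
    molecules: Sequence[MoleculeInput],
    spec: FixtureSpec,
    target: str = "SERT",
) -> Tuple[List[AffinityRecord], List[AffinityRecord], Dict[str, int]]:
    """Paired reference/secondary record sets with known reconciliation
    outcome.

    Every molecule appears in both sources.  A seeded fraction
    ``frac_disagree`` of the secondary records is shifted by
    ``disagree_delta`` (beyond the cross-database tolerance, so the pair
    is dropped); the remainder by ``agree_delta`` (within it, so the
    reference value is kept).  Returns (reference_records,
    secondary_records, expected_counts).
    """
    labels, _ = generate_labels(molecules, spec)
    n = len(molecules)
    n_disagree = int(round(spec.frac_disagree * n))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    disagree = np.zeros(n, dtype=bool)
    disagree[rng.permutation(n)[:n_disagree]] = True

    zinc, chembl = [], []
    for i, mol in enumerate(molecules):
        pki = float(labels[i])
        delta = spec.disagree_delta if disagree[i] else spec.agree_delta
        zinc.append(AffinityRecord(mol.canonical_smiles, SOURCE_ZINC, target, pKi=pki))
        chembl.append(
            AffinityRecord(mol.canonical_smiles, SOURCE_CHEMBL, target, pKi=pki + delta)
        )
    expected = {"kept": n - n_disagree, "dropped": n_disagree, "pairs": n}
    return zinc, chembl, expected


def generate_endpoint_tables(
    spec: FixtureSpec, target: str = "SERT", ratio: float = 0.8
) -> Tuple[pd.DataFrame, pd.DataFrame, GenerativeInfo]:
    """A ready train/test CSV pair in the per-endpoint layout
    (columns smiles, source, target, pKi/label)."""
    molecules = generate_molecules(spec.n_molecules, spec.seed)
    labels, info = generate_labels(molecules, spec)
    records = []
    for mol, value in zip(molecules, labels):
        if spec.task == "regression":
            records.append(
                AffinityRecord(mol.canonical_smiles, SOURCE_ZINC, target, pKi=float(value))
            )
        else:
            records.append(
                AffinityRecord(
                    mol.canonical_smiles, SOURCE_ZINC, target, class_label=int(value)
                )
            )
    split = split_train_test(CuratedDataset(records=records), ratio=ratio, seed=spec.seed)
    return records_to_frame(split.train), records_to_frame(split.test), info
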