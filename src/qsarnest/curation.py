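"""Curation of compound activity tables.

Reads raw id/SMILES/IC50 tables, standardizes structures (largest covalent
fragment, charge neutralization, canonical SMILES), merges duplicate
structures onto the median IC50, converts IC50 (nM) to pIC50, splits into
training and test sets, and computes drug-likeness (Lipinski) failure
counts.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.MolStandardize import rdMolStandardize


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed."""


@dataclass(frozen=True)
class CompoundRecord:
    """One curated compound: identifier, canonical SMILES, IC50 and pIC50.

    ``ic50_nM`` is the half-maximal inhibitory concentration in nanomolar;
    ``pic50`` is the negative decadic logarithm of the molar concentration,
    i.e. ``9 - log10(ic50_nM)``.
    """

    id: str
    smiles: str
    ic50_nM: float
    pic50: float

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"record {self.id!r}: empty SMILES")
        if not self.ic50_nM > 0:
            raise ValueError(f"record {self.id!r}: IC50 must be positive, got {self.ic50_nM}")
        if abs(self.pic50 - to_pic50(self.ic50_nM)) > 1e-9:
            raise ValueError(
                f"record {self.id!r}: pIC50 {self.pic50} inconsistent with IC50 {self.ic50_nM} nM"
            )


@dataclass
class CuratedDataset:
    """Deduplicated compound records with split labels and a provenance log."""

    records: list[CompoundRecord]
    split: list[str] = field(default_factory=list)  # per-record: train|test|unsplit
    provenance_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split:
            self.split = ["unsplit"] * len(self.records)
        if len(self.split) != len(self.records):
            raise ValueError("split labels must align with records")
        keys = [r.smiles for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate structure keys in curated dataset")

    def assign_split(self, train_idx, test_idx) -> None:
        labels = ["unsplit"] * len(self.records)
        for i in train_idx:
            labels[int(i)] = "train"
        for i in test_idx:
            labels[int(i)] = "test"
        self.split = labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ic50_nM": [r.ic50_nM for r in self.records],
                "pic50": [r.pic50 for r in self.records],
                "split": self.split,
            }
        )


@dataclass(frozen=True)
class PropertyProfile:
    """Physicochemical profile used for drug-likeness assessment."""

    mw: float  # g/mol
    alogp: float  # Ghose-Crippen atomic logP, unitless
    hbd: int  # H-bond donors
    hba: int  # H-bond acceptors
    rotatable_bonds: int

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError("molecular weight must be positive")
        if min(self.hbd, self.hba, self.rotatable_bonds) < 0:
            raise ValueError("counts must be non-negative")


def to_pic50(ic50_nM: float) -> float:
    """Convert IC50 in nanomolar to pIC50 = -log10(molar IC50) = 9 - log10(IC50 nM)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str, canonical_tautomer: bool = False) -> str:
    """Canonical structure key: largest covalent fragment, neutralized.

    Parses the SMILES, keeps the largest covalent fragment (most heavy
    atoms; ties broken by the longer canonical SMILES, then the
    lexicographically later one), neutralizes protonation-only charges and
    returns the canonical SMILES. Salt forms therefore collapse onto their
    parent acid/base. Optionally canonicalizes the tautomer (off by
    default: tautomer rule sets differ between toolkits).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    ranked = sorted(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), len(Chem.MolToSmiles(m)), Chem.MolToSmiles(m)),
    )
    best = ranked[-1]
    best = _uncharger.uncharge(best)
    if canonical_tautomer:
        best = rdMolStandardize.TautomerEnumerator().Canonicalize(best)
    return Chem.MolToSmiles(best)


def read_activity_table(
    path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    ic50_col: str = "ic50_nM",
    log: list | None = None,
) -> list[CompoundRecord]:
    """Read a raw activity CSV into compound records.

    Rows with unparsable SMILES or missing/non-positive IC50 are dropped;
    each drop is appended to ``log`` (if given) with its reason. SMILES are
    standardized on the way in.
    """
    table = pd.read_csv(path, dtype={id_col: str})
    for col in (id_col, smiles_col, ic50_col):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    records: list[CompoundRecord] = []
    for _, row in table.iterrows():
        cid = str(row[id_col])
        ic50 = pd.to_numeric(row[ic50_col], errors="coerce")
        if pd.isna(ic50):
            _log_drop(log, cid, "missing or non-numeric IC50")
            continue
        if not ic50 > 0:
            _log_drop(log, cid, f"non-positive IC50 ({ic50})")
            continue
        raw_smiles = row[smiles_col]
        if not isinstance(raw_smiles, str) or not raw_smiles.strip():
            _log_drop(log, cid, "missing SMILES")
            continue
        try:
            smiles = standardize_structure(raw_smiles.strip())
        except SmilesParseError:
            _log_drop(log, cid, f"unparsable SMILES ({raw_smiles!r})")
            continue
        records.append(
            CompoundRecord(id=cid, smiles=smiles, ic50_nM=float(ic50), pic50=to_pic50(float(ic50)))
        )
    return records


def _log_drop(log: list | None, cid: str, reason: str) -> None:
    if log is not None:
        log.append({"action": "drop", "id": cid, "reason": reason})


def deduplicate(records: list[CompoundRecord]) -> CuratedDataset:
    """Merge records sharing a structure key onto the median IC50.

    The merged IC50 is the median of the duplicates' IC50 values (midpoint
    of the two central values for an even count); pIC50 is recomputed from
    the merged IC50 rather than averaged.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles not in groups:
            groups[rec.smiles] = []
            order.append(rec.smiles)
        groups[rec.smiles].append(rec)
    merged: list[CompoundRecord] = []
    log: list[dict] = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            merged.append(members[0])
            continue
        med = float(statistics.median([m.ic50_nM for m in members]))
        keeper = replace(members[0], ic50_nM=med, pic50=to_pic50(med))
        merged.append(keeper)
        log.append(
            {
                "action": "merge",
                "ids": [m.id for m in members],
                "structure": key,
                "median_ic50_nM": med,
            }
        )
    return CuratedDataset(records=merged, provenance_log=log)


def split_train_test(n: int, ratio: float = 0.75, seed: int = 0):
    """Random train/test split: train size = floor(n * ratio), remainder test.

    Deterministic for a given seed; train and test index arrays are
    disjoint and exhaustive.
    """
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(n * ratio))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def property_profile(smiles: str) -> PropertyProfile:
    """Compute the drug-likeness property profile of a compound."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return PropertyProfile(
        mw=Descriptors.MolWt(mol),
        alogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
    )


def lipinski_failures(profile: PropertyProfile, fifth_check: str | None = "rotatable_bonds") -> int:
    """Count violations of the rule-of-five style drug-likeness bounds.

    Checks MW <= 500, ALogP <= 5, HBD <= 5, HBA <= 10 and, when
    ``fifth_check='rotatable_bonds'``, rotatable bonds <= 10. Pass
    ``fifth_check=None`` for the canonical four-rule variant (maximum 4
    failures).
    """
    failures = 0
    failures += profile.mw > 500
    failures += profile.alogp > 5
    failures += profile.hbd > 5
    failures += profile.hba > 10
    if fifth_check == "rotatable_bonds":
        failures += profile.rotatable_bonds > 10
    elif fifth_check is not None:
        raise ValueError(f"unknown fifth check {fifth_check!r}")
    return int(failures)
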