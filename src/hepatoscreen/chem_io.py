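"""Compound record I/O, structure standardization and name normalization.

Compound tables arrive as CSV (columns ``id,name,smiles,label``), SMILES files
(``SMILES<TAB>id`` per line) or SDF. Labels are normalized to the three-value
vocabulary {hepatotoxic, non_hepatotoxic, unknown}; structures are standardized
to a canonical parent (largest fragment, charges neutralized) whose canonical
SMILES serves as the deduplication key. Unparseable structures are retained
with a warning flag so that name-based screening still covers them.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "CompoundRecord",
    "Dataset",
    "DataFormatError",
    "read_compounds",
    "write_compounds",
    "normalize_name",
    "deduplicate",
    "standardize_smiles",
]

HEPATOTOXIC = "hepatotoxic"
NON_HEPATOTOXIC = "non_hepatotoxic"
UNKNOWN = "unknown"

#: accepted spellings for each internal label
_LABEL_ALIASES = {
    HEPATOTOXIC: {"1", "pos", "positive", "hepatotoxic", "toxic", "true", "yes"},
    NON_HEPATOTOXIC: {
        "0",
        "neg",
        "negative",
        "non_hepatotoxic",
        "non-hepatotoxic",
        "nonhepatotoxic",
        "nontoxic",
        "non-toxic",
        "false",
        "no",
    },
    UNKNOWN: {"", "unknown", "na", "nan", "none", "?"},
}


class DataFormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def normalize_label(raw: object) -> str:
    """Map a raw label spelling onto the internal three-value vocabulary."""
    text = str(raw).strip().lower()
    for canonical, aliases in _LABEL_ALIASES.items():
        if text in aliases:
            return canonical
    raise DataFormatError(f"unrecognized hepatotoxicity label: {raw!r}")


def normalize_name(raw: str) -> str:
    """Canonicalize a free-text compound/herb name for dictionary matching.

    Case-folds, strips surrounding whitespace, maps hyphens to spaces and
    collapses internal whitespace runs. Idempotent.

    >>> normalize_name("Aloe-Emodin")
    'aloe emodin'
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("name must be a non-empty string")
    text = raw.casefold().replace("-", " ")
    return re.sub(r"\s+", " ", text).strip()


def standardize_smiles(smiles: str) -> Optional[str]:
    """Canonical SMILES of the standardized parent structure, or None.

    Keeps the largest organic fragment (salt/solvent stripping) and
    neutralizes charges before canonicalization. Returns None when RDKit
    cannot parse the input.
    """
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception:  # standardization failure: fall back to the parsed mol
        pass
    return Chem.MolToSmiles(mol)


@dataclass
class CompoundRecord:
    """One compound: identifiers, structure, label and provenance."""

    compound_id: str
    name: str = ""
    smiles: Optional[str] = None
    structure_key: Optional[str] = None
    label: str = UNKNOWN
    source: tuple[str, ...] = ()
    probability: Optional[float] = None
    parse_failed: bool = False

    def __post_init__(self) -> None:
        if self.label not in (HEPATOTOXIC, NON_HEPATOTOXIC, UNKNOWN):
            self.label = normalize_label(self.label)
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability outside [0,1]: {self.probability}")

    @property
    def key(self) -> str:
        """Deduplication key: structure key when known, normalized name otherwise."""
        return self.structure_key or normalize_name(self.name or self.compound_id)


@dataclass
class Dataset:
    """Ordered collection of compound records with derived class counts."""

    records: list[CompoundRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(r.label for r in self.records)
        return {k: counts.get(k, 0) for k in (HEPATOTOXIC, NON_HEPATOTOXIC, UNKNOWN)}

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def labels(self, positive: str = HEPATOTOXIC) -> list[int]:
        """Binary label vector (1 = hepatotoxic)."""
        return [1 if r.label == positive else 0 for r in self.records]

    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate compound ids: {dupes[:5]}")


def _attach_structure_keys(records: list[CompoundRecord]) -> None:
    for i, rec in enumerate(records):
        if rec.smiles and rec.structure_key is None:
            key = standardize_smiles(rec.smiles)
            if key is None:
                records[i] = replace(rec, smiles=None, parse_failed=True)
                warnings.warn(
                    f"unparseable SMILES for compound {rec.compound_id!r}; "
                    "record retained without structure"
                )
            else:
                records[i] = replace(rec, structure_key=key)


def _read_csv(path: Path) -> list[CompoundRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        fields = {f.strip().lower() for f in reader.fieldnames}
        for required in ("id", "name", "smiles"):
            if required not in fields:
                raise DataFormatError(f"CSV compound table missing column {required!r}")
        has_label = "label" in fields
        records = []
        for row in reader:
            row = {k.strip().lower(): (v or "") for k, v in row.items() if k}
            records.append(
                CompoundRecord(
                    compound_id=row["id"].strip(),
                    name=row["name"].strip(),
                    smiles=row["smiles"].strip() or None,
                    label=normalize_label(row.get("label", "")) if has_label else UNKNOWN,
                    source=(str(path.name),),
                )
            )
    return records


def _read_smiles(path: Path) -> list[CompoundRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            smiles = parts[0].strip()
            cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            records.append(
                CompoundRecord(compound_id=cid, name=cid, smiles=smiles or None,
                               source=(str(path.name),))
            )
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                CompoundRecord(compound_id=f"sdf{i}", name=f"sdf{i}",
                               parse_failed=True, source=(str(path.name),))
            )
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"
        records.append(
            CompoundRecord(
                compound_id=name or f"sdf{i}",
                name=name or f"sdf{i}",
                smiles=Chem.MolToSmiles(mol),
                source=(str(path.name),),
            )
        )
    return records


def read_compounds(path: str | Path, format: str = "csv") -> Dataset:
    """Read a compound table into a :class:`Dataset`.

    Unparseable structures are retained with ``parse_failed=True`` and the
    SMILES cleared; record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"csv": _read_csv, "smiles": _read_smiles, "sdf": _read_sdf}
    if format not in readers:
        raise ValueError(f"unknown compound format {format!r}; expected one of {sorted(readers)}")
    records = readers[format](path)
    if format != "sdf":
        _attach_structure_keys(records)
    return Dataset(records)


def write_compounds(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as the canonical CSV compound table."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "smiles", "label"])
        for rec in ds:
            writer.writerow([rec.compound_id, rec.name, rec.smiles or "", rec.label])


def deduplicate(ds: Dataset, policy: str = "keep_first") -> tuple[Dataset, dict]:
    """Collapse duplicate records sharing a structure/name key.

    ``keep_first`` retains the first occurrence of each key.
    ``drop_conflicts`` additionally removes keys whose duplicates carry
    contradictory (hepatotoxic vs non-hepatotoxic) labels entirely.
    Returns the reduced dataset and a report of removed keys.
    """
    if policy not in ("keep_first", "drop_conflicts"):
        raise ValueError(f"unknown deduplication policy {policy!r}")
    by_key: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in ds:
        k = rec.key
        if k not in by_key:
            by_key[k] = []
            order.append(k)
        by_key[k].append(rec)

    conflicts = []
    dropped_dupes = []
    kept = []
    for k in order:
        group = by_key[k]
        labels = {r.label for r in group if r.label != UNKNOWN}
        if policy == "drop_conflicts" and len(labels) > 1:
            conflicts.append(k)
            continue
        kept.append(group[0])
        dropped_dupes.extend(r.compound_id for r in group[1:])
    report = {"conflicting_keys": conflicts, "dropped_duplicate_ids": dropped_dupes}
    return Dataset(kept), report
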