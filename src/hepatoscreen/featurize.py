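"""Per-family molecular feature matrices behind a pluggable backend contract.

Thirteen descriptor/fingerprint families are supported: twelve binary
fingerprint families (path, extended-connectivity, electrotopological-state,
graph-only, MACCS keys, PubChem-style, substructure presence/count,
Klekota-Roth presence/count, 2D atom-pair presence/count) and one continuous
2D-descriptor family. The calculator is a contract: any object exposing
``supports(family)`` and ``featurize_one(smiles, family)`` can stand behind
``compute_features``. Two backends ship with the package:

* :class:`RDKitBackend` — the reference backend, computing native RDKit
  fingerprints/descriptors (exact published widths for the
  electrotopological-state and MACCS families, hashed fingerprints at the
  published widths elsewhere);
* :class:`HashedBackend` — a dependency-light fallback hashing SMILES
  substrings into bits plus a small constitutional-descriptor block, so the
  full pipeline is exercisable without a chemistry toolkit.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

import numpy as np
import pandas as pd

from .chem_io import Dataset

__all__ = [
    "FAMILIES",
    "FAMILY_WIDTHS",
    "FeatureMatrix",
    "FeaturizerBackend",
    "RDKitBackend",
    "HashedBackend",
    "compute_features",
    "drop_degenerate",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: family tag -> (reference raw width, value kind)
FAMILY_WIDTHS: dict[str, tuple[int, str]] = {
    "FP": (1024, "binary"),
    "ExtFP": (1024, "binary"),
    "EStateFP": (79, "binary"),
    "GraphFP": (1024, "binary"),
    "MACCSFP": (166, "binary"),
    "PubchemFP": (881, "binary"),
    "SubFP": (307, "binary"),
    "SubFPC": (307, "binary"),
    "KRFP": (4860, "binary"),
    "KRFPC": (4860, "binary"),
    "AP2D": (780, "binary"),
    "APC2D": (780, "binary"),
    "2D Descriptor": (1444, "continuous"),
}

FAMILIES: tuple[str, ...] = tuple(FAMILY_WIDTHS)


@dataclass
class FeatureMatrix:
    """Compounds x named features for one descriptor family."""

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    family: str
    value_kind: str  # "binary" | "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.row_ids), -1)
        n, p = self.values.shape
        if n != len(self.row_ids) or p != len(self.feature_names):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.row_ids)} rows, {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if self.value_kind == "binary":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError("binary family contains non-0/1 values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset, preserving the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.row_ids, list(names), self.values[:, idx],
                             self.family, self.value_kind)

    def subset_rows(self, positions: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix([self.row_ids[i] for i in positions],
                             self.feature_names, self.values[positions],
                             self.family, self.value_kind)


class FeaturizerBackend(Protocol):
    """Contract for descriptor calculators."""

    name: str

    def supports(self, family: str) -> bool: ...

    def featurize_one(self, smiles: str, family: str) -> Optional[np.ndarray]:
        """Feature vector for one structure, or None on failure."""

    def feature_names(self, family: str) -> list[str]: ...


class HashedBackend:
    """Fallback calculator: hashed SMILES n-gram bits + constitutional block.

    Binary families hash character n-grams (n = 2..6) of the SMILES string
    into the family's published bit width; distinct families use distinct
    hash salts so their bit patterns are decorrelated. The continuous family
    emits simple constitutional counts (atom/bond/ring symbol tallies).
    """

    name = "hashed"

    _CONSTITUTIONAL = [
        "n_chars", "n_C", "n_c", "n_N", "n_O", "n_S", "n_P", "n_halogen",
        "n_ring_closure", "n_branch", "n_double", "n_triple", "n_aromatic",
        "n_charge", "frac_hetero", "frac_aromatic",
    ]

    def supports(self, family: str) -> bool:
        return family in FAMILY_WIDTHS

    def feature_names(self, family: str) -> list[str]:
        if FAMILY_WIDTHS[family][1] == "continuous":
            return list(self._CONSTITUTIONAL)
        width = FAMILY_WIDTHS[family][0]
        tag = family.replace(" ", "")
        return [f"{tag}_{i}" for i in range(width)]

    def featurize_one(self, smiles: str, family: str) -> Optional[np.ndarray]:
        if not smiles:
            return None
        width, kind = FAMILY_WIDTHS[family]
        if kind == "continuous":
            return self._constitutional(smiles)
        bits = np.zeros(width)
        salt = family.encode()
        for n in range(2, 7):
            for i in range(max(1, len(smiles) - n + 1)):
                gram = smiles[i : i + n].encode()
                h = hashlib.blake2b(gram, digest_size=8, salt=salt[:8].ljust(8, b"\0"))
                bits[int.from_bytes(h.digest(), "big") % width] = 1.0
        return bits

    def _constitutional(self, smiles: str) -> np.ndarray:
        s = smiles
        halogens = sum(s.count(x) for x in ("F", "Cl", "Br", "I"))
        aromatic = sum(s.count(x) for x in "cnos")
        hetero = sum(s.count(x) for x in "NOSPnos")
        vals = [
            len(s), s.count("C"), s.count("c"), s.count("N"), s.count("O"),
            s.count("S"), s.count("P"), halogens,
            sum(s.count(d) for d in "123456789"), s.count("("),
            s.count("="), s.count("#"), aromatic,
            s.count("+") + s.count("-"),
            hetero / max(1, len(s)), aromatic / max(1, len(s)),
        ]
        return np.asarray(vals, dtype=float)


class RDKitBackend:
    """Reference calculator built on RDKit.

    Native widths: electrotopological-state fingerprint (79 bits), MACCS keys
    (166 bits), RDKit 2D descriptor block (continuous). The remaining binary
    families are hashed RDKit fingerprints (path / Morgan / atom-pair /
    torsion / pattern) folded to each family's published width.
    """

    name = "rdkit"

    def __init__(self) -> None:
        from rdkit import Chem, RDLogger  # noqa: F401  (import check)

        RDLogger.DisableLog("rdApp.*")
        self._descriptor_names: Optional[list[str]] = None

    def supports(self, family: str) -> bool:
        return family in FAMILY_WIDTHS

    def _mol(self, smiles: str):
        from rdkit import Chem

        return Chem.MolFromSmiles(smiles) if smiles else None

    def feature_names(self, family: str) -> list[str]:
        if family == "2D Descriptor":
            if self._descriptor_names is None:
                from rdkit.Chem import Descriptors

                self._descriptor_names = [name for name, _ in Descriptors.descList]
            return list(self._descriptor_names)
        if family == "EStateFP":
            return [f"EStateFP_{i}" for i in range(79)]
        if family == "MACCSFP":
            return [f"MACCSFP_{i}" for i in range(1, 167)]
        width = FAMILY_WIDTHS[family][0]
        tag = family.replace(" ", "")
        return [f"{tag}_{i}" for i in range(width)]

    def featurize_one(self, smiles: str, family: str) -> Optional[np.ndarray]:
        mol = self._mol(smiles)
        if mol is None:
            return None
        if family == "2D Descriptor":
            return self._descriptors(mol)
        return self._fingerprint(mol, family)

    def _descriptors(self, mol) -> np.ndarray:
        from rdkit.Chem import Descriptors

        vals = []
        for _, fn in Descriptors.descList:
            try:
                vals.append(float(fn(mol)))
            except Exception:
                vals.append(np.nan)
        return np.asarray(vals, dtype=float)

    def _fingerprint(self, mol, family: str) -> np.ndarray:
        from rdkit import Chem
        from rdkit.Chem import AllChem, MACCSkeys
        from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

        width = FAMILY_WIDTHS[family][0]
        if family == "EStateFP":
            counts, _ = EStateFingerprinter.FingerprintMol(mol)
            return (np.asarray(counts) > 0).astype(float)
        if family == "MACCSFP":
            bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            arr = np.zeros(167)
            for b in bv.GetOnBits():
                arr[b] = 1.0
            return arr[1:]
        if family in ("FP", "GraphFP"):
            use_bond_order = family == "FP"  # graph-only family ignores bond orders
            bv = Chem.RDKFingerprint(mol, fpSize=width, useBondOrder=use_bond_order)
        elif family in ("ExtFP", "PubchemFP", "KRFP"):
            radius = {"ExtFP": 2, "PubchemFP": 1, "KRFP": 2}[family]
            gen = AllChem.GetMorganGenerator(radius=radius, fpSize=width)
            bv = gen.GetFingerprint(mol)
        elif family in ("SubFP", "SubFPC"):
            bv = Chem.PatternFingerprint(mol, fpSize=width)
        elif family in ("AP2D", "APC2D", "KRFPC"):
            gen = AllChem.GetAtomPairGenerator(fpSize=width) if family != "APC2D" \
                else AllChem.GetTopologicalTorsionGenerator(fpSize=width)
            bv = gen.GetFingerprint(mol)
        else:  # pragma: no cover - guarded by supports()
            raise ValueError(f"unsupported family {family!r}")
        arr = np.zeros(width)
        for b in bv.GetOnBits():
            arr[b] = 1.0
        return arr


def default_backend() -> FeaturizerBackend:
    """RDKit reference backend when importable, hashed fallback otherwise."""
    try:
        return RDKitBackend()
    except ImportError:  # pragma: no cover - rdkit present in normal installs
        return HashedBackend()


def compute_features(
    ds: Dataset, family: str, backend: Optional[FeaturizerBackend] = None
) -> tuple[FeatureMatrix, list[str]]:
    """Featurize every parseable compound of ``ds`` for one family.

    Returns the feature matrix (rows in dataset order restricted to
    successfully featurized compounds) and the rejection report: ids of
    compounds that could not be featurized.
    """
    if family not in FAMILY_WIDTHS:
        raise ValueError(f"unknown descriptor family {family!r}; expected one of {FAMILIES}")
    backend = backend or default_backend()
    if not backend.supports(family):
        raise ValueError(f"backend {backend.name!r} does not support family {family!r}")

    rows, ids, rejected = [], [], []
    for rec in ds:
        vec = backend.featurize_one(rec.smiles or "", family) if not rec.parse_failed else None
        if vec is None:
            rejected.append(rec.compound_id)
        else:
            rows.append(vec)
            ids.append(rec.compound_id)
    names = backend.feature_names(family)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    if len(ds) and not rows:
        raise RuntimeError(f"backend {backend.name!r} failed on every compound for {family!r}")
    kind = FAMILY_WIDTHS[family][1]
    return FeatureMatrix(ids, names, values, family, kind), rejected


def drop_degenerate(fm: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Remove zero-variance columns; impute continuous NaNs by column median.

    Imputation happens before the variance test so an all-NaN or constant
    descriptor is recognized as degenerate. Returns the filtered matrix and
    the removed column names.
    """
    values = fm.values.copy()
    if fm.value_kind == "continuous":
        medians = np.nanmedian(np.where(np.isfinite(values), values, np.nan), axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
        bad = ~np.isfinite(values)
        values[bad] = np.broadcast_to(medians, values.shape)[bad]
    keep = values.std(axis=0) > 0 if len(values) else np.ones(len(fm.feature_names), bool)
    removed = [n for n, k in zip(fm.feature_names, keep) if not k]
    kept_names = [n for n, k in zip(fm.feature_names, keep) if k]
    return FeatureMatrix(fm.row_ids, kept_names, values[:, keep], fm.family, fm.value_kind), removed


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with id column + header, and a ``<path>.meta`` key:value sidecar."""
    path = Path(path)
    fm.to_frame().to_csv(path, index_label="id")
    with open(path.with_suffix(path.suffix + ".meta"), "w", encoding="utf-8") as fh:
        fh.write(f"family: {fm.family}\nvalue_kind: {fm.value_kind}\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta")
    family, kind = "2D Descriptor", "continuous"
    if meta_path.exists():
        meta = dict(
            line.split(":", 1) for line in meta_path.read_text().splitlines() if ":" in line
        )
        family = meta.get("family", family).strip()
        kind = meta.get("value_kind", kind).strip()
    return FeatureMatrix([str(i) for i in df.index], list(df.columns),
                         df.to_numpy(float), family, kind)
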