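"""Synthetic data and in-package fixtures for every pipeline stage.

``make_classification_set`` emulates the statistical structure the selection
cascade assumes: a block of informative features separating the two classes,
a block of redundant features correlating with informative parents above the
pruning cutoff, and label-independent noise. ``make_pmt_fixture`` loads the
self-contained *Polygonum multiflorum* (He Shou Wu) screening case shipped
as package data: the 25-ingredient membership table of the three evidence
channels, the herb's star network, and the 6-name HILI subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_io import Dataset, read_compounds
from .ensemble import StackedDILIClassifier
from .featurize import FeatureMatrix
from .screen import HerbIngredientNetwork, HILIDataset, ScreeningResult

__all__ = [
    "SynthSpec",
    "make_classification_set",
    "PmtFixture",
    "make_pmt_fixture",
    "StubClassifier",
    "make_stub_bases",
    "stacked_from_stubs",
]

PMT_HERB_NAME = "he shou wu"


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings for a planted-signal classification table.

    ``effect_size`` is a standardized mean shift for continuous features and
    a bit-probability gap (P(bit|pos) - P(bit|neg)) for binary ones.
    """

    n: int = 200
    p_informative: int = 5
    p_redundant: int = 5
    p_noise: int = 10
    class_balance: float = 0.5
    effect_size: float = 1.5
    redundancy_rho: float = 0.95
    value_kind: str = "continuous"  # binary | continuous | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_redundant > 0 and self.p_informative == 0:
            raise ValueError("redundant features need informative parents")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.9 < self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must lie in (0.9, 1]")
        if self.value_kind not in ("binary", "continuous", "mixed"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.n < 4:
            raise ValueError("n must be >= 4")


def _binary_informative(rng, y, gap):
    p_pos, p_neg = min(1.0, 0.5 + gap / 2), max(0.0, 0.5 - gap / 2)
    probs = np.where(y == 1, p_pos, p_neg)
    return (rng.random(len(y)) < probs).astype(float)


def _binary_redundant(rng, parent, rho):
    flip = (1.0 - rho) / 2.0
    flips = rng.random(len(parent)) < flip
    return np.where(flips, 1.0 - parent, parent)


def _continuous_redundant(rng, parent, rho):
    sigma = np.sqrt(max(1.0 / rho**2 - 1.0, 1e-12))
    centred = parent - parent.mean()
    return parent + sigma * centred.std() * rng.standard_normal(len(parent))


def make_classification_set(
    spec: SynthSpec,
) -> tuple[FeatureMatrix, np.ndarray, dict[str, str]]:
    """Deterministic planted-signal feature table.

    Returns the feature matrix, the binary label vector, and the ground-truth
    role of every feature (informative / redundant / noise).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_pos = int(round(n * spec.class_balance))
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    y = y[rng.permutation(n)]

    def kind_of(block_index: int) -> str:
        if spec.value_kind != "mixed":
            return spec.value_kind
        return "continuous" if block_index % 2 == 0 else "binary"

    cols, names, roles = [], [], {}
    parents = []
    for i in range(spec.p_informative):
        kind = kind_of(i)
        if kind == "binary":
            col = _binary_informative(rng, y, spec.effect_size)
        else:
            col = rng.standard_normal(n) + np.where(y == 1, spec.effect_size / 2,
                                                    -spec.effect_size / 2)
        name = f"inf_{i}"
        cols.append(col)
        names.append(name)
        roles[name] = "informative"
        parents.append((col, kind))
    for i in range(spec.p_redundant):
        parent, kind = parents[i % len(parents)]
        col = (
            _binary_redundant(rng, parent, spec.redundancy_rho)
            if kind == "binary"
            else _continuous_redundant(rng, parent, spec.redundancy_rho)
        )
        name = f"red_{i}"
        cols.append(col)
        names.append(name)
        roles[name] = "redundant"
    for i in range(spec.p_noise):
        kind = kind_of(i)
        col = (
            (rng.random(n) < 0.5).astype(float)
            if kind == "binary"
            else rng.standard_normal(n)
        )
        name = f"noise_{i}"
        cols.append(col)
        names.append(name)
        roles[name] = "noise"

    values = np.column_stack(cols) if cols else np.empty((n, 0))
    value_kind = "binary" if spec.value_kind == "binary" else "continuous"
    fm = FeatureMatrix(
        [f"cmpd_{i}" for i in range(n)], names, values, family="synthetic",
        value_kind=value_kind,
    )
    return fm, y, roles


# ---------------------------------------------------------------------------
# stub base classifiers

class StubClassifier:
    """Replays a fixed prediction column regardless of input features."""

    def __init__(self, column: Sequence[int], row_ids: Optional[Sequence[str]] = None,
                 family: Optional[str] = None):
        self.column = np.asarray(column, dtype=int)
        self.row_ids = list(row_ids) if row_ids is not None else None
        self.family = family
        self.decision_threshold = 0.5

    def predict(self, fm) -> np.ndarray:
        ids = fm.row_ids if isinstance(fm, FeatureMatrix) else None
        if self.row_ids is not None and ids is not None:
            lookup = dict(zip(self.row_ids, self.column))
            try:
                return np.array([lookup[i] for i in ids], dtype=int)
            except KeyError as exc:
                raise ValueError(f"unknown row id for stub classifier: {exc}")
        n = len(ids) if ids is not None else len(fm)
        if n != len(self.column):
            raise ValueError("stub column length does not match the input rows")
        return self.column.copy()

    def predict_proba_pos(self, fm) -> np.ndarray:
        return self.predict(fm).astype(float)


def make_stub_bases(
    truth_table: np.ndarray, row_ids: Optional[Sequence[str]] = None,
    families: Optional[Sequence[str]] = None,
) -> list[StubClassifier]:
    """One stub per column of a binary n x m truth table."""
    table = np.asarray(truth_table)
    if table.ndim != 2:
        raise ValueError("truth table must be 2-dimensional")
    if not np.isin(table, (0, 1)).all():
        raise ValueError("truth table must be binary")
    fams = list(families) if families is not None else [None] * table.shape[1]
    if len(fams) != table.shape[1]:
        raise ValueError("one family tag per stub column required")
    return [StubClassifier(table[:, j], row_ids, fams[j]) for j in range(table.shape[1])]


def stacked_from_stubs(
    stubs: Sequence[StubClassifier],
    fms,
    labels,
    meta_alpha: float = 1.0,
) -> StackedDILIClassifier:
    """Stacked classifier whose bases are stubs; only the meta NB is fitted.

    Isolates the meta-learner for unit tests and supports screening runs with
    predefined base outputs.
    """
    from sklearn.naive_bayes import BernoulliNB

    from .ensemble import build_meta_features

    model = StackedDILIClassifier(base_recipes=[])
    model.base_models_ = list(stubs)
    meta = build_meta_features(model.base_models_, fms)
    model.meta_model_ = BernoulliNB(alpha=meta_alpha)
    model.meta_model_.fit(meta, np.asarray(labels, dtype=int))
    model.classes_ = model.meta_model_.classes_
    model.meta_feature_names_ = [f"stub_{j}" for j in range(len(stubs))]
    model.training_meta_ = meta
    return model


# ---------------------------------------------------------------------------
# the He Shou Wu screening fixture

@dataclass
class PmtFixture:
    """Self-contained screening case study loaded from package data."""

    ingredients: Dataset
    hili: HILIDataset
    network: HerbIngredientNetwork
    herb: str
    memberships: pd.DataFrame  # ingredient, in_s1, in_s2, in_s3
    expected: ScreeningResult


def _data_path(name: str):
    return resources.as_file(resources.files("hepatoscreen.data").joinpath(name))


def make_pmt_fixture() -> PmtFixture:
    """Load the 25-ingredient He Shou Wu case with expected channel memberships."""
    with _data_path("pmt_ingredients.csv") as p:
        ingredients = read_compounds(p, format="csv")
    with _data_path("pmt_hili.csv") as p:
        hili = HILIDataset.from_csv(p)
    with _data_path("pmt_network.tsv") as p:
        network = HerbIngredientNetwork.from_tsv(p)
    with _data_path("pmt_subgroups.csv") as p:
        memberships = pd.read_csv(p)
    expected = ScreeningResult(
        subgroup1=set(memberships.loc[memberships.in_s1 == 1, "ingredient"]),
        subgroup2=set(memberships.loc[memberships.in_s2 == 1, "ingredient"]),
        subgroup3=set(memberships.loc[memberships.in_s3 == 1, "ingredient"]),
    )
    return PmtFixture(
        ingredients=ingredients,
        hili=hili,
        network=network,
        herb=PMT_HERB_NAME,
        memberships=memberships,
        expected=expected,
    )
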