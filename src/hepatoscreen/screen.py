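"""Three-channel screen for hepatotoxic ingredients in herbal medicines.

An ingredient of a herbal preparation is flagged hepatotoxic by any of three
evidence channels: (1) the combined QSAR classifier (probability strictly
above 0.500), (2) exact name matching against a curated herb-induced liver
injury (HILI) ingredient dictionary, and (3) lookup of the herb's neighbours
in a curated bipartite herb-hepatotoxic-ingredient network. The three
subgroups are integrated by union with per-ingredient provenance. A
hierarchical clustering utility (Euclidean distance, average linkage by
default) supports exploring the structure of the flagged ingredients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .chem_io import Dataset, normalize_name
from .ensemble import StackedDILIClassifier, predict_stacked
from .featurize import FeatureMatrix

__all__ = [
    "HerbIngredientNetwork",
    "HILIDataset",
    "ScreeningResult",
    "screen_subgroup1",
    "screen_subgroup2",
    "screen_subgroup3",
    "integrate",
    "cluster_ingredients",
]


class HerbIngredientNetwork:
    """Bipartite herb <-> hepatotoxic-ingredient network with normalized names."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self.graph = nx.Graph()
        for herb, ingredient in edges:
            self.add_edge(herb, ingredient)

    def add_edge(self, herb: str, ingredient: str) -> None:
        h, i = normalize_name(herb), normalize_name(ingredient)
        if h == i:
            raise ValueError(f"self-loop rejected: {herb!r}")
        self.graph.add_node(h, bipartite="herb")
        self.graph.add_node(i, bipartite="ingredient")
        self.graph.add_edge(h, i)

    @property
    def herbs(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["bipartite"] == "herb"}

    @property
    def ingredients(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["bipartite"] == "ingredient"}

    def ingredients_of(self, herb: str) -> set[str]:
        """Neighbours of a herb node; empty set when the herb is absent."""
        h = normalize_name(herb)
        if h not in self.herbs:
            return set()
        return set(self.graph.neighbors(h))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HerbIngredientNetwork":
        """Edge list: one ``herb<TAB>ingredient`` per line (no header)."""
        net = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed network line: {line!r}")
            net.add_edge(parts[0], parts[1])
        return net


class HILIDataset:
    """Set of ingredient names with herb-induced liver-injury evidence."""

    def __init__(self, names: Iterable[str] = (), sources: Optional[Mapping[str, str]] = None):
        self.names: set[str] = {normalize_name(n) for n in names}
        self.sources = {normalize_name(k): v for k, v in (sources or {}).items()}

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.names

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HILIDataset":
        """CSV ``name[,source]`` with header."""
        df = pd.read_csv(path)
        col = df.columns[0]
        sources = None
        if df.shape[1] > 1:
            sources = dict(zip(df[col].astype(str), df[df.columns[1]].astype(str)))
        return cls(df[col].astype(str), sources)


@dataclass
class ScreeningResult:
    """Union of the three evidence channels with provenance bookkeeping."""

    subgroup1: set[str]
    subgroup2: set[str]
    subgroup3: set[str]
    probabilities: dict[str, float] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    @property
    def union(self) -> set[str]:
        return self.subgroup1 | self.subgroup2 | self.subgroup3

    @property
    def provenance(self) -> dict[str, set[str]]:
        prov: dict[str, set[str]] = {}
        for tag, group in (
            ("classifier", self.subgroup1),
            ("hili", self.subgroup2),
            ("network", self.subgroup3),
        ):
            for name in group:
                prov.setdefault(name, set()).add(tag)
        return prov

    @property
    def unique_counts(self) -> tuple[int, int, int]:
        """Ingredients found by exactly one channel, per channel."""
        return (
            len(self.subgroup1 - self.subgroup2 - self.subgroup3),
            len(self.subgroup2 - self.subgroup1 - self.subgroup3),
            len(self.subgroup3 - self.subgroup1 - self.subgroup2),
        )

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.union):
            rows.append(
                {
                    "ingredient": name,
                    "in_s1": name in self.subgroup1,
                    "in_s2": name in self.subgroup2,
                    "in_s3": name in self.subgroup3,
                    "probability": self.probabilities.get(name, np.nan),
                    "provenance": "+".join(sorted(self.provenance[name])),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        u1, u2, u3 = self.unique_counts
        return json.dumps(
            {
                "subgroup1": sorted(self.subgroup1),
                "subgroup2": sorted(self.subgroup2),
                "subgroup3": sorted(self.subgroup3),
                "union": sorted(self.union),
                "counts": {
                    "subgroup1": len(self.subgroup1),
                    "subgroup2": len(self.subgroup2),
                    "subgroup3": len(self.subgroup3),
                    "union": len(self.union),
                    "unique": [u1, u2, u3],
                },
                "probabilities": self.probabilities,
                "notices": self.notices,
            },
            indent=2,
        )


def screen_subgroup1(
    ingredients: Dataset,
    model: StackedDILIClassifier,
    fms: Mapping[str, FeatureMatrix],
    threshold: float = 0.500,
) -> tuple[set[str], dict[str, float], list[str]]:
    """Classifier channel: ingredients with P(hepatotoxic) strictly > threshold.

    Returns the flagged name set, per-ingredient probabilities, and notices
    for structure-less ingredients excluded from this channel.
    """
    featurized_ids = set(next(iter(fms.values())).row_ids)
    notices = [
        f"ingredient {rec.name!r} has no usable structure; "
        "covered only by the name/network channels"
        for rec in ingredients
        if rec.compound_id not in featurized_ids
    ]
    table = predict_stacked(model, fms)
    id_to_name = {rec.compound_id: normalize_name(rec.name) for rec in ingredients}
    probs = {
        id_to_name.get(row.id, str(row.id)): float(row.probability)
        for row in table.itertuples()
    }
    flagged = {name for name, p in probs.items() if p > threshold}
    return flagged, probs, notices


def screen_subgroup2(ingredients: Dataset, hili: HILIDataset) -> set[str]:
    """Dictionary channel: exact match of normalized names against the HILI set."""
    return {
        normalize_name(rec.name)
        for rec in ingredients
        if rec.name and normalize_name(rec.name) in hili.names
    }


def screen_subgroup3(herb: str, net: HerbIngredientNetwork) -> tuple[set[str], list[str]]:
    """Network channel: hepatotoxic ingredients recorded for the herb.

    An absent herb yields an empty set plus a notice (not an error).
    """
    found = net.ingredients_of(herb)
    notices = [] if found or normalize_name(herb) in net.herbs else [
        f"herb {herb!r} not found in the herb-ingredient network"
    ]
    return found, notices


def integrate(
    s1: set[str],
    s2: set[str],
    s3: set[str],
    probabilities: Optional[dict[str, float]] = None,
    notices: Optional[list[str]] = None,
) -> ScreeningResult:
    """Union of the three channels with provenance and unique counts."""
    return ScreeningResult(
        subgroup1=set(s1),
        subgroup2=set(s2),
        subgroup3=set(s3),
        probabilities=dict(probabilities or {}),
        notices=list(notices or []),
    )


def cluster_ingredients(
    fm: FeatureMatrix, n_groups: int, linkage: str = "average"
) -> tuple[dict[str, int], np.ndarray]:
    """Agglomerative clustering (Euclidean distance) of ingredient feature rows.

    Returns per-ingredient group labels (1..n_groups) from cutting the merge
    tree, plus the scipy linkage matrix itself.
    """
    n = len(fm.row_ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 ingredients")
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds the {n} ingredients")
    Z = hierarchy.linkage(fm.values, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return dict(zip(fm.row_ids, labels.tolist())), Z
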