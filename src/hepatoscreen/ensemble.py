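"""Combined classifier: eight heterogeneous bases fused by Naive Bayes.

Each base learner is trained on its own descriptor family and optimal
feature subset. The bases' hard positive/negative calls become eight binary
meta-features on which a Bernoulli Naive Bayes meta-model (Laplace +1
smoothing) is trained. Two meta-feature modes exist:

* ``resubstitution`` — each base predicts the very compounds it was trained
  on (the historically described construction; optimistically biased);
* ``out_of_fold`` (default) — meta-features for the training set come from
  cross-fitted copies of each base, so no base scores a compound it saw in
  training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

from .featurize import FeatureMatrix
from .learners import (
    DECISION_THRESHOLD,
    LearnerSpec,
    TrainedClassifier,
    load_classifier,
    save_classifier,
    train,
)

__all__ = [
    "BaseRecipe",
    "StackedDILIClassifier",
    "build_meta_features",
    "fit_stacked",
    "predict_stacked",
    "majority_vote",
    "save_stacked",
    "load_stacked",
]


@dataclass(frozen=True)
class BaseRecipe:
    """(algorithm spec, descriptor family, feature subset) for one base."""

    spec: LearnerSpec
    family: str
    subset: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset", tuple(self.subset))


def _check_alignment(fms: Mapping[str, FeatureMatrix]) -> list[str]:
    ids = None
    for fam, fm in fms.items():
        if ids is None:
            ids = list(fm.row_ids)
        elif list(fm.row_ids) != ids:
            raise ValueError(f"row ids of family {fam!r} disagree with the other families")
    if ids is None:
        raise ValueError("no feature matrices supplied")
    return ids


def build_meta_features(
    bases: Sequence, fms: Mapping[str, FeatureMatrix]
) -> np.ndarray:
    """n x n_bases binary matrix; entry (i, j) = 1 iff base j calls compound i
    hepatotoxic. Bases are used as fitted (resubstitution semantics); for
    leakage-free training meta-features see :class:`StackedDILIClassifier`
    with ``meta_feature_mode='out_of_fold'``."""
    _check_alignment(fms)
    cols = []
    for base in bases:
        fam = getattr(base, "family", None)
        if fam is not None and fam not in fms:
            raise ValueError(f"family {fam!r} missing from the supplied matrices")
        fm = fms[fam] if fam is not None else next(iter(fms.values()))
        cols.append(np.asarray(base.predict(fm), dtype=int))
    return np.column_stack(cols)


def majority_vote(meta: np.ndarray) -> np.ndarray:
    """Reference fusion rule used in tests: strict majority of base calls."""
    meta = np.asarray(meta)
    return (meta.mean(axis=1) > 0.5).astype(int)


class StackedDILIClassifier(BaseEstimator, ClassifierMixin):
    """Stack of base learners fused by a Bernoulli Naive Bayes meta-model.

    ``fit``/``predict`` consume a mapping family -> FeatureMatrix (one view
    per descriptor family) whose rows are aligned across families.

    Fitted attributes: ``base_models_`` (list of TrainedClassifier, registry
    order = recipe order), ``meta_model_`` (BernoulliNB), ``meta_feature_names_``.
    """

    def __init__(
        self,
        base_recipes: Sequence[BaseRecipe] = (),
        meta_feature_mode: str = "out_of_fold",
        oof_folds: int = 10,
        meta_alpha: float = 1.0,
        decision_threshold: float = DECISION_THRESHOLD,
        seed: int = 0,
    ):
        self.base_recipes = list(base_recipes)
        self.meta_feature_mode = meta_feature_mode
        self.oof_folds = oof_folds
        self.meta_alpha = meta_alpha
        self.decision_threshold = decision_threshold
        self.seed = seed

    # -- fitting -----------------------------------------------------------
    def fit(self, fms: Mapping[str, FeatureMatrix], y):
        if self.meta_feature_mode not in ("resubstitution", "out_of_fold"):
            raise ValueError(f"unknown meta_feature_mode {self.meta_feature_mode!r}")
        y = np.asarray(y, dtype=int)
        ids = _check_alignment(fms)
        if len(ids) != len(y):
            raise ValueError("labels do not match the feature-matrix rows")

        self.base_models_ = []
        for recipe in self.base_recipes:
            if recipe.family not in fms:
                raise ValueError(f"family {recipe.family!r} missing from the supplied matrices")
            try:
                clf = train(recipe.spec, fms[recipe.family], y, subset=recipe.subset or None)
            except Exception as exc:
                raise type(exc)(f"base {recipe.spec.algorithm!r} on {recipe.family!r}: {exc}")
            self.base_models_.append(clf)

        if self.meta_feature_mode == "resubstitution":
            meta = build_meta_features(self.base_models_, fms)
        else:
            meta = self._out_of_fold_meta(fms, y)
        self.meta_feature_names_ = [
            f"{r.spec.algorithm}:{r.family}" for r in self.base_recipes
        ]
        self.meta_model_ = BernoulliNB(alpha=self.meta_alpha)
        self.meta_model_.fit(meta, y)
        self.classes_ = self.meta_model_.classes_
        self.training_meta_ = meta
        return self

    def _out_of_fold_meta(self, fms, y) -> np.ndarray:
        n = len(y)
        k = min(self.oof_folds, int(np.bincount(y, minlength=2).min()))
        if k < 2:
            raise ValueError("out-of-fold meta-features need >= 2 members per class")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.seed)
        meta = np.zeros((n, len(self.base_recipes)), dtype=int)
        for tr, te in splitter.split(np.zeros(n), y):
            for j, recipe in enumerate(self.base_recipes):
                fm = fms[recipe.family]
                clf = train(recipe.spec, fm.subset_rows(tr), y[tr], subset=recipe.subset or None)
                meta[te, j] = clf.predict(fm.subset_rows(te))
        return meta

    # -- prediction --------------------------------------------------------
    def _meta_matrix(self, fms: Mapping[str, FeatureMatrix]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "meta_model_")
        return build_meta_features(self.base_models_, fms)

    def predict_proba_pos(self, fms) -> np.ndarray:
        """Meta-posterior P(hepatotoxic) per compound."""
        proba = self.meta_model_.predict_proba(self._meta_matrix(fms))
        return proba[:, list(self.meta_model_.classes_).index(1)]

    def predict_proba(self, fms) -> np.ndarray:
        pos = self.predict_proba_pos(fms)
        return np.column_stack([1 - pos, pos])

    def predict(self, fms) -> np.ndarray:
        """1 iff P(hepatotoxic) strictly exceeds the decision threshold."""
        return (self.predict_proba_pos(fms) > self.decision_threshold).astype(int)


def fit_stacked(
    base_recipes: Sequence[BaseRecipe],
    fms: Mapping[str, FeatureMatrix],
    labels,
    mode: str = "out_of_fold",
    seed: int = 0,
) -> StackedDILIClassifier:
    """Train the combined classifier from base recipes and family matrices."""
    model = StackedDILIClassifier(
        base_recipes=base_recipes, meta_feature_mode=mode, seed=seed
    )
    return model.fit(fms, labels)


def predict_stacked(
    stacked: StackedDILIClassifier, fms: Mapping[str, FeatureMatrix]
) -> pd.DataFrame:
    """Per-compound probability and hard label from the combined classifier."""
    ids = _check_alignment(fms)
    prob = stacked.predict_proba_pos(fms)
    return pd.DataFrame(
        {
            "id": ids,
            "probability": prob,
            "label": (prob > stacked.decision_threshold).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# persistence: directory of 8 base artifacts + meta artifact + manifest

def save_stacked(model: StackedDILIClassifier, path: str | Path) -> None:
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "meta_feature_mode": model.meta_feature_mode,
        "seed": model.seed,
        "decision_threshold": model.decision_threshold,
        "bases": [
            {"algorithm": r.spec.algorithm, "hyperparameters": r.spec.hp,
             "family": r.family, "subset": list(r.subset)}
            for r in model.base_recipes
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, base in enumerate(model.base_models_):
        save_classifier(base, path / f"base_{i}")
    joblib.dump(
        {"meta_model": model.meta_model_, "recipes": model.base_recipes,
         "meta_feature_names": model.meta_feature_names_},
        path / "meta.joblib",
    )


def load_stacked(path: str | Path) -> StackedDILIClassifier:
    import joblib

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    blob = joblib.load(path / "meta.joblib")
    model = StackedDILIClassifier(
        base_recipes=blob["recipes"],
        meta_feature_mode=manifest["meta_feature_mode"],
        decision_threshold=manifest["decision_threshold"],
        seed=manifest["seed"],
    )
    model.base_models_ = [
        load_classifier(path / f"base_{i}") for i in range(len(blob["recipes"]))
    ]
    model.meta_model_ = blob["meta_model"]
    model.meta_feature_names_ = blob["meta_feature_names"]
    model.classes_ = model.meta_model_.classes_
    return model
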