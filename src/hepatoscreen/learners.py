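"""Registry of the eight base learning algorithms and their tuning grids.

The eight algorithms span five classifier categories: Naive Bayes (bayes),
RBF-kernel SVM (function), K-nearest-neighbours and a K*-style entropic
instance learner (lazy), boosted and bagged meta-learners, and single /
ensembled decision trees. Hyperparameter names follow the field's usual
symbols: C (SVM penalty or, for trees, the pruning confidence Cf), gamma
(RBF width), K (neighbour count), B (global blending, 0-100), Depth
(maximum tree depth, 0 = unlimited), Cf (pruning confidence).

Two learners are authored here rather than taken from sklearn: a mixed
Bernoulli/Gaussian Naive Bayes (binary fingerprint bits and continuous
descriptors can share a table) and the K*-style learner (no equivalent in
sklearn). Everything else stands on sklearn estimators.
"""

from __future__ import annotations

import itertools
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.impute import SimpleImputer
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from . import evaluate as ev
from .featurize import FeatureMatrix

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "LearnerSpec",
    "TrainedClassifier",
    "MixedNaiveBayes",
    "KStarClassifier",
    "build_estimator",
    "train",
    "predict_proba",
    "tune",
    "save_classifier",
    "load_classifier",
]

DECISION_THRESHOLD = 0.500  # hepatotoxic iff P(pos) strictly greater

#: algorithm tag -> hyperparameter names it accepts
ALGORITHMS: dict[str, set[str]] = {
    "naive_bayes": set(),
    "svm_rbf": {"C", "gamma"},
    "knn": {"K"},
    "kstar": {"B"},
    "adaboost_tree": {"Cf", "n_estimators"},
    "bagging_knn": {"K", "n_estimators"},
    "decision_tree": {"Cf"},
    "random_forest": {"Depth", "n_estimators"},
}

#: default tuning grids for the parameter each algorithm optimizes
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "naive_bayes": {},
    "svm_rbf": {
        "C": [2.0**e for e in range(-5, 6)],
        "gamma": [2.0**e for e in range(-7, 4)],
    },
    "knn": {"K": [1, 3, 5, 7, 9]},
    "kstar": {"B": [1, 20, 40]},
    "adaboost_tree": {"Cf": [0.1, 0.25, 0.5]},
    "bagging_knn": {"K": [1, 3, 5, 7, 9]},
    "decision_tree": {"Cf": [0.1, 0.25, 0.5]},
    "random_forest": {"Depth": [0, 5, 10, 20]},
}


def _validate_hyperparameters(algorithm: str, hp: Mapping[str, object]) -> None:
    allowed = ALGORITHMS[algorithm]
    unknown = set(hp) - allowed
    if unknown:
        raise ValueError(
            f"hyperparameters {sorted(unknown)} not meaningful for {algorithm!r}; "
            f"allowed: {sorted(allowed) or 'none'}"
        )
    if "C" in hp and not float(hp["C"]) > 0:
        raise ValueError("C must be > 0")
    if "gamma" in hp and not float(hp["gamma"]) > 0:
        raise ValueError("gamma must be > 0")
    if "K" in hp and int(hp["K"]) < 1:
        raise ValueError("K must be >= 1")
    if "Depth" in hp and int(hp["Depth"]) < 0:
        raise ValueError("Depth must be >= 0 (0 = unlimited)")
    if "Cf" in hp and not 0 < float(hp["Cf"]) < 1:
        raise ValueError("Cf must lie in (0, 1)")
    if "B" in hp and not 0 <= float(hp["B"]) <= 100:
        raise ValueError("B must lie in [0, 100]")
    if "n_estimators" in hp and int(hp["n_estimators"]) < 1:
        raise ValueError("n_estimators must be >= 1")


@dataclass(frozen=True)
class LearnerSpec:
    """One base algorithm plus its hyperparameter settings and seed."""

    algorithm: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {sorted(ALGORITHMS)}"
            )
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )
        _validate_hyperparameters(self.algorithm, dict(self.hyperparameters))

    @property
    def hp(self) -> dict[str, object]:
        return dict(self.hyperparameters)

    def with_params(self, **kwargs) -> "LearnerSpec":
        hp = self.hp
        hp.update(kwargs)
        return LearnerSpec(self.algorithm, tuple(sorted(hp.items())), self.seed)


class MixedNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes over mixed binary/continuous columns.

    Columns whose training values are all in {0, 1} get Bernoulli
    likelihoods with Laplace smoothing; the rest get Gaussian likelihoods.
    The joint log-likelihood is the sum of both blocks plus one class prior.
    """

    def __init__(self, alpha: float = 1.0, var_smoothing: float = 1e-9):
        self.alpha = alpha
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.binary_mask_ = np.array(
            [np.isin(col[np.isfinite(col)], (0.0, 1.0)).all() for col in X.T]
        )
        self._bnb = self._gnb = None
        if self.binary_mask_.any():
            self._bnb = BernoulliNB(alpha=self.alpha)
            self._bnb.fit(X[:, self.binary_mask_], y)
        if (~self.binary_mask_).any():
            self._gnb = GaussianNB(var_smoothing=self.var_smoothing)
            self._gnb.fit(X[:, ~self.binary_mask_], y)
        counts = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        self.class_log_prior_ = np.log(counts / counts.sum())
        return self

    def _joint(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        joint = np.tile(self.class_log_prior_, (len(X), 1))
        if self._bnb is not None:
            joint += (
                self._bnb._joint_log_likelihood(X[:, self.binary_mask_])
                - self._bnb.class_log_prior_
            )
        if self._gnb is not None:
            joint += self._gnb._joint_log_likelihood(
                X[:, ~self.binary_mask_]
            ) - np.log(self._gnb.class_prior_)
        return joint

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        joint = self._joint(X)
        joint -= joint.max(axis=1, keepdims=True)
        p = np.exp(joint)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class KStarClassifier(BaseEstimator, ClassifierMixin):
    """Instance-based learner with a global blending parameter B in [0, 100].

    Each query point weights every training instance by exp(-d/s) where the
    scale s is solved (bisection) so that the effective number of voting
    neighbours equals 1 + (B/100)(n-1): B=0 degenerates to nearest-neighbour,
    B=100 to an unweighted vote over all instances. This reproduces the
    sphere-of-influence semantics of the entropic K* blend with Euclidean
    distances standing in for the full transformation-complexity measure.
    """

    def __init__(self, B: float = 20.0):
        self.B = B

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self._scale = X.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        self.X_ = X / self._scale
        self.y_idx_ = np.searchsorted(self.classes_, y)
        return self

    def _weights(self, d: np.ndarray) -> np.ndarray:
        n = len(d)
        n_eff = 1.0 + (self.B / 100.0) * (n - 1)
        zero = d <= 1e-12
        if zero.sum() >= n_eff or np.allclose(d, d[0]):
            w = np.where(zero, 1.0, 0.0) if zero.any() else np.ones(n)
            return w / w.sum()
        lo, hi = 1e-9, 1e9
        dmax = d.max()
        for _ in range(200):
            s = np.sqrt(lo * hi)
            total = np.exp(-d / (s * dmax + 1e-300)).sum()
            if abs(total - n_eff) < 1e-9:
                break
            if total < n_eff:
                lo = s
            else:
                hi = s
        w = np.exp(-d / (s * dmax + 1e-300))
        return w / w.sum()

    def predict_proba(self, X):
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float) / self._scale
        out = np.zeros((len(X), len(self.classes_)))
        for i, x in enumerate(X):
            d = np.linalg.norm(self.X_ - x, axis=1)
            w = self._weights(d)
            for c in range(len(self.classes_)):
                out[i, c] = w[self.y_idx_ == c].sum()
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _cf_to_ccp_alpha(cf: float) -> float:
    """Monotone map from a pruning confidence (small = aggressive pruning)
    to CART cost-complexity alpha (large = aggressive pruning)."""
    return 0.02 * (1.0 - float(cf))


def build_estimator(spec: LearnerSpec):
    """Instantiate the sklearn-compatible estimator for a learner spec."""
    hp = spec.hp
    seed = spec.seed
    alg = spec.algorithm
    if alg == "naive_bayes":
        return MixedNaiveBayes()
    if alg == "svm_rbf":
        return SVC(
            C=float(hp.get("C", 1.0)),
            gamma=hp.get("gamma", "scale"),
            kernel="rbf",
            probability=True,
            random_state=seed,
        )
    if alg == "knn":
        return KNeighborsClassifier(n_neighbors=int(hp.get("K", 1)))
    if alg == "kstar":
        return KStarClassifier(B=float(hp.get("B", 20)))
    if alg == "adaboost_tree":
        base = DecisionTreeClassifier(
            criterion="entropy",
            ccp_alpha=_cf_to_ccp_alpha(hp.get("Cf", 0.25)),
            random_state=seed,
        )
        return AdaBoostClassifier(
            estimator=base, n_estimators=int(hp.get("n_estimators", 10)),
            random_state=seed,
        )
    if alg == "bagging_knn":
        return BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=int(hp.get("K", 1))),
            n_estimators=int(hp.get("n_estimators", 10)),
            random_state=seed,
        )
    if alg == "decision_tree":
        return DecisionTreeClassifier(
            criterion="entropy",
            ccp_alpha=_cf_to_ccp_alpha(hp.get("Cf", 0.25)),
            random_state=seed,
        )
    if alg == "random_forest":
        depth = int(hp.get("Depth", 0))
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_depth=None if depth == 0 else depth,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {alg!r}")  # pragma: no cover


_SCALED = {"svm_rbf", "knn", "kstar", "bagging_knn"}


def build_pipeline(spec: LearnerSpec, value_kind: str) -> Pipeline:
    """Estimator wrapped with the preprocessing its inputs need.

    Continuous descriptor tables get median imputation (fitted on the
    training portion only, by construction of the pipeline) and, for
    distance/kernel learners, standardization.
    """
    steps = []
    if value_kind == "continuous":
        steps.append(("impute", SimpleImputer(strategy="median")))
        if spec.algorithm in _SCALED:
            steps.append(("scale", StandardScaler()))
    steps.append(("model", build_estimator(spec)))
    return Pipeline(steps)


@dataclass
class TrainedClassifier:
    """A fitted base learner bound to its descriptor family and feature subset."""

    spec: LearnerSpec
    family: str
    feature_names: list[str]
    pipeline: Pipeline
    value_kind: str
    decision_threshold: float = DECISION_THRESHOLD

    def _matrix(self, fm: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        df = fm.to_frame() if isinstance(fm, FeatureMatrix) else fm
        missing = [n for n in self.feature_names if n not in df.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing[:10]}")
        return df[self.feature_names].to_numpy(float)

    def predict_proba_pos(self, fm) -> np.ndarray:
        """P(hepatotoxic) per compound."""
        model = self.pipeline
        proba = model.predict_proba(self._matrix(fm))
        classes = list(model.classes_)
        return proba[:, classes.index(1)]

    def predict(self, fm) -> np.ndarray:
        """1 iff P(hepatotoxic) strictly exceeds the decision threshold."""
        return (self.predict_proba_pos(fm) > self.decision_threshold).astype(int)


def train(
    spec: LearnerSpec,
    fm: FeatureMatrix,
    labels: Sequence[int],
    subset: Optional[Sequence[str]] = None,
) -> TrainedClassifier:
    """Fit one base learner on a feature subset of one family matrix."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    names = list(subset) if subset is not None else list(fm.feature_names)
    sub = fm.select(names)
    if not np.isfinite(sub.values).all() and sub.value_kind != "continuous":
        raise ValueError("binary feature matrix contains missing values")
    pipe = build_pipeline(spec, sub.value_kind)
    pipe.fit(sub.values, y)
    return TrainedClassifier(
        spec=spec, family=fm.family, feature_names=names, pipeline=pipe,
        value_kind=sub.value_kind,
    )


def predict_proba(clf: TrainedClassifier, fm) -> np.ndarray:
    """P(hepatotoxic) for each compound in ``fm``."""
    return clf.predict_proba_pos(fm)


class LearnerRecipe:
    """Factory+model wrapper so generic CV can refit a spec per fold."""

    def __init__(self, spec: LearnerSpec, subset: Optional[Sequence[str]] = None):
        self.spec = spec
        self.subset = list(subset) if subset is not None else None
        self._fitted: Optional[TrainedClassifier] = None

    def fit(self, fm: FeatureMatrix, y):
        self._fitted = train(self.spec, fm, y, subset=self.subset)
        return self

    def predict_proba_pos(self, fm):
        return self._fitted.predict_proba_pos(fm)

    def predict(self, fm):
        return self._fitted.predict(fm)


def tune(
    spec: LearnerSpec,
    fm: FeatureMatrix,
    labels: Sequence[int],
    grid: Optional[Mapping[str, Sequence]] = None,
    k_folds: int = 10,
    seed: int = 0,
) -> tuple[LearnerSpec, pd.DataFrame]:
    """Exhaustive grid evaluation by stratified k-fold CV.

    Best cell maximizes mean(AUC, ACC/100); ties break toward the earlier
    grid cell (deterministic enumeration order). Returns the winning spec and
    the full score table.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRIDS[spec.algorithm])
    if not grid:
        grid = {"_default": [None]}
    names = sorted(grid)
    rows = []
    best: tuple[float, int] | None = None
    best_spec = spec
    for idx, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        params = {n: v for n, v in zip(names, combo) if n != "_default"}
        cand = spec.with_params(**params) if params else spec
        res = ev.cross_validate(
            lambda c=cand: LearnerRecipe(c), fm, labels, k=k_folds, seed=seed
        )
        score = (res.report.auc + res.report.acc / 100.0) / 2.0
        rows.append({**params, "ACC": res.report.acc, "AUC": res.report.auc,
                     "score": score})
        if best is None or score > best[0]:
            best = (score, idx)
            best_spec = cand
    return best_spec, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence

_ARTIFACT_VERSION = 1


def save_classifier(clf: TrainedClassifier, path: str | Path) -> None:
    """Persist as <path>/model.joblib + header.json (algorithm, subset, seed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "artifact_version": _ARTIFACT_VERSION,
        "algorithm": clf.spec.algorithm,
        "hyperparameters": clf.spec.hp,
        "seed": clf.spec.seed,
        "family": clf.family,
        "feature_names": clf.feature_names,
        "value_kind": clf.value_kind,
        "decision_threshold": clf.decision_threshold,
        "sklearn_version": sklearn.__version__,
        "python_version": platform.python_version(),
    }
    (path / "header.json").write_text(json.dumps(header, indent=2))
    joblib.dump(clf, path / "model.joblib")


def load_classifier(path: str | Path) -> TrainedClassifier:
    """Load a persisted classifier, refusing on header/model mismatch."""
    path = Path(path)
    header = json.loads((path / "header.json").read_text())
    if header.get("artifact_version") != _ARTIFACT_VERSION:
        raise ValueError("unsupported classifier artifact version")
    clf: TrainedClassifier = joblib.load(path / "model.joblib")
    if (
        clf.spec.algorithm != header["algorithm"]
        or clf.feature_names != header["feature_names"]
        or clf.family != header["family"]
    ):
        raise ValueError("classifier artifact header does not match its model")
    return clf
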