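"""Three-stage feature-selection cascade plus the nested-subset sweep.

Stage 1 — Boruta: all-relevant selection. Each iteration appends shuffled
"shadow" copies of every live feature, fits an importance estimator (random
forest by default) and scores a hit for each real feature whose importance
beats the best shadow. Features are confirmed/rejected by two-sided binomial
tests on their hit counts (Bonferroni-corrected); undecided features at the
iteration cap stay tentative and are treated as not selected.

Stage 2 — correlation pruning: the caret-style findCorrelation greedy loop.
While any pair of retained features has |Pearson r| above the cutoff (0.90
by default), the member of the worst pair with the larger mean absolute
correlation to all other features is dropped.

Stage 3 — RFE: recursive feature elimination down to a single feature
(step 1), yielding a complete ranking (rank 1 = retained longest).

The subset sweep then walks the ranking from the full width down to one
feature, cross-validating a learner on each prefix and choosing the subset
size maximizing mean(AUC, ACC/100), ties toward the smaller size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE

from . import evaluate as ev
from .featurize import FeatureMatrix
from .learners import LearnerRecipe, LearnerSpec

__all__ = [
    "SelectionConfig",
    "BorutaSelector",
    "boruta_select",
    "correlation_prune",
    "CorrelationPruner",
    "FeatureRanking",
    "rfe_rank",
    "SweepResult",
    "subset_sweep",
    "sweep_evaluation_count",
    "load_reference_selection_widths",
]


@dataclass
class SelectionConfig:
    """Knobs of the selection cascade."""

    correlation_cutoff: float = 0.90
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    rfe_step: int = 1
    importance_estimator: Optional[BaseEstimator] = None  # default: random forest
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_cutoff < 1:
            raise ValueError("correlation_cutoff must lie in (0, 1)")
        if self.rfe_step < 1:
            raise ValueError("rfe_step must be >= 1")

    def make_estimator(self) -> BaseEstimator:
        if self.importance_estimator is not None:
            est = clone(self.importance_estimator)
        else:
            est = RandomForestClassifier(n_estimators=100)
        if "random_state" in est.get_params():
            est.set_params(random_state=self.seed)
        return est


def _as_frame(fm) -> pd.DataFrame:
    if isinstance(fm, FeatureMatrix):
        return fm.to_frame()
    if isinstance(fm, pd.DataFrame):
        return fm
    arr = np.asarray(fm, dtype=float)
    return pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])


class BorutaSelector(BaseEstimator):
    """All-relevant feature selection against shuffled shadow features.

    Fitted attributes: ``confirmed_``, ``rejected_``, ``tentative_`` (feature
    name lists, disjoint, union = input features), ``support_`` (confirmed
    mask), ``hit_counts_`` and ``n_iterations_``.
    """

    def __init__(
        self,
        estimator: Optional[BaseEstimator] = None,
        alpha: float = 0.05,
        max_iter: int = 100,
        random_state: int = 0,
    ):
        self.estimator = estimator
        self.alpha = alpha
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("Boruta requires both classes in the labels")
        names = list(df.columns)
        values = df.to_numpy(float)
        p = len(names)
        rng = np.random.default_rng(self.random_state)
        est = clone(self.estimator) if self.estimator is not None else RandomForestClassifier(
            n_estimators=100, random_state=self.random_state
        )
        if "random_state" in est.get_params():
            est.set_params(random_state=self.random_state)

        status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
        hits = np.zeros(p, dtype=int)
        tested = np.zeros(p, dtype=int)
        self.n_iterations_ = 0
        for _ in range(self.max_iter):
            live = status >= 0  # rejected features leave the design
            undecided = status == 0
            if not undecided.any():
                break
            self.n_iterations_ += 1
            X_live = values[:, live]
            shadows = X_live.copy()
            for j in range(shadows.shape[1]):
                shadows[:, j] = rng.permutation(shadows[:, j])
            est.fit(np.hstack([X_live, shadows]), y)
            imp = est.feature_importances_
            real_imp = np.full(p, -np.inf)
            real_imp[live] = imp[: X_live.shape[1]]
            shadow_max = imp[X_live.shape[1]:].max()
            hits[undecided & (real_imp > shadow_max)] += 1
            tested[undecided] += 1

            # two-sided binomial decisions, Bonferroni-corrected
            m = int(undecided.sum())
            for j in np.flatnonzero(undecided):
                n_t = tested[j]
                p_hi = stats.binom.sf(hits[j] - 1, n_t, 0.5)
                p_lo = stats.binom.cdf(hits[j], n_t, 0.5)
                if p_hi < self.alpha / m:
                    status[j] = 1
                elif p_lo < self.alpha / m:
                    status[j] = -1

        self.feature_names_in_ = names
        self.hit_counts_ = dict(zip(names, hits.tolist()))
        self.confirmed_ = [n for n, s in zip(names, status) if s == 1]
        self.rejected_ = [n for n, s in zip(names, status) if s == -1]
        self.tentative_ = [n for n, s in zip(names, status) if s == 0]
        self.support_ = status == 1
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        df = _as_frame(X)
        return df[self.confirmed_]


def boruta_select(
    fm, labels, cfg: Optional[SelectionConfig] = None
) -> dict[str, set[str]]:
    """Run Boruta; returns {"confirmed", "rejected", "tentative"} name sets."""
    cfg = cfg or SelectionConfig()
    sel = BorutaSelector(
        estimator=cfg.make_estimator(),
        alpha=cfg.boruta_alpha,
        max_iter=cfg.boruta_max_iter,
        random_state=cfg.seed,
    ).fit(fm, labels)
    return {
        "confirmed": set(sel.confirmed_),
        "rejected": set(sel.rejected_),
        "tentative": set(sel.tentative_),
    }


def find_correlation(corr: np.ndarray, cutoff: float = 0.90) -> np.ndarray:
    """Greedy high-correlation filter on an absolute correlation matrix.

    Repeatedly locates the pair with the highest |r| above the cutoff and
    drops the member with the larger mean absolute correlation to all other
    retained features (ties: the earlier column is dropped). Returns the
    boolean keep-mask over columns.
    """
    corr = np.abs(np.asarray(corr, dtype=float))
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    corr = corr.copy()
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(corr.shape[0], dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), corr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i, alive].sum() / max(1, alive.sum() - 1)
        mean_j = sub[j, alive].sum() / max(1, alive.sum() - 1)
        drop = (i if i < j else j) if np.isclose(mean_i, mean_j) else (i if mean_i > mean_j else j)
        alive[drop] = False
    return alive


def correlation_prune(fm, cutoff: float = 0.90) -> list[str]:
    """Retained feature names with max pairwise Pearson |r| <= cutoff.

    Computes the absolute correlation matrix and applies
    :func:`find_correlation`.
    """
    df = _as_frame(fm)
    if df.shape[1] < 2:
        return list(df.columns)
    values = df.to_numpy(float)
    if (values.std(axis=0) == 0).any():
        bad = [c for c, s in zip(df.columns, values.std(axis=0)) if s == 0]
        raise ValueError(f"constant columns present (drop_degenerate first): {bad[:5]}")
    alive = find_correlation(np.corrcoef(values, rowvar=False), cutoff)
    return [c for c, a in zip(df.columns, alive) if a]


class CorrelationPruner(BaseEstimator):
    """Transformer facade over :func:`correlation_prune` (``retained_`` fitted attr)."""

    def __init__(self, cutoff: float = 0.90):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        self.retained_ = correlation_prune(X, self.cutoff)
        return self

    def transform(self, X):
        return _as_frame(X)[self.retained_]


@dataclass
class FeatureRanking:
    """Complete RFE ranking; rank 1 was retained longest."""

    names_by_rank: list[str]  # index 0 = rank 1
    elimination_round: dict[str, int]  # 1 = eliminated first

    def __post_init__(self) -> None:
        if len(set(self.names_by_rank)) != len(self.names_by_rank):
            raise ValueError("ranking must be a permutation of the feature names")

    def rank(self, name: str) -> int:
        return self.names_by_rank.index(name) + 1

    def top(self, k: int) -> list[str]:
        return self.names_by_rank[:k]

    def __len__(self) -> int:
        return len(self.names_by_rank)


def rfe_rank(fm, labels, cfg: Optional[SelectionConfig] = None) -> FeatureRanking:
    """Recursive feature elimination to a complete ranking (step = cfg.rfe_step)."""
    cfg = cfg or SelectionConfig()
    df = _as_frame(fm)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("RFE requires both classes in the labels")
    if df.shape[1] == 1:
        return FeatureRanking(list(df.columns), {df.columns[0]: 1})
    rfe = RFE(cfg.make_estimator(), n_features_to_select=1, step=cfg.rfe_step)
    rfe.fit(df.to_numpy(float), y)
    order = np.argsort(rfe.ranking_, kind="stable")
    names_by_rank = [df.columns[i] for i in order]
    p = len(names_by_rank)
    # rank p leaves in round 1; rank 1 survives every round (recorded as p)
    rounds = {n: max(1, p - r + 1) if r > 1 else p
              for r, n in enumerate(names_by_rank, start=1)}
    return FeatureRanking(names_by_rank, rounds)


@dataclass
class SweepResult:
    """Per-size CV metrics of the nested-subset sweep and the chosen subset."""

    table: pd.DataFrame  # columns: k, ACC, AUC, score
    best_k: int
    best_features: list[str]
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def n_evaluations(self) -> int:
        return len(self.table) + len(self.errors)


def subset_sweep(
    fm: FeatureMatrix,
    labels,
    ranking: FeatureRanking,
    learner: LearnerSpec,
    k_folds: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Evaluate every ranking prefix k = p..1 with one fixed CV partition.

    The stratified fold assignment is computed once and shared across subset
    sizes for comparability. Chosen k* maximizes mean(AUC, ACC/100) with ties
    broken toward the smaller subset. Learner failures at some k are recorded,
    not fatal.
    """
    missing = set(ranking.names_by_rank) - set(fm.feature_names)
    if missing:
        raise ValueError(f"ranking names absent from matrix: {sorted(missing)[:5]}")
    y = np.asarray(labels, dtype=int)
    p = len(ranking)
    rows = []
    errors: dict[int, str] = {}
    for k in range(p, 0, -1):
        subset = ranking.top(k)
        try:
            res = ev.cross_validate(
                lambda: LearnerRecipe(learner, subset), fm, y, k=k_folds, seed=seed
            )
        except Exception as exc:  # recorded, sweep continues
            errors[k] = f"{type(exc).__name__}: {exc}"
            continue
        score = (res.report.auc + res.report.acc / 100.0) / 2.0
        rows.append({"k": k, "ACC": res.report.acc, "AUC": res.report.auc, "score": score})
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("sweep failed at every subset size")
    # max score; ties toward smaller k
    best = table.sort_values(["score", "k"], ascending=[False, True]).iloc[0]
    best_k = int(best["k"])
    return SweepResult(
        table=table.reset_index(drop=True),
        best_k=best_k,
        best_features=ranking.top(best_k),
        errors=errors,
    )


def sweep_evaluation_count(widths: Iterable[int], n_learners: int = 1) -> int:
    """Bookkeeping: total sweep evaluations for the given post-pruning widths.

    Each family of width p contributes exactly p evaluations per learner
    (k = p down to 1, step 1).
    """
    return int(sum(int(w) for w in widths)) * int(n_learners)


def load_reference_selection_widths() -> pd.DataFrame:
    """Published per-family selection-cascade widths shipped as package data.

    Columns: family, raw, all_relevant (post-Boruta), pruned
    (post-correlation-filter). Used for sweep bookkeeping on a metadata-only
    stand-in for the full training set.
    """
    from importlib.resources import files

    path = files("hepatoscreen.data").joinpath("family_selection_widths.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
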