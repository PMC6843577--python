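"""Performance metrics, cross-validation, external validation, Y-randomization.

Metric conventions: accuracy is reported on the 0-100 scale, sensitivity /
specificity / balanced accuracy / AUC on the 0-1 scale. Balanced accuracy is
the plain mean of sensitivity and specificity. Cross-validation pools the
out-of-fold predictions into a single confusion matrix (the WEKA summary
convention) rather than averaging per-fold metrics. Display rounding is
round-half-up to three decimals; internal values keep full precision.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .featurize import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "YRandomizationResult",
    "round_half_up",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
    "y_randomization",
    "evaluate_external",
]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal round-half-up (0.7225 -> 0.723 at 3 decimals).

    Inputs are first quantized at 9 decimals (half-even) so that binary-float
    noise around an exact decimal midpoint — (0.725+0.720)/2 stored as
    0.72249999... — still rounds the way the decimal arithmetic would.
    """
    guard = Decimal(repr(float(x))).quantize(Decimal("1e-9"))
    q = Decimal(1).scaleb(-decimals)
    return float(guard.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN cell counts (positives = hepatotoxicants)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label/prediction length mismatch")
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """ACC (0-100), SE/SP/BACC/AUC (0-1) plus the underlying cell counts."""

    acc: float
    se: float
    sp: float
    bacc: float
    cm: ConfusionMatrix
    auc: Optional[float] = None
    rounding: int = 3

    def display(self) -> dict[str, float]:
        """Rounded view for reports (round-half-up)."""
        out = {
            "ACC": round_half_up(self.acc, self.rounding),
            "SE": round_half_up(self.se, self.rounding),
            "SP": round_half_up(self.sp, self.rounding),
            "BACC": round_half_up(self.bacc, self.rounding),
        }
        if self.auc is not None:
            out["AUC"] = round_half_up(self.auc, self.rounding)
        out.update(TP=self.cm.tp, TN=self.cm.tn, FP=self.cm.fp, FN=self.cm.fn)
        return out


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """ACC/SE/SP/BACC from a confusion matrix (AUC left unset)."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise ValueError("no positives present; sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no negatives present; specificity undefined")
    se = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    return MetricsReport(
        acc=100.0 * (cm.tp + cm.tn) / cm.n,
        se=se,
        sp=sp,
        bacc=(se + sp) / 2.0,
        cm=cm,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """AUC (ties half-weighted) plus the ROC point list.

    Equals the rank-statistic formulation P(score_pos > score_neg) +
    0.5 * P(tie).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC analysis requires both classes")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# generic model protocol helpers

FeatureView = "pd.DataFrame | np.ndarray | Mapping[str, FeatureMatrix]"


def subset_rows(X, positions: np.ndarray):
    """Row subset for an array, DataFrame, FeatureMatrix or a family mapping."""
    if isinstance(X, Mapping):
        return {k: subset_rows(v, positions) for k, v in X.items()}
    if isinstance(X, FeatureMatrix):
        return X.subset_rows(positions)
    if isinstance(X, pd.DataFrame):
        return X.iloc[positions]
    return np.asarray(X)[positions]


def _n_rows(X) -> int:
    if isinstance(X, Mapping):
        return _n_rows(next(iter(X.values())))
    if isinstance(X, FeatureMatrix):
        return len(X.row_ids)
    return len(X)


def _positive_scores(model, X) -> np.ndarray:
    """Probability of the positive (hepatotoxic) class from a fitted model."""
    if hasattr(model, "predict_proba_pos"):
        return np.asarray(model.predict_proba_pos(X), dtype=float)
    proba = np.asarray(model.predict_proba(X), dtype=float)
    if proba.ndim == 1:
        return proba
    classes = getattr(model, "classes_", np.array([0, 1]))
    return proba[:, list(classes).index(1)]


@dataclass
class CVResult:
    """Pooled k-fold predictions and their metrics."""

    report: MetricsReport
    table: pd.DataFrame  # index: row position; columns: fold, truth, probability, label
    k: int
    seed: int

    @property
    def fold_assignment(self) -> np.ndarray:
        return self.table["fold"].to_numpy()


def cross_validate(
    model_factory: Callable[[], object],
    X,
    y: Sequence[int],
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold CV with pooled-fold metrics.

    Every compound is predicted exactly once by a model that never saw it in
    training; any preprocessing lives inside the model/pipeline and is thus
    refitted per fold. ``model_factory`` must return a fresh unfitted model.
    """
    y = np.asarray(y, dtype=int)
    n = _n_rows(X)
    if n != len(y):
        raise ValueError("feature/label length mismatch")
    counts = np.bincount(y, minlength=2)
    if stratified and counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    fold = np.full(n, -1, dtype=int)
    prob = np.full(n, np.nan)
    for f, (tr, te) in enumerate(splitter.split(np.zeros(n), y)):
        model = model_factory()
        model.fit(subset_rows(X, tr), y[tr])
        prob[te] = _positive_scores(model, subset_rows(X, te))
        fold[te] = f
    pred = (prob > threshold).astype(int)
    report = compute_metrics(ConfusionMatrix.from_predictions(y, pred))
    report.auc, _ = roc_auc(prob, y)
    table = pd.DataFrame(
        {"fold": fold, "truth": y, "probability": prob, "label": pred}
    )
    return CVResult(report=report, table=table, k=k, seed=seed)


@dataclass
class YRandomizationResult:
    accs: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.accs, dtype=float)
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def y_randomization(
    model_factory: Callable[[], object],
    X,
    y: Sequence[int],
    runs: int = 100,
    k: int = 10,
    seed: int = 0,
) -> YRandomizationResult:
    """Label-permutation validation: CV accuracy under shuffled labels.

    Each run permutes the labels uniformly at random (features untouched,
    class counts preserved) and re-runs the full cross-validation. A sound
    model scores at chance, certifying that the unpermuted signal is real.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    accs = []
    for r in range(runs):
        y_perm = rng.permutation(y)
        res = cross_validate(model_factory, X, y_perm, k=k, seed=seed + r)
        accs.append(res.report.acc)
    return YRandomizationResult(accs=accs)


def evaluate_external(
    model,
    X_ext,
    y_ext: Sequence[int],
    ids: Optional[Sequence[str]] = None,
    names: Optional[Sequence[str]] = None,
    train_keys: Optional[set[str]] = None,
    external_keys: Optional[Sequence[str]] = None,
    overlap_fraction_limit: float = 0.0,
    strict: bool = False,
    threshold: float = 0.5,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Score a fitted model on an external hold-out set.

    When ``train_keys``/``external_keys`` are given, checks training/external
    disjointness by structure key; violations raise in strict mode when they
    exceed ``overlap_fraction_limit``, else warn.
    """
    import warnings

    y_ext = np.asarray(y_ext, dtype=int)
    if train_keys is not None and external_keys is not None:
        overlap = [k for k in external_keys if k in train_keys]
        frac = len(overlap) / max(1, len(list(external_keys)))
        if overlap and frac > overlap_fraction_limit and strict:
            raise ValueError(
                f"{len(overlap)} external compounds overlap the training set"
            )
        if overlap:
            warnings.warn(f"{len(overlap)} external compounds overlap the training set")
    prob = _positive_scores(model, X_ext)
    pred = (prob > threshold).astype(int)
    report = compute_metrics(ConfusionMatrix.from_predictions(y_ext, pred))
    report.auc, _ = roc_auc(prob, y_ext)
    n = len(y_ext)
    table = pd.DataFrame(
        {
            "id": list(ids) if ids is not None else list(range(n)),
            "name": list(names) if names is not None else [""] * n,
            "probability": prob,
            "label": pred,
            "truth": y_ext,
        }
    )
    return report, table
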