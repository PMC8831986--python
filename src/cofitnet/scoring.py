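"""Classifier benchmarking, ROC analysis and pair scoring.

Four interchangeable scorer backends (MARS, random forest, RBF-kernel SVM,
distance-weighted kNN) are compared under repeated stratified k-fold
cross-validation; the winner is chosen by mean out-of-fold AUROC, the edge
threshold is picked on the out-of-fold ROC curve by the Youden index, and
the refitted winner scores the full pair universe.

All backends expose ``fit(X, y)`` and ``score_samples(X) -> scores in [0,1]``.
Only the MARS backend is implemented in this package (it is the method of
interest); the comparators are thin wrappers over scikit-learn estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .mars import fit_mars
from .reference import TrainingTable

__all__ = [
    "BACKENDS",
    "ScorerSpec",
    "CVResult",
    "ROCResult",
    "make_scorer",
    "stratified_cv",
    "roc_analysis",
    "best_threshold",
    "score_pairs",
    "threshold_edges",
    "score_all_pairs",
]

BACKENDS = ("mars", "random_forest", "svm_rbf", "knn_weighted")


@dataclass(frozen=True)
class ScorerSpec:
    backend: str = "mars"
    seed: int = 0
    hyperparams: tuple = ()  # sorted (key, value) pairs; dataclass must stay hashable

    def params(self) -> dict:
        return dict(self.hyperparams)

    @staticmethod
    def make(backend: str, seed: int = 0, **hyper) -> "ScorerSpec":
        if backend not in BACKENDS:
            raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")
        return ScorerSpec(backend, seed, tuple(sorted(hyper.items())))


class _MarsScorer:
    def __init__(self, seed: int = 0, **kw):
        self.kw = kw
        self.model_ = None

    def fit(self, X, y):
        self.model_ = fit_mars(X, y, **self.kw)
        return self

    def score_samples(self, X):
        return self.model_.score_samples(X)


class _SklearnScorer:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(X, y)
        return self

    def score_samples(self, X):
        return self.est.predict_proba(X)[:, 1]


def make_scorer(spec: ScorerSpec):
    """Instantiate an unfitted scorer for a backend spec."""
    p = spec.params()
    if spec.backend == "mars":
        return _MarsScorer(seed=spec.seed, **p)
    if spec.backend == "random_forest":
        return _SklearnScorer(
            RandomForestClassifier(
                n_estimators=p.get("n_estimators", 100),
                random_state=spec.seed,
                n_jobs=1,
            )
        )
    if spec.backend == "svm_rbf":
        # Platt-calibrated decision values so the backend emits probabilities
        svc = SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
                  random_state=spec.seed)
        return _SklearnScorer(CalibratedClassifierCV(svc, ensemble=False))
    if spec.backend == "knn_weighted":
        return _SklearnScorer(
            KNeighborsClassifier(
                n_neighbors=p.get("n_neighbors", 10), weights="distance"
            )
        )
    raise ValueError(f"unknown backend {spec.backend!r}")


@dataclass
class CVResult:
    """Out-of-fold scores from repeated stratified k-fold CV."""

    model_id: str
    y: np.ndarray  # (n_rows,)
    oof_scores: np.ndarray  # (repeats, n_rows)
    fold_assignment: np.ndarray  # (repeats, n_rows) int fold ids
    aurocs: list[float] = field(default_factory=list)  # one per repeat

    def mean_auroc(self) -> float:
        return float(np.mean(self.aurocs))

    def pooled_scores(self) -> np.ndarray:
        """Per-row mean out-of-fold score across repeats."""
        return self.oof_scores.mean(axis=0)


def stratified_cv(
    spec: ScorerSpec,
    table: TrainingTable,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV; every row scored once out-of-fold per repeat."""
    X, y = table.X, table.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for cross-validation")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds minority class count ({int(counts.min())})"
        )
    n = len(y)
    oof = np.full((repeats, n), np.nan)
    folds = np.full((repeats, n), -1, dtype=int)
    aurocs = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold_id, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            scorer = make_scorer(spec)
            scorer.fit(X[train_idx], y[train_idx])
            oof[rep, test_idx] = scorer.score_samples(X[test_idx])
            folds[rep, test_idx] = fold_id
        if np.isnan(oof[rep]).any() or (folds[rep] < 0).any():
            raise AssertionError("CV folds failed to partition the rows")
        aurocs.append(roc_analysis(oof[rep], y).auroc)
    return CVResult(
        model_id=spec.backend, y=y.copy(), oof_scores=oof, fold_assignment=folds,
        aurocs=aurocs,
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending; +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    auroc_concordance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve under the rule "predict positive iff score > threshold".

    The trapezoidal area is cross-checked against the concordance
    (Mann-Whitney) form (#{pos > neg} + 0.5 #ties) / (#pos * #neg); the two
    agree to numerical precision by construction and both are reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both classes, got {n_pos} positives / {n_neg} negatives")

    grid = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    sens = np.array([(pos_scores > t).mean() for t in grid])
    spec = np.array([(neg_scores <= t).mean() for t in grid])

    fpr = 1.0 - spec
    auroc = float(np.trapezoid(sens, fpr))

    ranks = rankdata(scores)
    auroc_conc = float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )
    if abs(auroc - auroc_conc) > 1e-8:
        raise AssertionError(
            f"trapezoid AUROC {auroc} disagrees with concordance {auroc_conc}"
        )
    return ROCResult(grid, sens, spec, auroc, auroc_conc)


def best_threshold(
    roc: ROCResult, method: str = "youden"
) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties go to the larger threshold (the sparser network).  The +inf curve
    sentinel is not a usable operating point and is excluded.
    """
    if method != "youden":
        raise ValueError(f"unknown threshold method {method!r}")
    usable = np.isfinite(roc.thresholds) | (roc.thresholds == -np.inf)
    j = roc.sensitivity + roc.specificity - 1.0
    j = np.where(usable, j, -np.inf)
    best_j = j.max()
    # thresholds are descending: first index attaining the max is the largest
    idx = int(np.argmax(j >= best_j - 1e-12))
    return (
        float(roc.thresholds[idx]),
        float(roc.sensitivity[idx]),
        float(roc.specificity[idx]),
    )


def score_pairs(
    scorer, features: pd.DataFrame, scaler: TrainingTable
) -> pd.DataFrame:
    """Score every feature row with the fitted scorer, reusing training z-stats."""
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    raw = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = scaler.transform(raw)
    scored = features[["gene_a", "gene_b"]].copy()
    scored["score"] = scorer.score_samples(X)
    return scored


def threshold_edges(scored: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Edges = pairs scoring strictly above the cutoff, weight = score."""
    edges = scored[scored["score"] > cutoff].reset_index(drop=True)
    return edges[["gene_a", "gene_b", "score"]]


def score_all_pairs(
    scorer, features: pd.DataFrame, cutoff: float, scaler: TrainingTable
) -> pd.DataFrame:
    """Convenience composition: score the universe, keep pairs above cutoff."""
    return threshold_edges(score_pairs(scorer, features, scaler), cutoff)
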