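"""Two-step feature selection: ANOVA ranking then incremental selection.

Step one scores every feature by the ratio of between-group to
within-group variance,

    S(t) = S_B^2(t) / S_W^2(t),

with S_B^2 = (1/(K-1)) sum_i m_i (mean_i - grand_mean)^2 and
S_W^2 = (1/(N-K)) sum_ij (x_ij - mean_i)^2 over K groups of sizes m_i —
for two groups this is exactly the one-way ANOVA F statistic. Features
with zero within-group variance but distinct group means are perfectly
discriminative and receive a +inf sentinel, ranking ahead of all finite
scores; features that are constant everywhere score 0.

Step two (incremental feature selection, IFS) walks the ranked list in
increments, cross-validates a classifier on each leading subset, and keeps
the subset maximising the chosen objective (ties favour the smaller
subset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin

from .encoders import FeatureMatrix
from .metrics import EvalReport, evaluate
from .model import CVConfig, WekaStyleRandomForest, pooled_oof_scores

__all__ = [
    "AnovaRanking",
    "SelectionResult",
    "anova_f_statistic",
    "anova_scores",
    "incremental_select",
    "AnovaIncrementalSelector",
]

_OBJECTIVES = ("sn", "sp", "acc", "mcc", "auc")


def anova_f_statistic(X, y) -> np.ndarray:
    """Per-column ratio of between- to within-group variance (the F score).

    Supports K >= 2 groups; binary labels give K = 2. Columns with zero
    within-group variance map to +inf (group means differ) or 0 (they
    coincide).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    groups = np.unique(y)
    K, N = len(groups), len(y)
    if K < 2:
        raise ValueError("need at least two groups to score features")
    if N - K < 1:
        raise ValueError(f"need N - K >= 1 samples, got N={N}, K={K}")
    counts = np.array([np.sum(y == g) for g in groups])
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per group")
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g, m in zip(groups, counts):
        block = X[y == g]
        mean_g = block.mean(axis=0)
        ss_between += m * (mean_g - grand) ** 2
        ss_within += ((block - mean_g) ** 2).sum(axis=0)
    s_b = ss_between / (K - 1)
    s_w = ss_within / (N - K)
    scores = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(s_b, s_w, out=scores)
    zero_w = np.isclose(s_w, 0.0, atol=0.0)
    scores[zero_w & (s_b > 0)] = np.inf
    scores[zero_w & np.isclose(s_b, 0.0, atol=0.0)] = 0.0
    return scores


@dataclass
class AnovaRanking:
    """ANOVA scores and the induced descending feature order."""

    scores: np.ndarray
    order: np.ndarray  # permutation of 0..d-1, descending score, stable ties

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "AnovaRanking":
        scores = np.asarray(scores, dtype=float)
        order = np.argsort(-scores, kind="stable")
        return cls(scores=scores, order=order)


def anova_scores(features: FeatureMatrix) -> AnovaRanking:
    """Rank a labelled feature matrix by ANOVA score."""
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    return AnovaRanking.from_scores(
        anova_f_statistic(features.values, features.labels)
    )


@dataclass
class SelectionResult:
    """Outcome of ANOVA + IFS: the curve and the optimal subset."""

    ranking: AnovaRanking
    curve: list[tuple[int, EvalReport]]
    optimal_size: int
    optimal_features: list[str]
    objective: str

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "objective": self.objective,
            "scores": self.ranking.scores.tolist(),
            "order": self.ranking.order.tolist(),
            "curve": [
                {"size": size, "report": rep.to_dict()}
                for size, rep in self.curve
            ],
            "optimal_size": self.optimal_size,
            "optimal_features": self.optimal_features,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def curve_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("size\tsn\tsp\tacc\tmcc\tauc\n")
            for size, rep in self.curve:
                fh.write(
                    f"{size}\t{rep.sn!r}\t{rep.sp!r}\t{rep.acc!r}"
                    f"\t{rep.mcc!r}\t{rep.auc!r}\n"
                )
        return path


def _subset_sizes(d: int, step: int, max_size: int | None) -> list[int]:
    if step < 1:
        raise ValueError("step must be >= 1")
    cap = d if max_size is None else min(max_size, d)
    if cap < 1:
        raise ValueError("max_size must be >= 1")
    sizes = list(range(step, cap + 1, step))
    if not sizes or sizes[-1] != cap:
        sizes.append(cap)
    return sizes


def _choose_optimal(curve: list[tuple[int, EvalReport]], objective: str) -> int:
    best_size, best_val = None, -np.inf
    for size, rep in curve:
        val = rep.objective(objective)
        if val > best_val:  # strict: ties keep the earlier (smaller) size
            best_size, best_val = size, val
    assert best_size is not None
    return best_size


class AnovaIncrementalSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector running the ANOVA + IFS procedure in ``fit``.

    Parameters
    ----------
    estimator : classifier with a ``decision_scores`` method, optional
        Model cross-validated on each candidate subset; defaults to the
        WEKA-style random forest.
    cv : int
        Stratified fold count for the inner cross-validation.
    objective : {"sn", "sp", "acc", "mcc", "auc"}
        Metric maximised over the IFS curve.
    step : int
        Increment between candidate subset sizes (the full sweep uses 1).
    max_size : int, optional
        Cap on subset size; the cap itself is always evaluated.
    random_state : int
        Seed for fold construction and the default estimator.

    Attributes
    ----------
    scores_ : ndarray
        ANOVA score per input feature.
    ranking_ : ndarray
        Feature indices in descending-score order.
    curve_ : list of (size, EvalReport)
        Cross-validated performance of each leading subset.
    optimal_size_ : int
        Objective-maximising subset size (ties -> smallest).
    support_ : ndarray of bool
        Mask of the selected features.
    """

    def __init__(self, estimator=None, cv: int = 5, objective: str = "auc",
                 step: int = 1, max_size: int | None = None,
                 random_state: int = 0):
        self.estimator = estimator
        self.cv = cv
        self.objective = objective
        self.step = step
        self.max_size = max_size
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.objective not in _OBJECTIVES:
            raise ValueError(
                f"objective must be one of {_OBJECTIVES}, "
                f"got {self.objective!r}"
            )
        if self.cv < 2:
            raise ValueError("cv folds must be >= 2")
        base = (
            self.estimator
            if self.estimator is not None
            else WekaStyleRandomForest(random_state=self.random_state)
        )
        cv_cfg = CVConfig(folds=self.cv, stratified=True,
                          seed=self.random_state)
        self.scores_ = anova_f_statistic(X, y)
        self.ranking_ = AnovaRanking.from_scores(self.scores_).order
        self.curve_ = []
        for size in _subset_sizes(X.shape[1], self.step, self.max_size):
            cols = self.ranking_[:size]
            oof = pooled_oof_scores(clone(base), X[:, cols], y, cv_cfg)
            self.curve_.append((size, evaluate(y, oof)))
        self.optimal_size_ = _choose_optimal(self.curve_, self.objective)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_[: self.optimal_size_]] = True
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise ValueError("selector is not fitted")
        return self.support_

    def transform(self, X):
        """Select columns, preserving the ranked order of the subset."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, selector was fitted on "
                f"{self.n_features_in_}"
            )
        return X[:, self.ranking_[: self.optimal_size_]]


def incremental_select(
    features: FeatureMatrix,
    ranking: AnovaRanking | None = None,
    cv: CVConfig = CVConfig(),
    objective: str = "auc",
    step: int = 1,
    max_size: int | None = None,
    estimator=None,
) -> SelectionResult:
    """Run IFS over a labelled feature matrix and a (possibly precomputed)
    ANOVA ranking; returns the performance curve and the optimal subset."""
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    if ranking is None:
        ranking = anova_scores(features)
    if len(ranking.order) != features.n_features:
        raise ValueError(
            f"ranking covers {len(ranking.order)} features, matrix has "
            f"{features.n_features}"
        )
    if objective not in _OBJECTIVES:
        raise ValueError(
            f"objective must be one of {_OBJECTIVES}, got {objective!r}"
        )
    base = estimator if estimator is not None else WekaStyleRandomForest(
        random_state=cv.seed
    )
    X, y = features.values, features.labels
    curve: list[tuple[int, EvalReport]] = []
    for size in _subset_sizes(features.n_features, step, max_size):
        cols = ranking.order[:size]
        oof = pooled_oof_scores(clone(base), X[:, cols], y, cv)
        curve.append((size, evaluate(y, oof)))
    optimal_size = _choose_optimal(curve, objective)
    optimal_features = [
        features.feature_names[i] for i in ranking.order[:optimal_size]
    ]
    return SelectionResult(ranking, curve, optimal_size, optimal_features,
                           objective)
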