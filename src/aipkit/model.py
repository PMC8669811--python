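"""Random-forest classification, cross-validation and model persistence.

The forest follows WEKA's RandomForest defaults: 100 trees, unlimited
depth, and floor(log2(d)) + 1 candidate features per split for d input
features. The backend is scikit-learn's RandomForestClassifier; the split
rule is computed at fit time so the log2-plus-one convention is exact.
"""

from __future__ import annotations

import datetime
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .encoders import FeatureMatrix
from .metrics import EvalReport, evaluate

__all__ = [
    "RFConfig",
    "CVConfig",
    "WekaStyleRandomForest",
    "TrainedModel",
    "train_rf",
    "predict",
    "cross_validate",
    "pooled_oof_scores",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_SCHEMA_TAG = "aipkit-model/1"


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (defaults mirror WEKA's)."""

    n_trees: int = 100
    features_per_split: str | int = "log2"  # "log2" -> floor(log2 d) + 1
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        fps = self.features_per_split
        if not (fps in ("log2", "sqrt") or isinstance(fps, int)):
            raise ValueError(
                "features_per_split must be 'log2', 'sqrt' or an integer"
            )


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation layout: fold count, stratification, shuffle seed."""

    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class WekaStyleRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest with the WEKA default feature-subsampling rule.

    Parameters
    ----------
    n_trees : int
        Number of trees in the ensemble.
    features_per_split : {"log2", "sqrt"} or int
        Candidate features per split; ``"log2"`` means
        ``floor(log2(d)) + 1`` (WEKA's default), capped at d.
    max_depth : int or None
        Tree depth limit (None = grow until pure).
    random_state : int
        Seed for bootstrap and feature subsampling.
    """

    def __init__(self, n_trees: int = 100,
                 features_per_split: str | int = "log2",
                 max_depth: int | None = None, random_state: int = 0):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.max_depth = max_depth
        self.random_state = random_state

    def _resolve_max_features(self, d: int) -> int | str:
        fps = self.features_per_split
        if fps == "log2":
            return min(d, int(math.floor(math.log2(d))) + 1) if d > 1 else 1
        if fps == "sqrt":
            return "sqrt"
        if isinstance(fps, (int, np.integer)) and fps >= 1:
            return min(d, int(fps))
        raise ValueError(
            f"features_per_split must be 'log2', 'sqrt' or a positive "
            f"integer, got {fps!r}"
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        if not set(classes.tolist()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self._resolve_max_features(X.shape[1]),
            max_depth=self.max_depth,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class vote fraction in [0, 1]."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def predict(self, X) -> np.ndarray:
        # score exactly 0.5 predicts positive (fixed boundary convention)
        return (self.decision_scores(X) >= 0.5).astype(int)


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature names it was trained on."""

    estimator: WekaStyleRandomForest
    feature_names: list[str]
    config: RFConfig
    n_pos: int
    n_neg: int
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat(timespec="seconds")
    )

    def check_features(self, features: FeatureMatrix) -> None:
        if features.feature_names != self.feature_names:
            for i, (a, b) in enumerate(
                zip(features.feature_names, self.feature_names)
            ):
                if a != b:
                    raise ValueError(
                        f"feature mismatch at column {i}: got {a!r}, "
                        f"model expects {b!r}"
                    )
            raise ValueError(
                f"feature count mismatch: got {features.n_features}, "
                f"model expects {len(self.feature_names)}"
            )


def train_rf(features: FeatureMatrix, config: RFConfig = RFConfig()) -> TrainedModel:
    """Fit the random forest on a labelled feature matrix."""
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    y = features.labels
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n_pos, n_neg) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {n_pos} positive / "
            f"{n_neg} negative"
        )
    est = WekaStyleRandomForest(
        n_trees=config.n_trees,
        features_per_split=config.features_per_split,
        max_depth=config.max_depth,
        random_state=config.seed,
    ).fit(features.values, y)
    return TrainedModel(est, list(features.feature_names), config, n_pos, n_neg)


def predict(model: TrainedModel, features: FeatureMatrix
            ) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class scores in [0, 1] and hard labels at threshold 0.5."""
    model.check_features(features)
    scores = model.estimator.decision_scores(features.values)
    return scores, (scores >= 0.5).astype(int)


def _make_splitter(cv: CVConfig):
    if cv.stratified:
        return StratifiedKFold(n_splits=cv.folds, shuffle=True,
                               random_state=cv.seed)
    return KFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)


def pooled_oof_scores(estimator, X, y, cv: CVConfig) -> np.ndarray:
    """Out-of-fold positive-class scores for every sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv.folds:
        raise ValueError(
            f"folds={cv.folds} exceeds smallest class size {counts.min()}"
        )
    scores = np.full(len(y), np.nan)
    for train_idx, test_idx in _make_splitter(cv).split(X, y):
        est = clone(estimator).fit(X[train_idx], y[train_idx])
        scores[test_idx] = est.decision_scores(X[test_idx])
    assert not np.isnan(scores).any()
    return scores


def cross_validate(
    features: FeatureMatrix,
    rf: RFConfig = RFConfig(),
    cv: CVConfig = CVConfig(),
) -> tuple[EvalReport, list[EvalReport]]:
    """Stratified k-fold CV; pooled report from out-of-fold scores.

    Returns the pooled report (headline) plus one report per fold.
    """
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    X, y = features.values, features.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv.folds:
        raise ValueError(
            f"folds={cv.folds} exceeds smallest class size {counts.min()}"
        )
    base = WekaStyleRandomForest(
        n_trees=rf.n_trees, features_per_split=rf.features_per_split,
        max_depth=rf.max_depth, random_state=rf.seed,
    )
    scores = np.full(len(y), np.nan)
    fold_reports: list[EvalReport] = []
    for train_idx, test_idx in _make_splitter(cv).split(X, y):
        est = clone(base).fit(X[train_idx], y[train_idx])
        fold_scores = est.decision_scores(X[test_idx])
        scores[test_idx] = fold_scores
        fold_reports.append(evaluate(y[test_idx], fold_scores))
    pooled = evaluate(y, scores)
    return pooled, fold_reports


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist as a joblib blob plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "schema": _SCHEMA_TAG,
        "config": asdict(model.config),
        "feature_names": model.feature_names,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "timestamp": model.timestamp,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing model sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema") != _SCHEMA_TAG:
        raise ValueError(
            f"unsupported model schema {sidecar.get('schema')!r}; "
            f"expected {_SCHEMA_TAG}"
        )
    est = joblib.load(path)
    cfg = sidecar["config"]
    fps = cfg["features_per_split"]
    return TrainedModel(
        estimator=est,
        feature_names=list(sidecar["feature_names"]),
        config=RFConfig(n_trees=cfg["n_trees"], features_per_split=fps,
                        max_depth=cfg["max_depth"], seed=cfg["seed"]),
        n_pos=sidecar["n_pos"],
        n_neg=sidecar["n_neg"],
        timestamp=sidecar["timestamp"],
    )
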