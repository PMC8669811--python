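"""End-to-end experiment driver: encode -> rank -> select -> cross-validate.

The headline cross-validated report keeps feature selection *inside* each
training fold: ANOVA ranking and the incremental-selection sweep see only
the fold's training portion, and the fold's held-out samples are scored by
a forest fitted on the selected subset. Pooling those out-of-fold scores
gives an unbiased estimate — running selection on the full data first and
then cross-validating the chosen subset re-uses every label twice and
inflates the apparent performance (measurably so on null data).

Selection on the complete training set is still what defines the final
deployable model, and ``run_pipeline`` produces that artifact as well when
``fit_final=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoders import CodonTable, FeatureMatrix, encode_features
from .metrics import EvalReport, evaluate
from .model import (
    CVConfig,
    RFConfig,
    TrainedModel,
    WekaStyleRandomForest,
    _make_splitter,
    cross_validate,
    train_rf,
)
from .peptide_io import PeptideSet
from .selection import SelectionResult, incremental_select

__all__ = ["PipelineResult", "run_pipeline", "nested_cv_report"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    features: FeatureMatrix
    cv_report: EvalReport
    fold_reports: list[EvalReport]
    selection: SelectionResult | None = None
    model: TrainedModel | None = None

    @property
    def auc(self) -> float:
        return self.cv_report.auc


def _rf_estimator(rf: RFConfig) -> WekaStyleRandomForest:
    return WekaStyleRandomForest(
        n_trees=rf.n_trees, features_per_split=rf.features_per_split,
        max_depth=rf.max_depth, random_state=rf.seed,
    )


def nested_cv_report(
    features: FeatureMatrix,
    rf: RFConfig = RFConfig(),
    cv: CVConfig = CVConfig(),
    objective: str = "auc",
    step: int = 1,
    max_size: int | None = None,
) -> tuple[EvalReport, list[EvalReport]]:
    """Pooled CV report with ANOVA+IFS re-run inside every training fold."""
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    X, y = features.values, features.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv.folds:
        raise ValueError(
            f"folds={cv.folds} exceeds smallest class size {counts.min()}"
        )
    scores = np.full(len(y), np.nan)
    fold_reports: list[EvalReport] = []
    for train_idx, test_idx in _make_splitter(cv).split(X, y):
        train_fm = FeatureMatrix(
            X[train_idx], list(features.feature_names),
            [features.sample_ids[i] for i in train_idx], y[train_idx],
        )
        sel = incremental_select(
            train_fm, cv=cv, objective=objective, step=step,
            max_size=max_size,
        )
        cols = sel.ranking.order[: sel.optimal_size]
        est = _rf_estimator(rf).fit(X[np.ix_(train_idx, cols)], y[train_idx])
        fold_scores = est.decision_scores(X[np.ix_(test_idx, cols)])
        scores[test_idx] = fold_scores
        fold_reports.append(evaluate(y[test_idx], fold_scores))
    pooled = evaluate(y, scores)
    return pooled, fold_reports


def run_pipeline(
    peptides: PeptideSet,
    encoders: Sequence[str] = ("aac", "dde", "gdc1"),
    select: bool = True,
    step: int = 1,
    max_size: int | None = None,
    objective: str = "auc",
    rf: RFConfig = RFConfig(),
    cv: CVConfig = CVConfig(),
    codon_table: CodonTable | None = None,
    fit_final: bool = False,
) -> PipelineResult:
    """Run the full identification protocol on a labelled peptide set.

    With ``select=True`` the cross-validated report nests ANOVA+IFS inside
    each training fold; with ``select=False`` the forest is simply
    cross-validated on the full concatenated feature matrix. When
    ``fit_final=True`` selection is additionally run once on all data and
    a forest is fitted on the chosen subset — the deployable model, whose
    selection curve is reported in ``selection``.
    """
    features = encode_features(peptides, encoders, codon_table=codon_table)
    if features.labels is None:
        raise ValueError("peptides must all carry binary labels")
    if select:
        pooled, folds = nested_cv_report(
            features, rf=rf, cv=cv, objective=objective, step=step,
            max_size=max_size,
        )
    else:
        pooled, folds = cross_validate(features, rf=rf, cv=cv)
    selection: SelectionResult | None = None
    model: TrainedModel | None = None
    if fit_final:
        if select:
            selection = incremental_select(
                features, cv=cv, objective=objective, step=step,
                max_size=max_size,
            )
            final_fm = features.select(selection.optimal_features)
        else:
            final_fm = features
        model = train_rf(final_fm, rf)
    return PipelineResult(features=features, cv_report=pooled,
                          fold_reports=folds, selection=selection,
                          model=model)
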