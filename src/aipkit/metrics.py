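"""Binary-classifier evaluation: confusion counts, SN/SP/ACC/MCC, ROC, AUC.

Conventions: the positive class is label 1; sensitivity SN = TP/(TP+FN),
specificity SP = TN/(TN+FP), ACC = (TP+TN)/n, and MCC is the Matthews
correlation coefficient with the value 0 returned whenever one of its
denominator factors vanishes. AUC is the Mann-Whitney probability that a
random positive outscores a random negative, with ties credited 1/2 —
equivalent to the trapezoidal area under the tie-grouped ROC curve.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvalReport", "confusion_metrics", "roc_auc", "evaluate"]

logger = logging.getLogger(__name__)


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    vals = set(np.unique(v).tolist())
    if not vals <= {0, 1}:
        raise ValueError(f"{name} must be binary 0/1, found {sorted(vals)}")
    return v.astype(int)


@dataclass
class EvalReport:
    """Evaluation summary for one model on one labelled sample set."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    threshold: float = 0.5
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def objective(self, name: str) -> float:
        """Look up a metric by its conventional short name."""
        name = name.lower()
        table = {"sn": self.sn, "sp": self.sp, "acc": self.acc,
                 "mcc": self.mcc, "auc": self.auc}
        if name not in table:
            raise ValueError(
                f"unknown objective {name!r}; choose from {sorted(table)}"
            )
        value = table[name]
        if value is None:
            raise ValueError(f"objective {name!r} not available (no scores)")
        return value

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
            "threshold": self.threshold, "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def roc_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr!r}\t{tpr!r}\n")
        return path


def confusion_metrics(labels, predictions, threshold: float = 0.5) -> EvalReport:
    """SN, SP, ACC and MCC from hard binary predictions."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(
            f"length mismatch: {y.shape[0]} labels, {p.shape[0]} predictions"
        )
    if len(set(np.unique(y))) < 2:
        logger.debug("labels contain a single class; SN or SP is degenerate")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = tp + tn + fp + fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n if n else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("MCC denominator factor is zero; returning 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, sn=sn, sp=sp, acc=acc,
                      mcc=mcc, threshold=threshold)


def roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over all distinct score thresholds, and its AUC.

    Returns the (FPR, TPR) points from (0, 0) to (1, 1) and the area, equal
    to the tie-adjusted Mann-Whitney statistic.
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report from continuous scores: hard metrics at ``threshold``
    (score >= threshold predicts positive) plus ROC points and AUC."""
    s = np.asarray(scores, dtype=float)
    report = confusion_metrics(labels, (s >= threshold).astype(int), threshold)
    report.roc_points, report.auc = roc_auc(labels, s)
    return report


def plot_roc(report: EvalReport, path: str | Path, title: str = "ROC"):
    """Write a ROC plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in report.roc_points]
    tpr = [p[1] for p in report.roc_points]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
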