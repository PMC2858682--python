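"""Validation metrics for CNV classification.

The pathogenic (``mr``) class is the positive class throughout: PPV is
the fraction of MR calls that are truly MR, NPV the fraction of benign
calls that are truly benign.  AUC uses the rank (Mann-Whitney)
formulation, which handles tied distances and equals trapezoidal
integration of the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .nbtree import CLASSES

POSITIVE = CLASSES[1]  # "mr"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency counts with MR as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Proportion-scale metrics; a metric with an empty denominator is
    ``None`` (undefined), never 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    fpr: float | None
    fnr: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "auc": self.auc,
        }


def confusion(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionMatrix:
    """Count agreement between predicted and true labels."""
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truths must have equal length")
    for arr, name in ((pred, "predictions"), (truth, "truths")):
        bad = sorted(set(arr) - set(CLASSES))
        if bad:
            raise ValueError(f"{name} contain labels outside {CLASSES}: {bad}")
    pos_t = truth == POSITIVE
    pos_p = pred == POSITIVE
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricReport:
    """Standard confusion-matrix metrics; see :class:`MetricReport`."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fpr=None if spec is None else 1.0 - spec,
        fnr=None if sens is None else 1.0 - sens,
        auc=auc,
    )


def roc_auc(mr_distances: Sequence[float], truths: Sequence[str]) -> float:
    """Area under the ROC curve of the MR-distance scores.

    Computed as the Mann-Whitney probability that a random MR instance
    scores above a random benign one, counting ties as half.
    """
    scores = np.asarray(mr_distances, dtype=float)
    truth = np.asarray(truths)
    pos = truth == POSITIVE
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ranked_distance_table(
    results: pd.DataFrame, truths: Sequence[str] | None = None
) -> pd.DataFrame:
    """Rank CNVs by MR distance, descending; ties keep input order.

    ``results`` needs ``mr_distance`` and ``predicted`` columns (the
    output of ``classify_table``); the returned table adds ``rank``
    (1-based) and, when supplied, a ``truth`` column.
    """
    table = results.copy()
    if truths is not None:
        table["truth"] = list(truths)
    table = table.sort_values("mr_distance", ascending=False, kind="stable")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def accuracy_of(predictions: Sequence[str], truths: Sequence[str]) -> float:
    """Fraction of agreeing labels (convenience for the experiment loops)."""
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    return float((pred == truth).mean())


def format_report(report: MetricReport) -> str:
    """Human-readable report: percentages to the nearest point, predictive
    values as two-decimal proportions."""
    lines = []
    for key in ("sensitivity", "specificity", "accuracy"):
        v = getattr(report, key)
        lines.append(f"{key}\t{'NA' if v is None else f'{100 * v:.0f}%'}")
    for key in ("ppv", "npv", "fpr", "fnr"):
        v = getattr(report, key)
        lines.append(f"{key}\t{'NA' if v is None else f'{v:.2f}'}")
    if report.auc is not None:
        lines.append(f"auc\t{report.auc:.2f}")
    return "\n".join(lines)


def write_report(report: MetricReport, path: str | Path) -> None:
    """Machine-readable tab-separated key/value pairs (full precision)."""
    with open(path, "w") as fh:
        for key, v in report.as_dict().items():
            fh.write(f"{key}\t{'NA' if v is None else repr(v)}\n")
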