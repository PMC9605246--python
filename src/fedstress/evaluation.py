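"""Confusion-matrix evaluation: per-participant Acc/P/R/F1 and macro averages.

Stress is the positive class.  With TP/FP/FN/TN from the confusion matrix,

    Acc = (TP + TN) / (TP + FP + FN + TN)
    P   = TP / (TP + FP)
    R   = TP / (TP + FN)
    F1  = 2 P R / (P + R)

A 0/0 denominator yields 0 (flagged, not raised), which keeps macro averaging
total.  Reports round half-up to 4 decimals for display while retaining full
precision internally.  The macro average is the unweighted arithmetic mean of
the per-participant rows.

These metrics make the class-imbalance argument assertable: a predictor that
never outputs stress on a 90:10 non-stress:stress test set scores accuracy
0.9 yet F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .strategies import StrategyResult

METRIC_NAMES = ("Acc", "P", "R", "F1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays must have equal lengths")
    if t.size == 0:
        raise ValueError("need at least one evaluated window")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    return cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0


def recall(cm: ConfusionMatrix) -> float:
    return cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0


def f1(cm: ConfusionMatrix) -> float:
    return f1_from_pr(precision(cm), recall(cm))


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    return 2.0 * p * r / (p + r) if p + r else 0.0


def degenerate_denominators(cm: ConfusionMatrix) -> set[str]:
    """Which of P/R/F1 hit a 0/0 denominator (reported as 0 by convention)."""
    flags = set()
    if cm.tp + cm.fp == 0:
        flags.add("P")
    if cm.tp + cm.fn == 0:
        flags.add("R")
    if precision(cm) + recall(cm) == 0:
        flags.add("F1")
    return flags


def round_half_up(x: float, ndigits: int = 4) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass
class MetricRow:
    participant: int | str  # participant id or "Average"
    acc: float
    p: float
    r: float
    f1: float

    def rounded(self, ndigits: int = 4) -> dict:
        return {
            "Participant": self.participant,
            "Acc": round_half_up(self.acc, ndigits),
            "P": round_half_up(self.p, ndigits),
            "R": round_half_up(self.r, ndigits),
            "F1": round_half_up(self.f1, ndigits),
        }


def macro_average(rows: Sequence[MetricRow]) -> MetricRow:
    """Unweighted arithmetic mean of per-participant metric rows."""
    if not rows:
        raise ValueError("cannot average zero rows")
    return MetricRow(
        participant="Average",
        acc=float(np.mean([r.acc for r in rows])),
        p=float(np.mean([r.p for r in rows])),
        r=float(np.mean([r.r for r in rows])),
        f1=float(np.mean([r.f1 for r in rows])),
    )


@dataclass
class EvaluationReport:
    strategy: str
    rows: list[MetricRow]
    average: MetricRow
    matrices: dict[int, ConfusionMatrix]

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        records = [r.rounded() if rounded else vars(r) for r in [*self.rows, self.average]]
        return pd.DataFrame.from_records(records)

    def to_json_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "rows": [r.rounded() for r in self.rows],
            "average": self.average.rounded(),
            "confusion_matrices": {
                str(pid): {"TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn}
                for pid, cm in self.matrices.items()
            },
        }


def evaluate_strategy(result: StrategyResult) -> EvaluationReport:
    """Per-participant metric rows plus the unweighted average row."""
    rows, matrices = [], {}
    for pid, pred in sorted(result.predictions.items()):
        cm = confusion_matrix(pred.y_true, pred.y_pred)
        matrices[pid] = cm
        rows.append(MetricRow(pid, accuracy(cm), precision(cm), recall(cm), f1(cm)))
    return EvaluationReport(result.strategy, rows, macro_average(rows), matrices)


def compare_strategies(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Side-by-side average Acc/P/R/F1 per strategy, sorted by strategy name."""
    if not reports:
        raise ValueError("need at least one report")
    records = []
    for rep in sorted(reports, key=lambda r: r.strategy):
        row = rep.average.rounded()
        row["Strategy"] = rep.strategy
        records.append({k: row[k] for k in ("Strategy", "Acc", "P", "R", "F1")})
    return pd.DataFrame.from_records(records)
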