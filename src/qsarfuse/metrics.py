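"""Classification performance estimators and Utility ranking.

All rates are reported as percentages in [0, 100], the convention used
throughout QSAR benchmarking: sensitivity (Sn) and specificity (Sp) are the
percentages of correctly classified actives and inactives, the non-error
rate (NER, balanced accuracy) is their mean, coverage (Cvg) is the
percentage of chemicals that received a prediction at all, and Utility is
the arithmetic mean of Sn, Sp and Cvg used for multi-criteria ranking.

Chemicals without an experimental label are excluded from Sn/Sp/NER but
count in the coverage denominator: coverage measures chemical-space reach,
not correctness. Undefined rates (no evaluated actives, or no evaluated
inactives) raise instead of silently returning zero, because a silent zero
would corrupt NER.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ACTIVE, INACTIVE, NO_PREDICTION, UNKNOWN, PredictionTable


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/TN/FP counts for one binary classifier ("active" is positive)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class PerformanceReport:
    """Sn/Sp/NER/Cvg/Utility (percent) for one model or consensus strategy."""

    name: str
    sn: float
    sp: float
    ner: float
    cvg: float
    utility: float
    rank: int | None = None


def confusion_counts(table: PredictionTable, predictions: np.ndarray) -> ConfusionMatrix:
    """Count TP/FN/TN/FP over chemicals that are predicted and labelled.

    *predictions* is a per-chemical vote-code array aligned with the table;
    abstentions (``NO_PREDICTION``) and chemicals with unknown experimental
    label are excluded from all four cells.
    """
    predictions = np.asarray(predictions)
    if predictions.shape != (table.n_chemicals,):
        raise ValueError("predictions must align with the table's chemicals")
    labels = table.true_labels
    evaluated = (predictions != NO_PREDICTION) & (labels != UNKNOWN)
    if not evaluated.any():
        raise ValueError("no predicted chemicals with known labels: rates undefined")
    p, t = predictions[evaluated], labels[evaluated]
    return ConfusionMatrix(
        tp=int(np.sum((t == ACTIVE) & (p == ACTIVE))),
        fn=int(np.sum((t == ACTIVE) & (p == INACTIVE))),
        tn=int(np.sum((t == INACTIVE) & (p == INACTIVE))),
        fp=int(np.sum((t == INACTIVE) & (p == ACTIVE))),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """Percent of evaluated actives predicted active: 100*TP/(TP+FN)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no evaluated actives")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Percent of evaluated inactives predicted inactive: 100*TN/(TN+FP)."""
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no evaluated inactives")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def non_error_rate(sn: float, sp: float) -> float:
    """Balanced accuracy: the arithmetic mean of sensitivity and specificity."""
    return (sn + sp) / 2.0


def coverage(predictions: np.ndarray, n_total: int) -> float:
    """Percent of the *n_total* chemicals receiving a class prediction."""
    if n_total <= 0:
        raise ValueError("coverage undefined for an empty chemical set")
    predictions = np.asarray(predictions)
    return 100.0 * float(np.sum(predictions != NO_PREDICTION)) / n_total


def utility(sn: float, sp: float, cvg: float) -> float:
    """Arithmetic mean of Sn, Sp and Cvg — the multi-criteria ranking index."""
    return (sn + sp + cvg) / 3.0


def rank_by_utility(reports: list[PerformanceReport]) -> list[PerformanceReport]:
    """Fill ranks for decreasing Utility; rank 1 is best.

    Ties are broken by higher NER, then higher coverage, then stable input
    order, giving a deterministic total order. Returns new reports in the
    input order.
    """
    if not reports:
        raise ValueError("cannot rank an empty report list")
    order = sorted(
        range(len(reports)),
        key=lambda i: (-reports[i].utility, -reports[i].ner, -reports[i].cvg, i),
    )
    out = [replace(r) for r in reports]
    for rank, i in enumerate(order, start=1):
        out[i].rank = rank
    return out


def evaluate_predictions(table: PredictionTable, predictions: np.ndarray,
                         name: str = "consensus") -> PerformanceReport:
    """Full Sn/Sp/NER/Cvg/Utility report for one per-chemical prediction set."""
    cm = confusion_counts(table, predictions)
    sn = sensitivity(cm)
    sp = specificity(cm)
    cvg = coverage(predictions, table.n_chemicals)
    return PerformanceReport(
        name=name, sn=sn, sp=sp, ner=non_error_rate(sn, sp), cvg=cvg,
        utility=utility(sn, sp, cvg),
    )


def per_model_reports(table: PredictionTable) -> list[PerformanceReport]:
    """Evaluate every individual model on its own in-AD predictions.

    Models whose Sn or Sp is undefined on this table (no evaluated actives
    or no evaluated inactives) are skipped with a warning.
    """
    from .io import logger

    eff = table.effective_votes()
    reports = []
    for j, name in enumerate(table.model_names):
        try:
            reports.append(evaluate_predictions(table, eff[:, j], name=name))
        except ValueError as exc:
            logger.warning("model %s excluded from evaluation: %s", name, exc)
    return reports


def reports_to_frame(reports: list[PerformanceReport]):
    """Long-format DataFrame (name, Sn, Sp, NER, Cvg, Utility, rank)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "name": [r.name for r in reports],
            "Sn": [round(r.sn, 1) for r in reports],
            "Sp": [round(r.sp, 1) for r in reports],
            "NER": [round(r.ner, 1) for r in reports],
            "Cvg": [round(r.cvg, 1) for r in reports],
            "Utility": [round(r.utility, 1) for r in reports],
            "rank": [r.rank for r in reports],
        }
    )
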