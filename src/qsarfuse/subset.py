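"""Consensus performance as a function of the number of fused models.

Models are ranked by their individual non-error rate (computed on the same
labelled table, which is optimistic but mirrors evaluation-set practice) and
enter the consensus one at a time starting from the best ``k_min`` (default
five). For each subset size the requested consensus strategies are re-run
and their NER and coverage recorded, tracing out the reliability/coverage
trade-off as weaker models join the pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusConfig, estimate_likelihoods_from_table, run_consensus
from .io import PredictionTable, logger
from .metrics import coverage, evaluate_predictions, per_model_reports


@dataclass(frozen=True)
class CurvePoint:
    """NER/Cvg of one consensus method on the top-``k`` models."""

    k: int
    method: str
    ner: float
    cvg: float


def order_models_by_ner(table: PredictionTable) -> list[str]:
    """Model names sorted by decreasing individual NER.

    Ties are broken by higher coverage, then input order. Models whose NER
    is undefined on this table (no evaluated actives or inactives within
    their AD) are excluded with a warning, which `per_model_reports` emits.
    """
    reports = per_model_reports(table)
    if not reports:
        raise ValueError("no model has a defined NER on this table")
    input_pos = {name: i for i, name in enumerate(table.model_names)}
    ordered = sorted(reports, key=lambda r: (-r.ner, -r.cvg, input_pos[r.name]))
    return [r.name for r in ordered]


def consensus_curve(table: PredictionTable, methods: list[str],
                    k_min: int = 5,
                    smoothing_alpha: float = 0.5,
                    posterior_threshold: float = 0.95) -> list[CurvePoint]:
    """One (NER, Cvg) point per method per subset size k = k_min .. M.

    For the Bayes methods the likelihoods are re-estimated on each subset
    (from the same labelled table), so every point is self-contained. A
    point whose NER is undefined (e.g. a strict consensus that evaluates no
    actives) is recorded with NaN rates and a warning.
    """
    order = order_models_by_ner(table)
    m = len(order)
    if m < k_min:
        raise ValueError(f"need at least k_min = {k_min} rankable models, got {m}")
    points: list[CurvePoint] = []
    for k in range(k_min, m + 1):
        sub = table.select_models(order[:k])
        likelihoods = None
        if any(meth in ("B", "Bp") for meth in methods):
            likelihoods = estimate_likelihoods_from_table(sub, alpha=smoothing_alpha)
        for meth in methods:
            config = ConsensusConfig(method=meth, smoothing_alpha=smoothing_alpha,
                                     posterior_threshold=posterior_threshold)
            result = run_consensus(sub, config, likelihoods=likelihoods)
            cvg = coverage(result.fused, sub.n_chemicals)
            try:
                report = evaluate_predictions(sub, result.fused, name=meth)
                ner = report.ner
            except ValueError as exc:
                logger.warning("curve point (%s, k=%d): NER undefined: %s", meth, k, exc)
                ner = float("nan")
            points.append(CurvePoint(k=k, method=meth, ner=ner, cvg=cvg))
    return points


def curve_to_frame(points: list[CurvePoint]) -> pd.DataFrame:
    """Long-format frame (method, k, NER, Cvg) for CSV export and plotting."""
    return pd.DataFrame(
        {
            "method": [p.method for p in points],
            "k": [p.k for p in points],
            "NER": [p.ner for p in points],
            "Cvg": [p.cvg for p in points],
        }
    )


def plot_curve(points: list[CurvePoint], path) -> None:
    """NER and coverage vs number of fused models, one panel per quantity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = curve_to_frame(points)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for method, grp in df.groupby("method"):
        axes[0].plot(grp["k"], grp["NER"], marker="o", ms=3, label=method)
        axes[1].plot(grp["k"], grp["Cvg"], marker="o", ms=3, label=method)
    axes[0].set_ylabel("NER (%)")
    axes[1].set_ylabel("Cvg (%)")
    for ax in axes:
        ax.set_xlabel("number of models")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
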