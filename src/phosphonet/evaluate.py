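"""Scoring of inferred networks and activities against ground truth.

Includes ROC / precision-recall sweeps over edge scores, precision at a
fixed recall level (the headline comparison for DPI variants), the weighted
drug-sensitivity benchmark score (partial sum of differential-activity
ranks weighted by per-protein sensitivity), and a recovery report for
synthetic ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .network import Interaction
from .simulate import GroundTruth

__all__ = [
    "GoldStandard",
    "pr_roc",
    "precision_at_recall",
    "weighted_sensitivity_score",
    "recovery_report",
]


@dataclass
class GoldStandard:
    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    priors: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.positives = set(self.positives)
        self.negatives = set(self.negatives)
        if self.positives & self.negatives:
            raise ValueError("positive and negative gold-standard sets overlap")


def pr_roc(predicted: Mapping[tuple[str, str], float], gold: GoldStandard) -> dict:
    """ROC and precision-recall curves plus trapezoidal AUCs.

    ``predicted`` maps edges to scores; gold edges missing from the
    prediction are treated as scored below every predicted edge.
    """
    if not gold.positives or not gold.negatives:
        raise ValueError("gold standard must contain positives and negatives")
    edges = sorted(gold.positives | gold.negatives)
    floor = min(predicted.values()) - 1.0 if predicted else 0.0
    y = np.array([e in gold.positives for e in edges], dtype=int)
    s = np.array([predicted.get(e, floor) for e in edges], dtype=float)
    fpr, tpr, _ = skm.roc_curve(y, s)
    prec, rec, _ = skm.precision_recall_curve(y, s)
    return {
        "auroc": float(skm.auc(fpr, tpr)),
        "auprc": float(skm.auc(rec, prec)),
        "roc": (fpr, tpr),
        "pr": (rec, prec),
    }


def precision_at_recall(
    predicted: Mapping[tuple[str, str], float],
    positives: set[tuple[str, str]],
    recall: float = 0.25,
) -> float:
    """Precision of the score-ranked edge list at the first point where the
    requested recall is reached; NaN if the prediction never reaches it."""
    if not positives:
        raise ValueError("no positive edges")
    ranked = sorted(predicted.items(), key=lambda kv: -kv[1])
    need = recall * len(positives)
    tp = 0
    for k, (edge, _) in enumerate(ranked, start=1):
        if edge in positives:
            tp += 1
            if tp >= need:
                return tp / k
    return float("nan")


def weighted_sensitivity_score(dp: Sequence[float], w: Sequence[float], n: int) -> float:
    """Partial sum of sensitivity-weighted differential activities.

    ``dp`` is ranked most-to-least significant; the score is
    sum_{i<=n} w_i * dp_i. ``n`` beyond the list length is truncated with a
    warning.
    """
    dp = np.asarray(dp, dtype=float)
    w = np.asarray(w, dtype=float)
    if dp.size != w.size:
        raise ValueError("dp and w must align")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > dp.size:
        warnings.warn(f"n={n} exceeds list length {dp.size}; truncated")
        n = dp.size
    return float(np.sum(w[:n] * dp[:n]))


def recovery_report(
    interactions: Sequence[Interaction],
    truth: GroundTruth,
    activity: pd.DataFrame | None = None,
) -> dict:
    """Edge precision/recall, indirect false-inclusion rate and (optionally)
    per-regulator Spearman correlation of inferred vs true activities.

    Precision with an empty prediction is reported as NaN rather than 0/1.
    """
    pred = {(i.regulator, i.target) for i in interactions}
    direct = truth.direct_edges()
    indirect = truth.indirect_edges()
    tp = len(pred & direct)
    report = {
        "n_predicted": len(pred),
        "n_true": len(direct),
        "precision": tp / len(pred) if pred else float("nan"),
        "recall": tp / len(direct) if direct else float("nan"),
        "indirect_included": (len(pred & indirect) / len(indirect)
                              if indirect else float("nan")),
    }
    if activity is not None:
        rhos = {}
        for reg in truth.activities.index:
            if reg in activity.index:
                shared = [c for c in truth.activities.columns if c in activity.columns]
                a = truth.activities.loc[reg, shared].to_numpy(float)
                b = activity.loc[reg, shared].to_numpy(float)
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 3:
                    rhos[reg] = float(stats.spearmanr(a[ok], b[ok]).statistic)
        report["activity_spearman"] = rhos
        report["median_activity_spearman"] = (
            float(np.median(list(rhos.values()))) if rhos else float("nan"))
    return report
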