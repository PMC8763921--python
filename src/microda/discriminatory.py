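"""Per-feature AUROC discrimination and threshold precision/recall/F1.

Each feature's discriminatory value is the area under its ROC curve when the
feature's abundance alone is used to separate the two groups. The AUROC is
computed by the Mann-Whitney rank identity (ties counted half) and, by
default, folded to max(AUC, 1 - AUC) so a feature depleted in cases scores
the same as one equally enriched. Tool-level summaries treat features above
an AUC threshold as the "true positives" and score each method's significant
set by precision, recall, and F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methods import DAResult
from .tables import CountTable, GroupLabels
from .transforms import clr_transform, tss_normalize

__all__ = [
    "AUCRecord",
    "DiscriminationSummary",
    "feature_auc",
    "auc_records",
    "discrimination_summary",
]


@dataclass(frozen=True)
class AUCRecord:
    feature_id: str
    auc_rel: float
    auc_clr: float


@dataclass
class DiscriminationSummary:
    method: str
    mean_auc: float | None
    metrics: dict[float, dict[str, float | None]]  # threshold -> precision/recall/f1


def feature_auc(values, labels: GroupLabels | np.ndarray, fold: bool = True) -> float:
    """AUROC of one feature's per-sample abundances.

    AUROC = P(value in second group > value in first) + 0.5 P(tie), via the
    rank identity. With ``fold=True`` (default) the result is
    max(AUC, 1 - AUC), scoring enrichment in either direction equally.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype == bool:
        member = labels
    else:
        uniq = sorted(set(labels.tolist()))
        if len(uniq) != 2:
            raise ValueError("labels must define exactly two groups")
        member = labels == uniq[1]
    n_b = int(member.sum())
    n_a = member.size - n_b
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(values)
    r_b = ranks[member].sum()
    auc = (r_b - n_b * (n_b + 1) / 2.0) / (n_a * n_b)
    return float(max(auc, 1.0 - auc)) if fold else float(auc)


def auc_records(
    table: CountTable, labels: GroupLabels, fold: bool = True
) -> list[AUCRecord]:
    """AUROCs for every feature on both relative (TSS) and CLR abundances of
    the non-rarefied table."""
    sample_ids = [s for s in table.sample_ids if s in labels.assignment]
    sub = table.select_samples(sample_ids)
    member = labels.membership(sample_ids)
    rel = tss_normalize(sub)
    clr = clr_transform(sub)
    return [
        AUCRecord(
            feature_id=f,
            auc_rel=feature_auc(rel[i], member, fold=fold),
            auc_clr=feature_auc(clr[i], member, fold=fold),
        )
        for i, f in enumerate(sub.feature_ids)
    ]


def discrimination_summary(
    results: dict[str, DAResult],
    aucs: list[AUCRecord],
    thresholds: tuple[float, ...] = (0.7, 0.9),
    use_clr: bool = False,
) -> dict[str, DiscriminationSummary]:
    """Per-method mean AUROC of significant features and precision/recall/F1
    at each AUC threshold.

    At threshold t, TP = significant and AUC > t (strictly above), FP =
    significant and AUC <= t, FN = non-significant and AUC > t. Metrics with
    a zero denominator are reported as None rather than 0/0.
    """
    auc_map = {
        rec.feature_id: (rec.auc_clr if use_clr else rec.auc_rel) for rec in aucs
    }
    out: dict[str, DiscriminationSummary] = {}
    for name, res in results.items():
        missing = [f for f in res.feature_ids if f not in auc_map]
        if missing:
            raise ValueError(f"AUC missing for features, e.g. {missing[:3]}")
        sig = res.significant_features
        sig_aucs = [auc_map[f] for f in sig]
        mean_auc = float(np.mean(sig_aucs)) if sig_aucs else None
        metrics: dict[float, dict[str, float | None]] = {}
        for t in thresholds:
            tp = sum(1 for f in res.feature_ids if f in sig and auc_map[f] > t)
            fp = sum(1 for f in res.feature_ids if f in sig and auc_map[f] <= t)
            fn = sum(1 for f in res.feature_ids if f not in sig and auc_map[f] > t)
            precision = tp / (tp + fp) if (tp + fp) > 0 else None
            recall = tp / (tp + fn) if (tp + fn) > 0 else None
            if precision is not None and recall is not None and (precision + recall) > 0:
                f1 = 2 * precision * recall / (precision + recall)
            elif precision is not None and recall is not None:
                f1 = 0.0
            else:
                f1 = None
            metrics[t] = {"precision": precision, "recall": recall, "f1": f1}
        out[name] = DiscriminationSummary(method=name, mean_auc=mean_auc, metrics=metrics)
    return out
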