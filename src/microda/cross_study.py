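"""Genus-level cross-study consistency of differential-abundance calls.

Given several case-control studies of the same phenotype, each tool's
significant genera are tallied across studies and the observed mean
recurrence (among genera significant at least once) is compared with a
constructed permutation null in which each genus is called independently in
study i with probability equal to that study's observed proportion of
significant genera. The summary per tool is the fold difference of observed
over expected mean recurrence and a one-tailed permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = [
    "GenusCollapseSpec",
    "ConsistencyResult",
    "collapse_to_genus",
    "restrict_to_common",
    "observed_consistency",
    "permutation_null",
    "consistency_test",
    "cross_study_consistency",
]


@dataclass(frozen=True)
class GenusCollapseSpec:
    """Feature -> genus mapping plus label exclusion rules.

    Features whose genus label is unclassified-like or carries a
    "sensu stricto" qualifier contribute to no genus. Matching is
    exact-string after trimming and case-folding.
    """

    taxonomy: dict[str, str]
    exclude_unclassified: bool = True
    exclude_sensu_stricto: bool = True

    def genus_of(self, feature_id: str) -> str | None:
        label = self.taxonomy.get(feature_id)
        if label is None:
            return None
        clean = label.strip()
        folded = clean.casefold()
        if self.exclude_unclassified and (
            folded in {"", "na", "nan", "unclassified"} or "unclassified" in folded
        ):
            return None
        if self.exclude_sensu_stricto and "sensu stricto" in folded:
            return None
        return clean


@dataclass
class ConsistencyResult:
    """One tool's cross-study consistency summary (one table row)."""

    method: str
    n_sig_genera: int
    max_overlap: int
    mean_expected: float
    mean_observed: float
    fold_difference: float
    p: float
    n_permutations: int
    n_empty_replicates: int = 0


def collapse_to_genus(table: CountTable, spec: GenusCollapseSpec) -> CountTable:
    """Sum feature counts into genera per sample; excluded features are dropped."""
    genera: dict[str, np.ndarray] = {}
    for i, f in enumerate(table.feature_ids):
        genus = spec.genus_of(f)
        if genus is None:
            continue
        if genus in genera:
            genera[genus] = genera[genus] + table.counts[i]
        else:
            genera[genus] = table.counts[i].copy()
    names = sorted(genera)
    counts = np.vstack([genera[g] for g in names]) if names else np.zeros(
        (0, table.n_samples), dtype=np.int64
    )
    return CountTable(tuple(names), table.sample_ids, counts)


def restrict_to_common(tables: list[CountTable]) -> list[CountTable]:
    """Restrict every genus table to the intersection of genus sets (sorted)."""
    if len(tables) < 2:
        raise ValueError("need >= 2 tables")
    common = set(tables[0].feature_ids)
    for t in tables[1:]:
        common &= set(t.feature_ids)
    if not common:
        raise ValueError("no genera shared by all tables")
    order = sorted(common)
    return [t.select_features(order) for t in tables]


def observed_consistency(
    sig_sets: list[set[str]],
) -> tuple[dict[str, int], float, int, int]:
    """Recurrence counts of significant genera across studies.

    Returns (per-genus counts, mean recurrence among genera significant at
    least once, number of such genera, maximum recurrence). Directionality is
    ignored; genera never significant contribute nothing.
    """
    if len(sig_sets) < 2:
        raise ValueError("need >= 2 studies")
    counts: dict[str, int] = {}
    for s in sig_sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise ValueError("no genus significant in any study")
    vals = np.array(list(counts.values()))
    return counts, float(vals.mean()), int(vals.size), int(vals.max())


def permutation_null(
    n_sig_per_study: list[int],
    n_common_genera: int,
    n_permutations: int = 1000,
    seed: int = 42,
) -> tuple[np.ndarray, float, int]:
    """Null distribution of mean recurrence under independent random calls.

    Per replicate, each of the ``n_common_genera`` genera is called in study
    i independently with probability ``n_sig_i / n_common_genera``; the
    replicate statistic is the mean recurrence among genera called at least
    once. Replicates with zero calls carry no statistic and are excluded
    (their number is returned). Returns (null statistics, their mean,
    number of empty replicates).
    """
    n_sig = np.asarray(n_sig_per_study, dtype=np.float64)
    if np.any(n_sig > n_common_genera):
        raise ValueError("a study cannot have more significant genera than common genera")
    probs = n_sig / n_common_genera
    rng = np.random.default_rng(seed)
    stats_out = []
    n_empty = 0
    for _ in range(n_permutations):
        calls = rng.random((len(probs), n_common_genera)) < probs[:, None]
        rec = calls.sum(axis=0)
        rec = rec[rec > 0]
        if rec.size == 0:
            n_empty += 1
            continue
        stats_out.append(rec.mean())
    null = np.asarray(stats_out)
    if null.size == 0:
        raise ValueError("every replicate had zero calls; null undefined")
    return null, float(null.mean()), n_empty


def consistency_test(
    mean_observed: float, null: np.ndarray, n_permutations: int | None = None
) -> tuple[float, float]:
    """Fold difference and one-tailed permutation p of observed mean recurrence.

    fold = mean_observed / mean(null); p = (1 + #{null >= observed}) /
    (1 + n_permutations), so the minimum attainable p is 1/(1+N).
    """
    null = np.asarray(null, dtype=np.float64)
    if null.size == 0:
        raise ValueError("empty null distribution")
    mean_expected = float(null.mean())
    if mean_expected == 0:
        raise ValueError("null mean recurrence is zero")
    n_perm = n_permutations if n_permutations is not None else null.size
    exceed = int(np.sum(null >= mean_observed))
    p = (1 + exceed) / (1 + n_perm)
    return mean_observed / mean_expected, float(p)


def cross_study_consistency(
    sig_sets: list[set[str]],
    n_common_genera: int,
    method: str = "",
    n_permutations: int = 1000,
    seed: int = 42,
) -> ConsistencyResult:
    """Full per-tool pipeline: observed recurrence, permutation null, test."""
    _, mean_obs, n_sig_genera, max_overlap = observed_consistency(sig_sets)
    null, mean_exp, n_empty = permutation_null(
        [len(s) for s in sig_sets], n_common_genera, n_permutations, seed
    )
    fold, p = consistency_test(mean_obs, null, n_permutations)
    return ConsistencyResult(
        method=method,
        n_sig_genera=n_sig_genera,
        max_overlap=max_overlap,
        mean_expected=mean_exp,
        mean_observed=mean_obs,
        fold_difference=fold,
        p=p,
        n_permutations=n_permutations,
        n_empty_replicates=n_empty,
    )
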