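"""Count tables, sample groupings, and dataset preparation.

The universal input to every analysis here is a feature-by-sample table of
non-negative integer counts (rows are ASVs or genera, columns are samples)
plus a two-group assignment of samples. This module reads and writes those
tables, rarefies them to a common read depth, applies prevalence filtering,
and summarises the dataset characteristics (sparsity, richness, depth
statistics, and the Aitchison-distance PERMANOVA effect size) that the
evaluation modules correlate against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "GroupLabels",
    "DatasetCharacteristics",
    "TableFormatError",
    "GroupingError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "rarefy",
    "prevalence_filter",
    "characterize",
    "aitchison_effect_size",
]


class TableFormatError(ValueError):
    """Raised when a count table violates the integer feature-by-sample contract."""


class GroupingError(ValueError):
    """Raised when sample metadata does not define exactly two groups of >= 2 samples."""


@dataclass(frozen=True)
class CountTable:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    feature_ids
        Unique row identifiers (ASVs, OTUs, or genera).
    sample_ids
        Unique column identifiers.
    counts
        Integer matrix of shape ``(len(feature_ids), len(sample_ids))``.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise TableFormatError("counts must be integers")
        if np.any(counts < 0):
            raise TableFormatError("counts must be non-negative")
        fids = tuple(str(f) for f in self.feature_ids)
        sids = tuple(str(s) for s in self.sample_ids)
        if counts.shape != (len(fids), len(sids)):
            raise TableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(fids)} features x {len(sids)} samples"
            )
        if len(set(fids)) != len(fids):
            raise TableFormatError("duplicate feature IDs")
        if len(set(sids)) != len(sids):
            raise TableFormatError("duplicate sample IDs")
        object.__setattr__(self, "feature_ids", fids)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample library sizes (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.feature_ids, tuple(sample_ids), self.counts[:, idx])

    def select_features(self, feature_ids: Sequence[str]) -> "CountTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountTable(tuple(feature_ids), self.sample_ids, self.counts[idx, :])


@dataclass(frozen=True)
class GroupLabels:
    """Assignment of samples to exactly two groups.

    ``groups`` fixes the contrast orientation: effect directions reported by
    the testing workflows are positive when a feature is higher in
    ``groups[1]`` (the second group).
    """

    assignment: dict[str, str]
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        present = set(self.assignment.values())
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise GroupingError("groups must be two distinct labels")
        if present != set(self.groups):
            raise GroupingError(
                f"labels present {sorted(present)} do not match groups {self.groups}"
            )
        for g in self.groups:
            n = sum(1 for v in self.assignment.values() if v == g)
            if n < 2:
                raise GroupingError(f"group {g!r} has {n} samples; need >= 2")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def membership(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean vector: True where the sample belongs to the second group."""
        return np.array([self.assignment[s] == self.groups[1] for s in sample_ids])

    def restrict(self, sample_ids: Sequence[str]) -> "GroupLabels":
        sub = {s: self.assignment[s] for s in sample_ids if s in self.assignment}
        return GroupLabels(sub, self.groups)


@dataclass(frozen=True)
class DatasetCharacteristics:
    """Scalar summaries of one dataset used in the characteristic correlations."""

    n_samples: int
    sparsity: float
    mean_richness: float
    median_depth: float
    depth_range: float
    depth_cv: float
    pct_low_prevalence: float
    effect_size_r2: float
    effect_size_p: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_samples": self.n_samples,
            "sparsity": self.sparsity,
            "mean_richness": self.mean_richness,
            "median_depth": self.median_depth,
            "depth_range": self.depth_range,
            "depth_cv": self.depth_cv,
            "pct_low_prevalence": self.pct_low_prevalence,
            "effect_size_r2": self.effect_size_r2,
            "effect_size_p": self.effect_size_p,
        }


def read_count_table(path) -> CountTable:
    """Read a tab-delimited feature table (first column feature IDs, header samples)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        raise TableFormatError(f"duplicate feature IDs in {path}")
    if frame.columns.has_duplicates:
        raise TableFormatError(f"duplicate sample IDs in {path}")
    try:
        values = frame.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if np.any(~np.isfinite(values)):
        raise TableFormatError(f"missing or non-finite cell in {path}")
    if np.any(values != np.floor(values)):
        raise TableFormatError(f"non-integer count in {path}")
    if np.any(values < 0):
        raise TableFormatError(f"negative count in {path}")
    return CountTable(
        feature_ids=tuple(str(i) for i in frame.index),
        sample_ids=tuple(str(c) for c in frame.columns),
        counts=values.astype(np.int64),
    )


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path, group_column: str, sample_ids: Sequence[str] | None = None) -> GroupLabels:
    """Read a tab-delimited metadata table and extract the two-group assignment.

    When ``sample_ids`` is given, the assignment is restricted to those
    samples; metadata rows for absent samples are dropped with a warning.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if group_column not in meta.columns:
        raise GroupingError(f"column {group_column!r} not found in {path}")
    assignment = {str(s): str(g) for s, g in meta[group_column].items()}
    if sample_ids is not None:
        keep = set(map(str, sample_ids))
        dropped = sorted(set(assignment) - keep)
        if dropped:
            warnings.warn(
                f"{len(dropped)} metadata samples absent from the count table "
                f"were excluded (e.g. {dropped[:3]})",
                stacklevel=2,
            )
            logger.warning("excluded metadata-only samples: %s", dropped)
        assignment = {s: g for s, g in assignment.items() if s in keep}
    labels = sorted(set(assignment.values()))
    if len(labels) != 2:
        raise GroupingError(
            f"need exactly 2 group labels, found {len(labels)}: {labels}"
        )
    return GroupLabels(assignment, (labels[0], labels[1]))


class EmptyOutputError(ValueError):
    """Raised when rarefaction would discard every sample."""


def rarefy(table: CountTable, depth="auto", seed: int = 42) -> CountTable:
    """Subsample each sample without replacement to a common read depth.

    With ``depth="auto"`` the target is the smallest library size that is at
    least 2000 reads, and samples below 2000 reads are discarded (samples
    below an explicit ``depth`` are likewise discarded). Subsampling is
    multivariate-hypergeometric per sample, i.e. drawing ``depth`` reads
    uniformly without replacement from the sample's reads.
    """
    depths = table.depths
    if depth == "auto":
        eligible = depths[depths >= 2000]
        if eligible.size == 0:
            raise EmptyOutputError("no sample has >= 2000 reads")
        target = int(eligible.min())
    else:
        target = int(depth)
        if target < 1:
            raise ValueError("depth must be >= 1")
    keep = depths >= target
    if not keep.any():
        raise EmptyOutputError(f"no sample reaches depth {target}")
    rng = np.random.default_rng(seed)
    out = np.empty((table.n_features, int(keep.sum())), dtype=np.int64)
    kept_ids = []
    j = 0
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        col = table.counts[:, i]
        if depths[i] == target:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, target, method="marginals")
        kept_ids.append(sid)
        j += 1
    return CountTable(table.feature_ids, tuple(kept_ids), out)


def prevalence_filter(table: CountTable, min_prevalence: float = 0.10) -> CountTable:
    """Drop features present (count > 0) in fewer than ``min_prevalence`` of samples.

    A feature present in exactly the threshold fraction is retained: removal
    applies strictly below the cut-off.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    return CountTable(
        tuple(f for f, k in zip(table.feature_ids, keep) if k),
        table.sample_ids,
        table.counts[keep, :],
    )


def _clr_matrix(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    logc = np.log(counts + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def aitchison_effect_size(
    table: CountTable,
    labels: GroupLabels,
    n_permutations: int = 999,
    seed: int = 42,
) -> tuple[float, float]:
    """PERMANOVA effect size (R^2) and permutation p on Aitchison distances.

    The Aitchison distance is the Euclidean distance between CLR-transformed
    samples (pseudocount 1). R^2 = SS_between / SS_total is computed from the
    distance matrix; the p-value is ``(1 + #{perm F >= obs F}) / (1 + N)``
    over random label permutations.
    """
    sample_ids = [s for s in table.sample_ids if s in labels.assignment]
    sub = table.select_samples(sample_ids)
    member = labels.membership(sample_ids)
    if member.sum() < 2 or (~member).sum() < 2:
        raise GroupingError("each group needs >= 2 samples present in the table")
    clr = _clr_matrix(sub.counts.astype(np.float64))
    d2 = squareform(pdist(clr.T, metric="euclidean")) ** 2
    if not np.any(d2 > 0):
        raise ValueError("degenerate distance matrix: all distances are zero")
    n = len(sample_ids)

    def pseudo_f(mask: np.ndarray) -> tuple[float, float]:
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for grp_mask in (mask, ~mask):
            idx = np.flatnonzero(grp_mask)
            if idx.size > 1:
                block = d2[np.ix_(idx, idx)]
                ss_within += block[np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore"):
            f = (ss_between / 1.0) / (ss_within / (n - 2))
        return f, ss_between / ss_total

    f_obs, r2 = pseudo_f(member)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(member)
        f_perm, _ = pseudo_f(perm)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return float(r2), float(p)


def characterize(
    table: CountTable,
    labels: GroupLabels | None = None,
    n_permutations: int = 999,
    seed: int = 42,
    depth_cv_ddof: int = 1,
) -> DatasetCharacteristics:
    """Summarise a dataset's structure.

    sparsity = fraction of zero cells; mean_richness = mean per-sample number
    of nonzero features; depth statistics are computed on column sums with
    ``depth_cv`` using the sample (n-1) standard deviation by default;
    pct_low_prevalence = percentage of features present in < 10% of samples.
    The PERMANOVA effect size fields are filled when ``labels`` is given.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValueError("cannot characterize an empty table")
    counts = table.counts
    depths = table.depths.astype(np.float64)
    sparsity = float((counts == 0).mean())
    mean_richness = float((counts > 0).sum(axis=0).mean())
    prevalence = (counts > 0).mean(axis=1)
    pct_low_prev = float(100.0 * (prevalence < 0.10).mean())
    if labels is not None:
        r2, p = aitchison_effect_size(table, labels, n_permutations, seed)
    else:
        r2, p = float("nan"), float("nan")
    return DatasetCharacteristics(
        n_samples=table.n_samples,
        sparsity=sparsity,
        mean_richness=mean_richness,
        median_depth=float(np.median(depths)),
        depth_range=float(depths.max() - depths.min()),
        depth_cv=float(np.std(depths, ddof=depth_cv_ddof) / depths.mean()),
        pct_low_prevalence=pct_low_prev,
        effect_size_r2=r2,
        effect_size_p=p,
    )
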