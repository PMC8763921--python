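"""Synthetic 16S-like count tables with known differential-abundance truth.

The generator emulates the statistical structure of amplicon feature tables:
heavy-tailed (lognormal) taxon relative abundances, per-sample read depths
drawn lognormally so libraries vary over roughly an order of magnitude,
sparsity from both sampling zeros and optional extra zero-inflation,
optional confounding of group and read depth, and a configurable subset of
truly differential taxa with multiplicative fold changes applied
compositionally (spike then renormalise, so unspiked taxa shift slightly, as
real compositional coupling dictates). Multi-study collections share a core
of differential genera across studies with per-study jitter.

The default parameters describe a mid-sized, moderately sparse case-control
amplicon dataset: 200 taxa, 50 samples per group, ~10,000 reads per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tables import CountTable, GroupLabels

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_dataset",
    "generate_null_dataset",
    "generate_multi_study",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset generator.

    n_taxa: number of features.
    n_samples_per_group: (group A, group B) sample counts.
    depth_log_mean / depth_log_sd: natural-log mean and sd of per-sample read
        depths (defaults centre on ~10,000 reads with ~an order of magnitude
        spread across samples).
    baseline_log_sd: lognormal sd of baseline relative abundances; 3.0 gives
        the heavy-tailed rank-abundance profile typical of 16S data (a few
        dominant taxa, a long rare tail, overall sparsity around 0.55 at the
        default depth).
    zero_inflation: probability of forcing a taxon to zero in a sample before
        renormalisation, on top of sampling zeros.
    n_da / fold_changes: number of truly differential taxa and the
        multiplicative effects applied to group B. Spiked taxa are drawn
        from taxa whose baseline relative abundance lies in
        [``da_min_abundance``, ``da_max_abundance``] (defaults 5e-4 and 0.01):
        a taxon with no observable counts cannot carry a differential signal,
        and spiking a dominant taxon would let the renormalisation swamp the
        rest of the community rather than create per-taxon effects.
    depth_confound: ratio of group-B to group-A mean depth (1 = none).
    """

    n_taxa: int = 200
    n_samples_per_group: tuple[int, int] = (50, 50)
    depth_log_mean: float = math.log(10_000.0)
    depth_log_sd: float = 0.55
    baseline_log_sd: float = 3.0
    zero_inflation: float = 0.25
    n_da: int = 0
    fold_changes: tuple[float, ...] = ()
    da_min_abundance: float = 5e-4
    da_max_abundance: float = 0.01
    depth_confound: float = 1.0
    dirichlet_multinomial: bool = False
    dm_concentration: float = 200.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_da > self.n_taxa:
            raise ValueError("n_da must be <= n_taxa")
        if self.n_da and len(self.fold_changes) != self.n_da:
            raise ValueError("fold_changes length must equal n_da")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.depth_confound <= 0:
            raise ValueError("depth_confound must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset: which taxa were spiked and how."""

    da_taxa: frozenset[str]
    fold_changes: dict[str, float]
    group_mean_depths: tuple[float, float]


def _spike_eligible(
    baseline: np.ndarray, spec: SyntheticSpec, limit: int | None = None
) -> np.ndarray:
    """Indices eligible for spiking: observable but not community-dominant.

    Falls back to the taxa closest to (but above) the lower bound when the
    band holds fewer than ``n_da`` taxa.
    """
    n = limit if limit is not None else baseline.size
    band = np.flatnonzero(
        (baseline[:n] >= spec.da_min_abundance)
        & (baseline[:n] <= spec.da_max_abundance)
    )
    if band.size < spec.n_da:
        # relax the lower bound: most abundant taxa still below the cap
        below_cap = np.flatnonzero(baseline[:n] <= spec.da_max_abundance)
        band = below_cap[np.argsort(baseline[below_cap])[::-1]][: max(spec.n_da, 1)]
    if band.size < spec.n_da:
        # tiny communities with no taxon below the cap: least dominant taxa
        band = np.argsort(baseline[:n])[: max(spec.n_da, 1)]
    return band


def _feature_names(n: int, prefix: str = "taxon") -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def generate_dataset(
    spec: SyntheticSpec,
    feature_ids: tuple[str, ...] | None = None,
    baseline: np.ndarray | None = None,
    da_idx: np.ndarray | None = None,
) -> tuple[CountTable, GroupLabels, SyntheticTruth]:
    """Draw one two-group dataset from the generative model.

    Per sample: depth ~ lognormal (group-B depths scaled by depth_confound);
    the latent composition is the baseline relative-abundance vector with
    spiked taxa multiplied by their fold change in group B, extra zeros
    applied, and the result renormalised; counts ~ multinomial(depth,
    composition). Deterministic given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_samples_per_group
    n = n_a + n_b
    if feature_ids is None:
        feature_ids = _feature_names(spec.n_taxa)
    if baseline is None:
        baseline = rng.lognormal(mean=0.0, sigma=spec.baseline_log_sd, size=spec.n_taxa)
        baseline = baseline / baseline.sum()
    if da_idx is None:
        if spec.n_da:
            da_idx = rng.choice(
                _spike_eligible(baseline, spec), size=spec.n_da, replace=False
            )
        else:
            da_idx = np.empty(0, dtype=int)
    member = np.array([False] * n_a + [True] * n_b)
    depths = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=n)
    depths[member] *= spec.depth_confound
    depths = np.maximum(depths.astype(np.int64), 50)
    counts = np.zeros((spec.n_taxa, n), dtype=np.int64)
    fold = np.ones(spec.n_taxa)
    fold[da_idx] = np.asarray(spec.fold_changes, dtype=np.float64)
    for s in range(n):
        comp = baseline.copy()
        if member[s]:
            comp = comp * fold
        if spec.zero_inflation > 0:
            keep = rng.random(spec.n_taxa) >= spec.zero_inflation
            comp = comp * keep
        total = comp.sum()
        if total <= 0:
            raise ValueError("zero_inflation emptied a sample's composition")
        comp = comp / total
        if spec.dirichlet_multinomial:
            comp = rng.dirichlet(comp * spec.dm_concentration)
        counts[:, s] = rng.multinomial(depths[s], comp)
    sample_ids = tuple(f"S{j:04d}" for j in range(n))
    assignment = {
        sid: ("B" if member[j] else "A") for j, sid in enumerate(sample_ids)
    }
    labels = GroupLabels(assignment, ("A", "B"))
    realized = counts.sum(axis=0).astype(np.float64)
    truth = SyntheticTruth(
        da_taxa=frozenset(feature_ids[i] for i in da_idx),
        fold_changes={
            feature_ids[i]: float(f)
            for i, f in zip(da_idx, np.asarray(spec.fold_changes, dtype=np.float64))
        },
        group_mean_depths=(
            float(realized[~member].mean()),
            float(realized[member].mean()),
        ),
    )
    return CountTable(feature_ids, sample_ids, counts), labels, truth


def generate_null_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, GroupLabels, SyntheticTruth]:
    """A dataset with no group effect: groups are exchangeable by construction."""
    return generate_dataset(replace(spec, n_da=0, fold_changes=()))


def generate_multi_study(
    spec: SyntheticSpec,
    n_studies: int,
    shared_da_fraction: float,
    seed: int = 42,
) -> tuple[list[tuple[CountTable, GroupLabels, SyntheticTruth]], dict[str, str]]:
    """Generate a collection of studies sharing a core of differential genera.

    A core set of ``round(shared_da_fraction * n_da)`` taxa is differential in
    every study; the remainder are re-drawn independently per study.
    Per-study baseline abundances are jittered lognormally. Returns the list
    of (table, labels, truth) plus a taxonomy mapping feature -> genus shared
    across studies (a small tail of features is labelled "unclassified" to
    exercise taxonomy exclusion rules downstream).
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    if not 0 <= shared_da_fraction <= 1:
        raise ValueError("shared_da_fraction must be in [0, 1]")
    master = np.random.default_rng(seed)
    feature_ids = _feature_names(spec.n_taxa)
    n_unclassified = max(1, spec.n_taxa // 50)
    taxonomy = {}
    for i, fid in enumerate(feature_ids):
        if i >= spec.n_taxa - n_unclassified:
            taxonomy[fid] = "unclassified"
        else:
            taxonomy[fid] = f"Genus{i:04d}"
    n_core = int(round(shared_da_fraction * spec.n_da))
    # core DA taxa must be classified (to survive genus collapse) and
    # abundant enough to carry an observable signal
    classifiable = spec.n_taxa - n_unclassified
    base_shape = master.lognormal(0.0, spec.baseline_log_sd, size=spec.n_taxa)
    rel = base_shape / base_shape.sum()
    eligible = _spike_eligible(rel, spec, limit=classifiable)
    core_idx = master.choice(eligible, size=n_core, replace=False)
    studies = []
    for k in range(n_studies):
        rng_k = np.random.default_rng(master.integers(0, 2**31 - 1))
        remaining = np.setdiff1d(eligible, core_idx)
        extra = rng_k.choice(
            remaining, size=spec.n_da - n_core, replace=False
        ) if spec.n_da - n_core > 0 else np.empty(0, dtype=int)
        da_idx = np.concatenate([core_idx, extra]).astype(int)
        jitter = rng_k.lognormal(0.0, 0.3, size=spec.n_taxa)
        baseline = base_shape * jitter
        baseline = baseline / baseline.sum()
        study_spec = replace(spec, seed=int(rng_k.integers(0, 2**31 - 1)))
        table, labels, truth = generate_dataset(
            study_spec, feature_ids=feature_ids, baseline=baseline, da_idx=da_idx
        )
        studies.append((table, labels, truth))
    return studies, taxonomy
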