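"""Within-dataset evaluation: significance summaries, characteristic
correlations, cross-tool consensus, Jaccard/PCoA ordination, and the
random-relabel false-discovery simulation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .methods import DAResult, MethodConfig, RAREFIED_METHODS, run_all
from .tables import CountTable, DatasetCharacteristics, GroupLabels, rarefy

__all__ = [
    "SignificanceMatrix",
    "FDRSimResult",
    "ConsensusTally",
    "percent_significant_matrix",
    "correlate_characteristics",
    "consensus_tally",
    "top_k_overlap",
    "jaccard_matrix",
    "mean_jaccard_pcoa",
    "fdr_simulation",
]


@dataclass
class SignificanceMatrix:
    """Datasets x methods percentages of significant features, plus a
    per-dataset standardized (scaled, mean-centred) version and the
    complete-linkage dataset ordering used for heatmap display."""

    datasets: list[str]
    methods: list[str]
    pct_significant: np.ndarray
    standardized: np.ndarray
    dataset_order: list[int]

    def to_frame(self, standardized: bool = False) -> pd.DataFrame:
        m = self.standardized if standardized else self.pct_significant
        return pd.DataFrame(m, index=self.datasets, columns=self.methods)


@dataclass
class FDRSimResult:
    """Replicate percentages of significant features under random relabelling."""

    dataset: str
    method: str
    replicate_pct_significant: np.ndarray
    n_replicates: int
    seed: int

    @property
    def median_pct(self) -> float:
        vals = self.replicate_pct_significant
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else float("nan")


@dataclass
class ConsensusTally:
    """Per-feature count of methods calling it significant, with per-method
    breakdowns of how shared each method's calls are."""

    tally: dict[str, int]
    per_method: dict[str, dict[int, int]]
    n_methods: int

    @property
    def histogram(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.tally.values():
            out[c] = out.get(c, 0) + 1
        return out

    def unique_fraction(self, method: str) -> float:
        """Fraction of a method's calls that no other method made."""
        breakdown = self.per_method[method]
        total = sum(breakdown.values())
        return breakdown.get(1, 0) / total if total else float("nan")


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    if m.shape[1] < 2:
        return np.zeros_like(m, dtype=np.float64)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(m, dtype=np.float64)
    np.divide(m - mean, sd, out=out, where=sd > 0)
    return out


def percent_significant_matrix(
    results: dict[str, dict[str, DAResult]]
) -> SignificanceMatrix:
    """Percent significant features per dataset x method, standardized rows,
    and a complete-linkage (Euclidean) clustering order of the datasets."""
    datasets = list(results)
    method_sets = [tuple(r) for r in results.values()]
    if len(set(method_sets)) != 1:
        raise ValueError("all datasets must share the same method set")
    methods = list(method_sets[0])
    pct = np.zeros((len(datasets), len(methods)))
    for i, ds in enumerate(datasets):
        for j, m in enumerate(methods):
            res = results[ds][m]
            n_tested = len(res.feature_ids)
            if n_tested == 0:
                raise ValueError(f"dataset {ds!r} has zero tested features")
            pct[i, j] = 100.0 * np.sum(res.significant) / n_tested
    standardized = _standardize_rows(pct)
    if len(datasets) > 2:
        order = list(leaves_list(linkage(pct, method="complete", metric="euclidean")))
    else:
        order = list(range(len(datasets)))
    return SignificanceMatrix(datasets, methods, pct, standardized, order)


_CHARACTERISTICS = (
    "n_samples",
    "effect_size_r2",
    "sparsity",
    "mean_richness",
    "median_depth",
    "depth_range",
    "depth_cv",
)


def correlate_characteristics(
    sig: SignificanceMatrix,
    chars: dict[str, DatasetCharacteristics],
    include_low_prev: bool = False,
    display_alpha: float = 0.05,
) -> dict[str, dict[str, tuple[float, float, bool]]]:
    """Spearman correlations of per-method % significant vs dataset
    characteristics. Returns method -> characteristic -> (rho, p, displayed)
    where ``displayed`` masks at uncorrected p < display_alpha. Constant
    characteristic vectors yield no entry."""
    if len(sig.datasets) < 5:
        raise ValueError("need >= 5 datasets for characteristic correlations")
    names = _CHARACTERISTICS + (("pct_low_prevalence",) if include_low_prev else ())
    out: dict[str, dict[str, tuple[float, float, bool]]] = {}
    char_vectors = {
        name: np.array([chars[ds].as_dict()[name] for ds in sig.datasets])
        for name in names
    }
    for j, method in enumerate(sig.methods):
        y = sig.pct_significant[:, j]
        out[method] = {}
        for name, x in char_vectors.items():
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = stats.spearmanr(x, y)
            out[method][name] = (float(rho), float(p), bool(p < display_alpha))
    return out


def consensus_tally(results: dict[str, DAResult]) -> ConsensusTally:
    """Tally, per feature, how many methods called it significant."""
    tally: dict[str, int] = {}
    for res in results.values():
        for f in res.significant_features:
            tally[f] = tally.get(f, 0) + 1
    per_method: dict[str, dict[int, int]] = {}
    for name, res in results.items():
        breakdown: dict[int, int] = {}
        for f in res.significant_features:
            c = tally[f]
            breakdown[c] = breakdown.get(c, 0) + 1
        per_method[name] = breakdown
    return ConsensusTally(tally, per_method, n_methods=len(results))


def _ranking_key(res: DAResult) -> list[str]:
    """Feature ranking for top-k overlap: ascending raw p; descending W for
    the ANCOM-like method; descending |score| (then ascending screen p) for
    the LEfSe-like method. Ties broken by feature ID."""
    fids = res.feature_ids
    if res.method == "ancom2":
        keys = [(-res.statistic[i], fids[i]) for i in range(len(fids))]
    elif res.method == "lefse":
        keys = []
        for i in range(len(fids)):
            score = res.statistic[i]
            if np.isfinite(score):
                keys.append((0, -score, fids[i]))
            else:
                p = res.raw_p[i] if res.raw_p is not None else 1.0
                keys.append((1, p, fids[i]))
    elif res.raw_p is not None:
        keys = [(res.raw_p[i], fids[i]) for i in range(len(fids))]
    else:
        raise ValueError(f"method {res.method!r} lacks a usable ranking")
    order = sorted(range(len(fids)), key=lambda i: keys[i])
    return [fids[i] for i in order]


def top_k_overlap(results: dict[str, DAResult], k: int = 20) -> ConsensusTally:
    """Consensus tally over each method's top-k ranked features."""
    top_sets: dict[str, set[str]] = {}
    for name, res in results.items():
        if len(res.feature_ids) < k:
            raise ValueError(f"method {name!r} tested fewer than k={k} features")
        try:
            ranked = _ranking_key(res)
        except ValueError:
            import warnings

            warnings.warn(f"method {name!r} lacks a ranking; excluded", stacklevel=2)
            continue
        top_sets[name] = set(ranked[:k])
    tally: dict[str, int] = {}
    for s in top_sets.values():
        for f in s:
            tally[f] = tally.get(f, 0) + 1
    per_method = {
        name: _breakdown(s, tally) for name, s in top_sets.items()
    }
    return ConsensusTally(tally, per_method, n_methods=len(top_sets))


def _breakdown(features: set[str], tally: dict[str, int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for f in features:
        c = tally[f]
        out[c] = out.get(c, 0) + 1
    return out


def jaccard_matrix(results: dict[str, DAResult]) -> pd.DataFrame:
    """Method x method Jaccard distances between significant-feature sets.

    Convention for empty sets: two empty sets are at distance 0; an empty set
    vs a non-empty set is at distance 1.
    """
    names = list(results)
    sets = {n: results[n].significant_features for n in names}
    d = np.zeros((len(names), len(names)))
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            a, b = sets[ni], sets[names[j]]
            union = len(a | b)
            dist = 0.0 if union == 0 else 1.0 - len(a & b) / union
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=names, columns=names)


def mean_jaccard_pcoa(
    matrices: list[pd.DataFrame],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Average the per-dataset distance matrices (weighting datasets equally)
    and ordinate by classical metric MDS (double-centring + eigendecomposition).

    Returns coordinates on the positive-eigenvalue axes and the full
    eigenvalue spectrum.
    """
    if not matrices:
        raise ValueError("need at least one distance matrix")
    methods = list(matrices[0].index)
    if len(methods) < 3:
        raise ValueError("need >= 3 methods for ordination")
    for m in matrices:
        if list(m.index) != methods or list(m.columns) != methods:
            raise ValueError("distance matrices must share method order")
    mean_d = np.mean([m.to_numpy() for m in matrices], axis=0)
    n = len(methods)
    d2 = mean_d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return pd.DataFrame(coords, index=methods, columns=cols), eigvals


def fdr_simulation(
    table: CountTable,
    labels: GroupLabels,
    methods: list[str],
    n_replicates: int = 100,
    cfg: MethodConfig = MethodConfig(),
    seed: int = 42,
    replicate_budget: dict[str, int] | None = None,
    balanced: bool = True,
    rarefy_depth="auto",
) -> list[FDRSimResult]:
    """False-discovery simulation by random relabelling.

    The most frequent group is retained (ensuring compositional homogeneity);
    per replicate its samples are randomly split into case/control (balanced
    by default) and the requested workflows are run; the percentage of
    features significant under each workflow's own rule (BH q <= alpha for
    p-value methods) is recorded. ``replicate_budget`` lowers the replicate
    count for slow methods. A failed method run is recorded as NaN.
    """
    counts = {
        g: sum(1 for v in labels.assignment.values() if v == g) for g in labels.groups
    }
    major = max(labels.groups, key=lambda g: counts[g])
    keep = [
        s
        for s in table.sample_ids
        if labels.assignment.get(s) == major
    ]
    if len(keep) < 8:
        raise ValueError("majority group must have >= 8 samples")
    sub = table.select_samples(keep)
    rarefied = rarefy(sub, depth=rarefy_depth, seed=seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]
    budgets = {m: n_replicates for m in methods}
    if replicate_budget:
        budgets.update(replicate_budget)
    per_method = {m: np.full(n_replicates, np.nan) for m in methods}
    n = len(keep)
    half = n // 2
    for r in range(n_replicates):
        rng = np.random.default_rng(child_seeds[r])
        perm = rng.permutation(n)
        if balanced:
            case_idx = set(perm[:half])
        else:
            n_case = int(rng.integers(2, n - 1))
            case_idx = set(perm[:n_case])
        assignment = {
            s: ("case" if i in case_idx else "control") for i, s in enumerate(keep)
        }
        split = GroupLabels(assignment, ("control", "case"))
        rep_cfg = dataclasses.replace(cfg, seed=child_seeds[r])
        active = [m for m in methods if r < budgets[m]]
        if not active:
            continue
        try:
            res = run_all(sub, rarefied, split, rep_cfg, methods=active)
        except Exception:
            res = {}
            for m in active:
                try:
                    res.update(run_all(sub, rarefied, split, rep_cfg, methods=[m]))
                except Exception:
                    pass
        for m in active:
            if m in res:
                r_m = res[m]
                per_method[m][r] = 100.0 * np.sum(r_m.significant) / len(r_m.feature_ids)
    return [
        FDRSimResult(
            dataset="",
            method=m,
            replicate_pct_significant=per_method[m][: budgets[m]],
            n_replicates=budgets[m],
            seed=seed,
        )
        for m in methods
    ]
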