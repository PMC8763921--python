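"""Native implementations of the differential-abundance testing workflows.

Nine two-group workflows are provided, spanning the main families of
microbiome DA testing:

====================  ==========================================================
name                  procedure
====================  ==========================================================
``ttest_rare``        Welch's t-test on TSS proportions of the rarefied table
``wilcoxon_rare``     Wilcoxon rank-sum on raw rarefied abundances
``wilcoxon_clr``      Wilcoxon rank-sum on CLR abundances (non-rarefied, pc 1)
``aldex2``            Dirichlet Monte-Carlo instances -> CLR -> rank-sum,
                      expected BH q averaged across instances
``ancom2``            ANCOM-style pairwise additive log-ratio rank-sum tests,
                      W statistic with a 0.9 detection fraction, structural
                      zeros auto-called
``corncob``           per-feature beta-binomial regression (logit mean, shared
                      logit overdispersion), Wald test on the group coefficient
``lefse``             Kruskal-Wallis screen then LDA effect size on per-million
                      abundances, threshold 2.0, no FDR correction
``maaslin2``          TSS -> arcsine-square-root -> linear model Wald test
``maaslin2_rare``     the same on the rarefied table
====================  ==========================================================

All p-value-based workflows apply Benjamini-Hochberg correction and call a
feature significant at q <= alpha (default 0.05). Effect directions are
positive when the feature is higher in the second group of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .tables import CountTable, GroupLabels
from .transforms import benjamini_hochberg, clr_transform, tss_normalize

__all__ = [
    "MethodConfig",
    "DAResult",
    "t_test_rare",
    "wilcoxon_rare",
    "wilcoxon_clr",
    "aldex2_like",
    "ancom2_like",
    "lefse_like",
    "maaslin2_like",
    "corncob_like",
    "run_all",
    "METHOD_NAMES",
    "RAREFIED_METHODS",
]


@dataclass(frozen=True)
class MethodConfig:
    """Shared knobs of the testing workflows.

    alpha: significance cutoff on BH-adjusted p-values.
    pseudocount: added before log transforms.
    n_mc_instances: Dirichlet Monte-Carlo instances for the ALDEx2-like test.
    w_fraction: detection fraction of the ANCOM W rule (W > w_fraction*(m-1)).
    lda_threshold: LEfSe-style log10 effect-size cutoff.
    kw_alpha: LEfSe-style Kruskal-Wallis screening alpha (uncorrected).
    lefse_rounds / lefse_subsample / lefse_shrinkage: LDA bootstrap settings.
    ancom_outlier_zeros: optional outlier-zero masking step (off by default).
    """

    alpha: float = 0.05
    pseudocount: float = 1.0
    n_mc_instances: int = 128
    w_fraction: float = 0.9
    lda_threshold: float = 2.0
    kw_alpha: float = 0.05
    seed: int = 42
    lefse_rounds: int = 30
    lefse_subsample: float = 2.0 / 3.0
    lefse_shrinkage: float = 1e-3
    ancom_outlier_zeros: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.w_fraction <= 1:
            raise ValueError("w_fraction must be in (0, 1]")
        if self.n_mc_instances < 2:
            raise ValueError("n_mc_instances must be >= 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class DAResult:
    """Per-feature output of one testing workflow."""

    method: str
    feature_ids: tuple[str, ...]
    statistic: np.ndarray
    raw_p: np.ndarray | None
    q: np.ndarray | None
    significant: np.ndarray
    effect_direction: np.ndarray
    notes: list[str]

    def __post_init__(self) -> None:
        m = len(self.feature_ids)
        for name in ("statistic", "significant", "effect_direction"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length != number of features")
        for name in ("raw_p", "q"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != m:
                raise ValueError(f"{name} length != number of features")
        if len(self.notes) != m:
            raise ValueError("notes length != number of features")

    @property
    def significant_features(self) -> set[str]:
        return {f for f, s in zip(self.feature_ids, self.significant) if s}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.feature_ids),
                "statistic": self.statistic,
                "raw_p": self.raw_p if self.raw_p is not None else np.nan,
                "q": self.q if self.q is not None else np.nan,
                "significant": self.significant,
                "direction": self.effect_direction,
                "notes": self.notes,
            }
        )


def _split(table: CountTable, labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    """Counts restricted to labelled samples plus the second-group membership mask."""
    sample_ids = [s for s in table.sample_ids if s in labels.assignment]
    missing_groups = {labels.assignment[s] for s in sample_ids}
    if len(missing_groups) < 2:
        raise ValueError("both groups must be present among the table's samples")
    idx = [table.sample_ids.index(s) for s in sample_ids]
    counts = table.counts[:, idx].astype(np.float64)
    member = labels.membership(sample_ids)
    if member.sum() < 2 or (~member).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return counts, member


def _rank_sum(
    b: np.ndarray, a: np.ndarray, exact_max: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided rank-sum test of b vs a.

    Exact null distribution when both group sizes are <= ``exact_max`` and the
    row has no ties; otherwise the normal approximation with continuity and
    tie correction. Returns (U of b, p, all-tied mask).
    """
    b = np.atleast_2d(b)
    a = np.atleast_2d(a)
    n_feat = b.shape[0]
    tied = np.array(
        [np.ptp(np.concatenate([b[i], a[i]])) == 0 for i in range(n_feat)]
    )
    u = np.full(n_feat, np.nan)
    p = np.ones(n_feat)
    small = b.shape[1] <= exact_max and a.shape[1] <= exact_max
    for_asym = []
    for i in range(n_feat):
        if tied[i]:
            u[i] = b.shape[1] * a.shape[1] / 2.0
            continue
        row_has_ties = (
            np.unique(np.concatenate([b[i], a[i]])).size < b.shape[1] + a.shape[1]
        )
        if small and not row_has_ties:
            res = stats.mannwhitneyu(b[i], a[i], method="exact")
            u[i], p[i] = res.statistic, res.pvalue
        else:
            for_asym.append(i)
    if for_asym:
        idx = np.array(for_asym)
        res = stats.mannwhitneyu(b[idx], a[idx], axis=1, method="asymptotic")
        u[idx] = res.statistic
        p[idx] = res.pvalue
    return u, np.clip(p, 0.0, 1.0), tied


def _directions(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    return np.sign(np.median(b, axis=1) - np.median(a, axis=1))


def t_test_rare(
    rarefied: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """Welch's t-test per feature on TSS proportions of the rarefied table."""
    counts, member = _split(rarefied, labels)
    props = tss_normalize(counts)
    b, a = props[:, member], props[:, ~member]
    notes = [""] * rarefied.n_features
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=np.float64)
    p = np.asarray(res.pvalue, dtype=np.float64)
    var0 = (np.var(b, axis=1) == 0) & (np.var(a, axis=1) == 0)
    equal_means = np.isclose(b.mean(axis=1), a.mean(axis=1))
    for i in np.flatnonzero(var0 & equal_means):
        stat[i], p[i], notes[i] = 0.0, 1.0, "untestable"
    for i in np.flatnonzero(var0 & ~equal_means):
        stat[i] = np.inf * np.sign(b[i].mean() - a[i].mean())
        p[i], notes[i] = 0.0, "degenerate_variance"
    p = np.where(np.isnan(p), 1.0, p)
    q = benjamini_hochberg(p)
    return DAResult(
        method="ttest_rare",
        feature_ids=rarefied.feature_ids,
        statistic=stat,
        raw_p=p,
        q=q,
        significant=q <= cfg.alpha,
        effect_direction=np.sign(b.mean(axis=1) - a.mean(axis=1)),
        notes=notes,
    )


def _wilcoxon_result(
    name: str,
    feature_ids: tuple[str, ...],
    values: np.ndarray,
    member: np.ndarray,
    cfg: MethodConfig,
) -> DAResult:
    b, a = values[:, member], values[:, ~member]
    u, p, tied = _rank_sum(b, a)
    notes = ["all_tied" if t else "" for t in tied]
    q = benjamini_hochberg(p)
    return DAResult(
        method=name,
        feature_ids=feature_ids,
        statistic=u,
        raw_p=p,
        q=q,
        significant=q <= cfg.alpha,
        effect_direction=_directions(b, a),
        notes=notes,
    )


def wilcoxon_rare(
    rarefied: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """Wilcoxon rank-sum test per feature on raw rarefied abundances."""
    counts, member = _split(rarefied, labels)
    return _wilcoxon_result("wilcoxon_rare", rarefied.feature_ids, counts, member, cfg)


def wilcoxon_clr(
    table: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """Wilcoxon rank-sum test per feature on CLR abundances of the non-rarefied table."""
    counts, member = _split(table, labels)
    clr = clr_transform(counts, cfg.pseudocount)
    return _wilcoxon_result("wilcoxon_clr", table.feature_ids, clr, member, cfg)


def aldex2_like(
    table: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """Dirichlet Monte-Carlo instance test with expected BH q.

    Per instance a composition is drawn for every sample from
    Dirichlet(counts + 1) (uniform prior), CLR-transformed, and tested per
    feature with the rank-sum test; BH correction is applied within each
    instance and the final q per feature is the mean q across instances.
    """
    counts, member = _split(table, labels)
    rng = np.random.default_rng(cfg.seed)
    n_feat = counts.shape[0]
    sum_p = np.zeros(n_feat)
    sum_q = np.zeros(n_feat)
    sum_effect = np.zeros(n_feat)
    for _ in range(cfg.n_mc_instances):
        gammas = rng.standard_gamma(counts + 1.0)
        comp = gammas / gammas.sum(axis=0, keepdims=True)
        logc = np.log(comp)
        clr = logc - logc.mean(axis=0, keepdims=True)
        b, a = clr[:, member], clr[:, ~member]
        res = stats.mannwhitneyu(b, a, axis=1, method="asymptotic")
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        sum_p += p
        sum_q += benjamini_hochberg(p)
        sum_effect += b.mean(axis=1) - a.mean(axis=1)
    mean_p = sum_p / cfg.n_mc_instances
    mean_q = sum_q / cfg.n_mc_instances
    effect = sum_effect / cfg.n_mc_instances
    return DAResult(
        method="aldex2",
        feature_ids=table.feature_ids,
        statistic=effect,
        raw_p=mean_p,
        q=mean_q,
        significant=mean_q <= cfg.alpha,
        effect_direction=np.sign(effect),
        notes=[""] * n_feat,
    )


def ancom2_like(
    table: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """ANCOM-style W statistic with structural-zero handling.

    Features with zero total count in exactly one group are removed from the
    log-ratio testing and automatically called significant ("structural
    zeros"). For the m remaining features, every pairwise additive log-ratio
    log(c_i + 1) - log(c_j + 1) is tested between groups with the rank-sum
    test; each feature's m-1 p-values are BH-corrected and W_i counts those
    with q <= alpha. A feature is called when W_i > w_fraction * (m - 1).
    """
    counts, member = _split(table, labels)
    n_feat = counts.shape[0]
    tot_b = counts[:, member].sum(axis=1)
    tot_a = counts[:, ~member].sum(axis=1)
    structural = ((tot_a == 0) & (tot_b > 0)) | ((tot_b == 0) & (tot_a > 0))
    testable = np.flatnonzero(~structural & ((tot_a + tot_b) > 0))
    m = testable.size
    if m < 2:
        raise ValueError("fewer than 2 testable features after structural-zero removal")
    logc = np.log(counts[testable] + cfg.pseudocount)
    if cfg.ancom_outlier_zeros:
        logc = _mask_outlier_zeros(counts[testable], logc, member)
    ii, jj = np.triu_indices(m, 1)
    alr = logc[ii] - logc[jj]
    b, a = alr[:, member], alr[:, ~member]
    if np.isnan(alr).any():
        p_pairs = np.empty(ii.size)
        for k in range(ii.size):
            xb = b[k][~np.isnan(b[k])]
            xa = a[k][~np.isnan(a[k])]
            if xb.size < 2 or xa.size < 2 or np.ptp(np.concatenate([xb, xa])) == 0:
                p_pairs[k] = 1.0
            else:
                p_pairs[k] = stats.mannwhitneyu(xb, xa, method="asymptotic").pvalue
    else:
        res = stats.mannwhitneyu(b, a, axis=1, method="asymptotic")
        p_pairs = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    pmat = np.ones((m, m))
    pmat[ii, jj] = p_pairs
    pmat[jj, ii] = p_pairs
    w = np.zeros(n_feat)
    for local_i, feat in enumerate(testable):
        row = np.delete(pmat[local_i], local_i)
        qrow = benjamini_hochberg(row)
        w[feat] = int(np.sum(qrow <= cfg.alpha))
    significant = np.zeros(n_feat, dtype=bool)
    significant[testable] = w[testable] > cfg.w_fraction * (m - 1)
    significant |= structural
    notes = [""] * n_feat
    for i in np.flatnonzero(structural):
        notes[i] = "structural_zero"
    for i in np.flatnonzero(~structural & ((tot_a + tot_b) == 0)):
        notes[i] = "untestable"
    clr = clr_transform(counts, cfg.pseudocount)
    return DAResult(
        method="ancom2",
        feature_ids=table.feature_ids,
        statistic=w,
        raw_p=None,
        q=None,
        significant=significant,
        effect_direction=np.sign(
            clr[:, member].mean(axis=1) - clr[:, ~member].mean(axis=1)
        ),
        notes=notes,
    )


def _mask_outlier_zeros(
    counts: np.ndarray, logc: np.ndarray, member: np.ndarray
) -> np.ndarray:
    """Optional ANCOM outlier-zero masking: a zero is treated as missing when
    the feature is otherwise consistently present in that group (within-group
    nonzero fraction > 0.75 and nonzero median > 5)."""
    logc = logc.copy()
    for mask in (member, ~member):
        grp = counts[:, mask]
        nz_frac = (grp > 0).mean(axis=1)
        nz_median = np.array(
            [np.median(row[row > 0]) if (row > 0).any() else 0.0 for row in grp]
        )
        outlier_rows = (nz_frac > 0.75) & (nz_median > 5)
        cols = np.flatnonzero(mask)
        for i in np.flatnonzero(outlier_rows):
            zero_cols = cols[grp[i] == 0]
            logc[i, zero_cols] = np.nan
    return logc


def _kruskal_two_group(values: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Vectorised two-group Kruskal-Wallis p-values (chi-square, tie-corrected)."""
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    r_b = ranks[:, member].sum(axis=1)
    n_b = int(member.sum())
    n_a = n - n_b
    r_a = ranks[:, ~member].sum(axis=1)
    grand = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        n_b * (r_b / n_b - grand) ** 2 + n_a * (r_a / n_a - grand) ** 2
    )
    # tie correction
    correction = np.ones(values.shape[0])
    for i in range(values.shape[0]):
        _, t_counts = np.unique(values[i], return_counts=True)
        c = 1.0 - np.sum(t_counts**3 - t_counts) / (n**3 - n)
        correction[i] = c
    with np.errstate(divide="ignore", invalid="ignore"):
        h = h / correction
    p = stats.chi2.sf(h, df=1)
    return np.where(np.isnan(p) | (correction <= 0), 1.0, p)


def lefse_like(
    rarefied: CountTable, labels: GroupLabels, cfg: MethodConfig = MethodConfig()
) -> DAResult:
    """Kruskal-Wallis screen + LDA effect size on per-million abundances.

    Counts are TSS-normalised and rescaled to per-million. Features passing
    the (uncorrected) KW screen at ``kw_alpha`` receive an LDA-based effect
    size: over ``lefse_rounds`` random subsamples of ~2/3 of each class, a
    two-class LDA with a small shrinkage ridge is fitted and the per-feature
    effect is the average of the feature's discriminant contribution
    (coefficient times projected class difference) and its raw class-mean
    difference; the reported score is log10(1 + mean effect). A feature is
    significant when score >= lda_threshold. No multiple-testing correction
    is applied, matching the original biomarker-discovery behaviour.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    counts, member = _split(rarefied, labels)
    ppm = tss_normalize(counts) * 1e6
    n_feat = counts.shape[0]
    raw_p = _kruskal_two_group(ppm, member)
    survivors = np.flatnonzero(raw_p <= cfg.kw_alpha)
    score = np.full(n_feat, np.nan)
    notes = [""] * n_feat
    direction = _directions(ppm[:, member], ppm[:, ~member])
    if survivors.size > 0:
        x = ppm[survivors].T  # samples x surviving features
        y = member.astype(int)
        rng = np.random.default_rng(cfg.seed)
        idx_b = np.flatnonzero(member)
        idx_a = np.flatnonzero(~member)
        n_sub_b = max(2, int(np.ceil(cfg.lefse_subsample * idx_b.size)))
        n_sub_a = max(2, int(np.ceil(cfg.lefse_subsample * idx_a.size)))
        effects = np.zeros(survivors.size)
        regularized = False
        for _ in range(cfg.lefse_rounds):
            pick = np.concatenate(
                [
                    rng.choice(idx_b, size=min(n_sub_b, idx_b.size), replace=False),
                    rng.choice(idx_a, size=min(n_sub_a, idx_a.size), replace=False),
                ]
            )
            xs, ys = x[pick], y[pick]
            shrink = cfg.lefse_shrinkage
            for attempt in range(3):
                try:
                    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrink)
                    lda.fit(xs, ys)
                    break
                except Exception:
                    shrink = min(1.0, 10.0 ** (attempt + 1) * cfg.lefse_shrinkage)
                    regularized = True
            else:  # pragma: no cover - last resort
                continue
            w = lda.coef_[0]
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            w = w / norm
            mu1 = xs[ys == 1].mean(axis=0)
            mu0 = xs[ys == 0].mean(axis=0)
            d = float(w @ (mu1 - mu0))
            effects += np.abs((w * d + (mu1 - mu0)) / 2.0)
        effects /= cfg.lefse_rounds
        score[survivors] = np.log10(1.0 + effects)
        if regularized:
            for i in survivors:
                notes[i] = "lda_regularized"
    significant = np.zeros(n_feat, dtype=bool)
    significant[survivors] = score[survivors] >= cfg.lda_threshold
    return DAResult(
        method="lefse",
        feature_ids=rarefied.feature_ids,
        statistic=score,
        raw_p=raw_p,
        q=None,
        significant=significant,
        effect_direction=direction,
        notes=notes,
    )


def maaslin2_like(
    table: CountTable,
    labels: GroupLabels,
    cfg: MethodConfig = MethodConfig(),
    rarefied_input: bool = False,
) -> DAResult:
    """TSS + arcsine-square-root transform + linear-model Wald test.

    Each feature's AST-transformed relative abundance is regressed on the
    group indicator with an ordinary linear model; the Wald test on the group
    coefficient in this two-group, no-covariate design is the pooled-variance
    two-sample t-test. Pass the rarefied table with ``rarefied_input=True``
    for the rarefied variant of the workflow.
    """
    counts, member = _split(table, labels)
    y = np.arcsin(np.sqrt(tss_normalize(counts)))
    b, a = y[:, member], y[:, ~member]
    n_b, n_a = b.shape[1], a.shape[1]
    df = n_b + n_a - 2
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = b.var(axis=1, ddof=1) * (n_b - 1) + a.var(axis=1, ddof=1) * (n_a - 1)
    pooled_var = ss / df
    notes = [""] * table.n_features
    stat = np.zeros(table.n_features)
    p = np.ones(table.n_features)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled_var * (1.0 / n_b + 1.0 / n_a))
        t = diff / se
    ok = se > 0
    stat[ok] = t[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    for i in np.flatnonzero(~ok):
        notes[i] = "untestable"
    q = benjamini_hochberg(p)
    return DAResult(
        method="maaslin2_rare" if rarefied_input else "maaslin2",
        feature_ids=table.feature_ids,
        statistic=stat,
        raw_p=p,
        q=q,
        significant=q <= cfg.alpha,
        effect_direction=np.sign(diff),
        notes=notes,
    )


def _betabinom_nll(params: np.ndarray, k: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    b0, b1, c0 = params
    mu = expit(np.clip(b0 + b1 * x, -30, 30))
    rho = expit(np.clip(c0, -30, 15))
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    rho = np.clip(rho, 1e-10, 1 - 1e-6)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    ll = stats.betabinom.logpmf(k, n, a, b)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return float(-ll.sum())


def corncob_like(
    table: CountTable,
    labels: GroupLabels,
    cfg: MethodConfig = MethodConfig(),
    n_restarts: int = 3,
) -> DAResult:
    """Beta-binomial regression per feature with a Wald test on the group term.

    Counts are modelled as BetaBinomial(depth, mu, rho) with
    logit(mu) = b0 + b1 * group and a shared logit overdispersion, so only
    mean (abundance) differences are tested. The Wald SE comes from the
    observed information at the maximum-likelihood estimate. Features present
    in only one group are flagged "untestable" and excluded from the BH
    correction, as the original tool reports no value for them.
    """
    from scipy.optimize import minimize
    from statsmodels.tools.numdiff import approx_hess3

    counts, member = _split(table, labels)
    depths = counts.sum(axis=0)
    x = member.astype(np.float64)
    n_feat = table.n_features
    stat = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    coefs = np.full(n_feat, np.nan)
    notes = [""] * n_feat
    rng = np.random.default_rng(cfg.seed)
    for i in range(n_feat):
        k = counts[i]
        in_b = k[member].sum() > 0
        in_a = k[~member].sum() > 0
        if not (in_b and in_a):
            notes[i] = "untestable"
            continue
        overall = np.clip(k.sum() / depths.sum(), 1e-6, 1 - 1e-6)
        x0 = np.array([logit(overall), 0.0, logit(0.1)])
        best = None
        for attempt in range(1 + n_restarts):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=3)
            try:
                res = minimize(
                    _betabinom_nll,
                    start,
                    args=(k, depths, x),
                    method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
                )
            except Exception:
                continue
            if best is None or res.fun < best.fun:
                best = res
            if res.success and attempt >= 0 and best.fun < 1e11:
                break
        if best is None or best.fun >= 1e11:
            notes[i] = "nonconverged"
            continue
        try:
            hess = approx_hess3(best.x, _betabinom_nll, args=(k, depths, x))
            cov = np.linalg.inv(hess)
            with np.errstate(invalid="ignore"):
                se = np.sqrt(cov[1, 1])
        except Exception:
            notes[i] = "nonconverged"
            continue
        if not np.isfinite(se) or se <= 0:
            notes[i] = "nonconverged"
            continue
        coefs[i] = best.x[1]
        z = best.x[1] / se
        stat[i] = z
        p[i] = 2.0 * stats.norm.sf(abs(z))
    q = benjamini_hochberg(p)
    significant = np.zeros(n_feat, dtype=bool)
    ok = ~np.isnan(q)
    significant[ok] = q[ok] <= cfg.alpha
    result = DAResult(
        method="corncob",
        feature_ids=table.feature_ids,
        statistic=stat,
        raw_p=p,
        q=q,
        significant=significant,
        effect_direction=np.sign(np.where(np.isnan(coefs), 0.0, coefs)),
        notes=notes,
    )
    result.coefficients = coefs  # ML group coefficients, for recovery checks
    return result


RAREFIED_METHODS = frozenset({"ttest_rare", "wilcoxon_rare", "lefse", "maaslin2_rare"})

_DISPATCH: dict[str, Callable] = {
    "ttest_rare": t_test_rare,
    "wilcoxon_rare": wilcoxon_rare,
    "wilcoxon_clr": wilcoxon_clr,
    "aldex2": aldex2_like,
    "ancom2": ancom2_like,
    "corncob": corncob_like,
    "lefse": lefse_like,
    "maaslin2": lambda t, l, c: maaslin2_like(t, l, c, rarefied_input=False),
    "maaslin2_rare": lambda t, l, c: maaslin2_like(t, l, c, rarefied_input=True),
}

METHOD_NAMES: tuple[str, ...] = tuple(_DISPATCH)


def run_all(
    table: CountTable,
    rarefied: CountTable,
    labels: GroupLabels,
    cfg: MethodConfig = MethodConfig(),
    methods: Sequence[str] = METHOD_NAMES,
) -> dict[str, DAResult]:
    """Run the named workflows, dispatching each to its required input table."""
    unknown = [m for m in methods if m not in _DISPATCH]
    if unknown:
        raise ValueError(
            f"unknown methods {unknown}; valid names: {sorted(_DISPATCH)}"
        )
    results: dict[str, DAResult] = {}
    for name in methods:
        input_table = rarefied if name in RAREFIED_METHODS else table
        results[name] = _DISPATCH[name](input_table, labels, cfg)
    return results
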