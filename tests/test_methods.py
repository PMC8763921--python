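import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import betabinom

from microda import (
    CountTable,
    GroupLabels,
    MethodConfig,
    aldex2_like,
    ancom2_like,
    corncob_like,
    lefse_like,
    maaslin2_like,
    run_all,
    t_test_rare,
    wilcoxon_clr,
    wilcoxon_rare,
)
from microda.methods import METHOD_NAMES
from microda.simulate import SyntheticSpec, generate_dataset
from microda.tables import rarefy


def _two_group_table(a_rows: np.ndarray, b_rows: np.ndarray):
    """Build a CountTable + labels from per-group count matrices (features x n)."""
    counts = np.hstack([a_rows, b_rows]).astype(int)
    n_a, n_b = a_rows.shape[1], b_rows.shape[1]
    sids = tuple(f"a{i}" for i in range(n_a)) + tuple(f"b{i}" for i in range(n_b))
    table = CountTable(
        tuple(f"f{i}" for i in range(counts.shape[0])), sids, counts
    )
    labels = GroupLabels(
        {s: ("B" if s.startswith("b") else "A") for s in sids}, ("A", "B")
    )
    return table, labels


class TestWelch:
    def test_identical_groups_all_p_one(self, cfg):
        block = np.array([[5, 8, 7], [10, 10, 10]])
        table, labels = _two_group_table(block, block)
        res = t_test_rare(table, labels, cfg)
        assert np.all(res.raw_p == 1.0)
        assert not res.significant.any()

    def test_matches_textbook_welch_formula(self, cfg):
        # proportions of a 2-feature table so TSS is transparent; Welch t and
        # Welch-Satterthwaite df evaluated by hand on the first feature
        a = np.array([[10, 20, 30, 20], [90, 80, 70, 80]])
        b = np.array([[60, 50, 70], [40, 50, 30]])
        table, labels = _two_group_table(a, b)
        res = t_test_rare(table, labels, cfg)
        xa = a[0] / 100
        xb = b[0] / 100
        va, vb = xa.var(ddof=1) / 4, xb.var(ddof=1) / 3
        t_hand = (xb.mean() - xa.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 2)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        assert res.statistic[0] == pytest.approx(t_hand)
        assert res.raw_p[0] == pytest.approx(p_hand)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: full enumeration of the rank-sum null (no ties).

    Two-sided p = min(1, 2 * min(P(S <= s), P(S >= s))) over all equally
    likely assignments of the pooled ranks to the first group.
    """
    from scipy.stats import rankdata

    pooled_ranks = rankdata(np.concatenate([x, y]))
    n1 = len(x)
    obs = pooled_ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(pooled_ranks, n1)]
    n_total = len(sums)
    p_le = sum(1 for s in sums if s <= obs + 1e-9) / n_total
    p_ge = sum(1 for s in sums if s >= obs - 1e-9) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_extreme_ordering_exact_p(self, cfg):
        a = np.array([[1, 2, 3]])
        b = np.array([[4, 5, 6]])
        table, labels = _two_group_table(a, b)
        res = wilcoxon_rare(table, labels, cfg)
        assert res.raw_p[0] == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_constant_groups_p_one(self, cfg):
        block = np.full((1, 4), 7)
        table, labels = _two_group_table(block, block)
        res = wilcoxon_rare(table, labels, cfg)
        assert res.raw_p[0] == 1.0
        assert res.notes[0] == "all_tied"

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5)])
    def test_exact_p_matches_full_enumeration(self, cfg, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            vals = rng.choice(np.arange(1, 40), size=n1 + n2, replace=False)
            a, b = vals[:n1].reshape(1, -1), vals[n1:].reshape(1, -1)
            table, labels = _two_group_table(a, b)
            res = wilcoxon_rare(table, labels, cfg)
            assert res.raw_p[0] == pytest.approx(
                _exact_rank_sum_p(b[0].astype(float), a[0].astype(float))
            )

    def test_invariant_under_monotone_transform(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        squared = CountTable(table.feature_ids, table.sample_ids, table.counts**2)
        p1 = wilcoxon_rare(table, labels, cfg).raw_p
        p2 = wilcoxon_rare(squared, labels, cfg).raw_p
        assert np.allclose(p1, p2)

    def test_single_feature_clr_degenerate(self, cfg):
        a = np.array([[3, 6, 9]])
        b = np.array([[100, 50, 80]])
        table, labels = _two_group_table(a, b)
        res = wilcoxon_clr(table, labels, cfg)
        assert res.raw_p[0] == 1.0  # CLR of a single part is identically zero


class TestMaaslin2:
    def test_ast_endpoints(self):
        assert np.arcsin(np.sqrt(0.0)) == 0.0
        assert np.arcsin(np.sqrt(1.0)) == pytest.approx(np.pi / 2)

    def test_wald_equals_pooled_t_by_hand(self, cfg):
        a = np.array([[10, 30, 20], [90, 70, 80]])
        b = np.array([[50, 70, 60, 40], [50, 30, 40, 60]])
        table, labels = _two_group_table(a, b)
        res = maaslin2_like(table, labels, cfg)
        ya = np.arcsin(np.sqrt(a[0] / 100))
        yb = np.arcsin(np.sqrt(b[0] / 100))
        sp2 = (ya.var(ddof=1) * 2 + yb.var(ddof=1) * 3) / 5
        t_hand = (yb.mean() - ya.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 4))
        assert res.statistic[0] == pytest.approx(t_hand)

    def test_constant_feature_flagged(self, cfg):
        a = np.array([[50], [50], [0]]).reshape(3, 1) * np.ones((1, 3), dtype=int)
        b = a.copy()
        table, labels = _two_group_table(a, b)
        res = maaslin2_like(table, labels, cfg)
        assert "untestable" in res.notes

    def test_rarefied_variant_renames_method(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        res = maaslin2_like(table, labels, cfg, rarefied_input=True)
        assert res.method == "maaslin2_rare"


class TestAldex2:
    def test_null_data_rarely_calls(self):
        calls = []
        for seed in range(10):
            spec = SyntheticSpec(n_taxa=40, n_samples_per_group=(12, 12), seed=seed)
            table, labels, _ = generate_dataset(spec)
            res = aldex2_like(table, labels, MethodConfig(seed=seed, n_mc_instances=64))
            calls.append(int(res.significant.sum()))
        assert sum(1 for c in calls if c == 0) >= 9

    def test_strong_spike_detected(self):
        hits = []
        for seed in range(10):
            spec = SyntheticSpec(
                n_taxa=50,
                n_samples_per_group=(20, 20),
                n_da=1,
                fold_changes=(100.0,),
                zero_inflation=0.05,
                seed=seed,
            )
            table, labels, truth = generate_dataset(spec)
            res = aldex2_like(table, labels, MethodConfig(seed=seed))
            spiked = next(iter(truth.da_taxa))
            hits.append(spiked in res.significant_features)
        assert np.mean(hits) >= 0.95

    def test_expected_q_stable_across_seeds(self):
        spec = SyntheticSpec(n_taxa=50, n_samples_per_group=(20, 20), seed=5)
        table, labels, _ = generate_dataset(spec)
        qs = np.array(
            [aldex2_like(table, labels, MethodConfig(seed=s)).q for s in range(4)]
        )
        assert np.max(qs.std(axis=0)) < 0.02

    def test_deterministic_per_seed(self):
        spec = SyntheticSpec(n_taxa=20, n_samples_per_group=(8, 8), seed=1)
        table, labels, _ = generate_dataset(spec)
        r1 = aldex2_like(table, labels, MethodConfig(seed=3, n_mc_instances=16))
        r2 = aldex2_like(table, labels, MethodConfig(seed=3, n_mc_instances=16))
        assert np.array_equal(r1.q, r2.q)


class TestAncom2:
    def test_structural_zero_auto_called(self, cfg):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 50, size=(5, 8))
        a = base[:, :4].copy()
        b = base[:, 4:].copy()
        a[0] = 0  # absent in group A, present in B
        table, labels = _two_group_table(a, b)
        res = ancom2_like(table, labels, cfg)
        assert res.notes[0] == "structural_zero"
        assert res.significant[0]
        # structural zeros never enter the W computation
        assert res.statistic[0] == 0

    def test_w_bounded_by_m_minus_one(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        res = ancom2_like(table, labels, cfg)
        tested = [i for i, n in enumerate(res.notes) if n == ""]
        m = len(tested)
        assert np.all(res.statistic[tested] <= m - 1)
        assert np.all(res.statistic >= 0)

    def test_null_data_below_threshold(self):
        ok = 0
        for seed in range(10):
            spec = SyntheticSpec(n_taxa=30, n_samples_per_group=(12, 12), seed=seed + 50)
            table, labels, _ = generate_dataset(spec)
            res = ancom2_like(table, labels, MethodConfig(seed=seed))
            nonstructural = np.array(
                [n != "structural_zero" for n in res.notes]
            )
            ok += not res.significant[nonstructural].any()
        assert ok >= 9

    def test_single_strong_spike_is_unique_call(self):
        unique = []
        for seed in range(10):
            spec = SyntheticSpec(
                n_taxa=10,
                n_samples_per_group=(30, 30),
                n_da=1,
                fold_changes=(50.0,),
                baseline_log_sd=1.5,
                zero_inflation=0.05,
                seed=seed + 300,
            )
            table, labels, truth = generate_dataset(spec)
            res = ancom2_like(table, labels, MethodConfig(seed=seed))
            spiked = next(iter(truth.da_taxa))
            idx = table.feature_ids.index(spiked)
            unique.append(
                res.significant_features == {spiked}
                and res.statistic[idx] >= 0.9 * 9
            )
        assert np.mean(unique) >= 0.9

    def test_too_few_testable_features_errors(self, cfg):
        a = np.array([[5, 6], [0, 0]])
        b = np.array([[7, 8], [3, 4]])
        table, labels = _two_group_table(a, b)
        with pytest.raises(ValueError):
            ancom2_like(table, labels, cfg)


class TestLefse:
    def test_no_screen_survivors_no_calls(self, cfg):
        block = np.array([[10, 11, 12, 10], [90, 89, 88, 90]])
        table, labels = _two_group_table(block, block)
        res = lefse_like(table, labels, cfg)
        assert not res.significant.any()

    def test_large_mean_shift_scores_above_threshold(self, cfg):
        # proportions ~0.002 in group A vs ~0.2 in group B with tiny variance,
        # i.e. per-million means of ~2,000 vs ~200,000
        a = np.array([[20, 21, 19, 20], [9980, 9979, 9981, 9980]])
        b = np.array([[2000, 2010, 1990, 2005], [8000, 7990, 8010, 7995]])
        table, labels = _two_group_table(a, b)
        res = lefse_like(table, labels, cfg)
        assert res.statistic[0] > 2
        assert res.significant[0]

    def test_significance_ignores_alpha_setting(self, cfg, spiked_dataset):
        table, labels, _ = spiked_dataset
        rare = rarefy(table, depth=2000, seed=0)
        s1 = lefse_like(rare, labels, cfg).significant_features
        s2 = lefse_like(rare, labels, replace(cfg, alpha=0.001)).significant_features
        assert s1 == s2

    def test_q_absent(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        res = lefse_like(table, labels, cfg)
        assert res.q is None


class TestCorncob:
    def _betabinom_table(self, rng, n_per_group=40, depth=8000, delta=0.0, rho=0.01):
        mu0 = expit(-5.0)
        mu1 = expit(-5.0 + delta)
        rows = []
        for mu_pair in [(mu0, mu1)] * 8:
            k = np.concatenate(
                [
                    betabinom.rvs(
                        depth,
                        mu_pair[0] * (1 - rho) / rho,
                        (1 - mu_pair[0]) * (1 - rho) / rho,
                        size=n_per_group,
                        random_state=rng,
                    ),
                    betabinom.rvs(
                        depth,
                        mu_pair[1] * (1 - rho) / rho,
                        (1 - mu_pair[1]) * (1 - rho) / rho,
                        size=n_per_group,
                        random_state=rng,
                    ),
                ]
            )
            rows.append(k)
        k = np.array(rows)
        filler = depth - k.sum(axis=0)
        k = np.vstack([k, filler])
        a, b = k[:, :n_per_group], k[:, n_per_group:]
        return _two_group_table(a, b)

    def test_null_wald_p_roughly_uniform(self, cfg):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(4):
            table, labels = self._betabinom_table(rng, n_per_group=30)
            res = corncob_like(table, labels, cfg)
            ps.append(res.raw_p[:8])
        ps = np.concatenate(ps)
        ps = ps[~np.isnan(ps)]
        assert 0.0 <= (ps < 0.05).mean() <= 0.2
        assert ps.mean() > 0.3

    def test_coefficient_recovery(self, cfg):
        rng = np.random.default_rng(33)
        errs = []
        for _ in range(2):
            table, labels = self._betabinom_table(rng, n_per_group=50, delta=1.5)
            res = corncob_like(table, labels, cfg)
            errs.append(np.nanmean(res.coefficients[:8]) - 1.5)
        assert abs(np.mean(errs)) < 0.3

    def test_one_group_only_feature_untestable(self, cfg):
        rng = np.random.default_rng(4)
        a = rng.integers(10, 100, size=(4, 6))
        b = rng.integers(10, 100, size=(4, 6))
        a[2] = 0  # observed only in group B
        table, labels = _two_group_table(a, b)
        res = corncob_like(table, labels, cfg)
        assert res.notes[2] == "untestable"
        assert np.isnan(res.raw_p[2]) and np.isnan(res.q[2])
        assert not res.significant[2]


class TestRunAll:
    def test_all_nine_workflows(self, cfg, spiked_dataset):
        table, labels, _ = spiked_dataset
        rare = rarefy(table, depth=2000, seed=1)
        results = run_all(table, rare, labels, cfg, methods=METHOD_NAMES)
        assert len(results) == 9
        for name, res in results.items():
            assert res.feature_ids == table.feature_ids

    def test_empty_method_list(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        rare = rarefy(table, depth=1000, seed=1)
        assert run_all(table, rare, labels, cfg, methods=[]) == {}

    def test_unknown_method_lists_valid_names(self, cfg, null_dataset):
        table, labels, _ = null_dataset
        rare = rarefy(table, depth=1000, seed=1)
        with pytest.raises(ValueError, match="wilcoxon_rare"):
            run_all(table, rare, labels, cfg, methods=["nonsense"])

    def test_result_invariants_hold(self, cfg, spiked_dataset):
        table, labels, _ = spiked_dataset
        rare = rarefy(table, depth=2000, seed=1)
        results = run_all(table, rare, labels, cfg, methods=METHOD_NAMES)
        for name, res in results.items():
            m = len(res.feature_ids)
            assert len(res.statistic) == m
            assert len(res.significant) == m
            if res.raw_p is not None and res.q is not None:
                both = ~np.isnan(res.raw_p) & ~np.isnan(res.q)
                assert np.all(res.q[both] >= res.raw_p[both] - 1e-12)
                if name not in ("lefse", "ancom2", "aldex2"):
                    assert np.all(res.significant[both] == (res.q[both] <= cfg.alpha))
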