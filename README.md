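# microda

Consensus differential-abundance (DA) testing for two-group microbiome count
tables, with the evaluation machinery needed to compare DA workflows against
each other rather than trust any single one.

## Who this is for

Microbiome researchers hold a feature-by-sample table of 16S ASV (or genus)
counts and a two-group contrast (case/control, treated/untreated) and must
pick among a dozen mutually disagreeing DA tools. `microda` implements nine
representative workflows natively behind one interface, plus the analyses
that quantify their disagreement: cross-tool consensus tallies, a
random-relabelling false-discovery simulation, per-feature AUROC
discrimination scoring, and a genus-level cross-study consistency test
against a constructed permutation null.

## The workflows

All workflows test, per feature, whether abundance differs between two
groups, at alpha 0.05 on Benjamini–Hochberg adjusted p-values (where the
original tool corrects at all):

| name | procedure | input table |
|---|---|---|
| `ttest_rare` | Welch's t-test on TSS proportions | rarefied |
| `wilcoxon_rare` | Wilcoxon rank-sum on raw abundances | rarefied |
| `wilcoxon_clr` | Wilcoxon rank-sum on CLR abundances (pseudocount 1) | non-rarefied |
| `aldex2` | Dirichlet Monte-Carlo instances → CLR → rank-sum, expected BH q averaged over instances | non-rarefied |
| `ancom2` | all pairwise additive log-ratios tested by rank-sum; W statistic, detection at W > 0.9·(m−1); structural zeros auto-called | non-rarefied |
| `corncob` | beta-binomial regression (logit mean with group term, shared logit overdispersion), Wald test | non-rarefied |
| `lefse` | Kruskal–Wallis screen (p ≤ 0.05, uncorrected) then LDA effect size on per-million abundances, called at log10 score ≥ 2.0 | rarefied |
| `maaslin2` | TSS → arcsine-square-root → linear model Wald test | non-rarefied |
| `maaslin2_rare` | same, on the rarefied table | rarefied |

Key statistics, in standard notation: the CLR transform
clr(x)_i = ln(x_i / g(x)) with g the geometric mean of the pseudocounted
composition; the ANCOM W_i counts BH-significant pairwise log-ratio tests
log(x_i/x_j) for j ≠ i; per-feature AUROC is
P(X_case > X_ctrl) + ½·P(tie), folded to max(AUC, 1−AUC); cross-study
consistency compares the mean recurrence of significant genera across k
studies with its expectation under independent per-study random calls,
reported as a fold difference with a one-tailed permutation p.

## Worked example

```python
from microda import MethodConfig, consensus_tally, prevalence_filter, rarefy, run_all
from microda.simulate import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_da=20, fold_changes=(10.0,) * 20, seed=42)
table, labels, truth = generate_dataset(spec)     # 200 taxa, 50+50 samples
filtered = prevalence_filter(table, 0.10)         # drop features in <10% of samples
rarefied = rarefy(filtered, depth="auto", seed=42)
results = run_all(filtered, rarefied, labels, MethodConfig(seed=42))
for name, res in results.items():
    print(name, len(res.significant_features))
```

prints (see `examples/01_run_workflows.py` for the full script):

```
ttest_rare 52
wilcoxon_rare 37
wilcoxon_clr 56
aldex2 28
ancom2 0
corncob 36
lefse 50
maaslin2 36
maaslin2_rare 37
```

Twenty taxa were spiked 10-fold, yet the workflows call between 0 and 56
features: the extra calls are compositional coupling (spiking shifts every
relative abundance) plus each method's idiosyncrasies, and ANCOM-II's W rule
abstains entirely because more than 10% of taxa genuinely shifted. This
spread — and how to interpret it via consensus — is exactly what the
evaluation modules quantify. The other `examples/` scripts demonstrate the
false-discovery simulation, the read-depth confound artifact of CLR testing,
cross-study consistency, and AUROC discrimination.

A thin CLI mirrors the library (`microda simulate|prep|da run|eval|crossstudy|report`);
run `microda --help` for the stages.

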