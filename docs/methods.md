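# Methods

## Scope and model

`microda` treats a microbiome dataset as a feature-by-sample matrix of
non-negative integer counts with a two-group sample assignment. Counts are
compositional: library size is an artifact of sequencing effort, so only
relative information is meaningful. Every analysis is organised around that
constraint — workflows either equalise depth (rarefaction), normalise it
away (TSS), or model it explicitly (CLR, Dirichlet resampling,
beta-binomial trials).

Preparation follows the standard two-group pipeline: an optional prevalence
filter removes features present in fewer than 10% of samples (a feature at
exactly 10% is retained; removal is strictly below the cut-off), and
rarefaction subsamples each sample without replacement — multivariate
hypergeometric per sample — to the smallest library of at least 2000 reads,
discarding shallower samples. Prevalence is assessed on the unrarefied
table, and the filtered-rarefied table is produced by re-rarefying the
filtered table rather than subsetting the rarefied one, so that retained
samples keep exactly the target depth.

## Testing workflows

The nine workflows and their tunable parameters (all in `MethodConfig`):

- **alpha** (0.05): significance cut-off on BH-adjusted p-values, used by
  every workflow that corrects.
- **pseudocount** (1): added before any log transform.
- **ALDEx2-like** — per Monte-Carlo instance, each sample's composition is
  drawn from Dirichlet(counts + 1) (a uniform prior), CLR-transformed, and
  each feature tested by rank-sum; BH runs within each instance and the
  reported q is the arithmetic mean across instances ("expected q").
  **n_mc_instances** defaults to 128, the convention of the original tool;
  the expected q of a fixed input is stable to ~0.02 (s.d. across seeds) at
  that setting.
- **ANCOM-like** — features with zero total count in exactly one group are
  structural zeros: excluded from testing and called significant outright.
  For the m remaining features, each pairwise additive log-ratio
  log(c_i+1) − log(c_j+1) is rank-sum tested; each feature's m−1 p-values
  are BH-corrected and W_i counts those with q ≤ alpha. Detection requires
  W_i > **w_fraction** (0.9) × (m−1). The original tool's outlier-zero
  masking is under-specified upstream; it is implemented as an optional
  step, off by default: a zero is masked as missing when the feature's
  within-group nonzero fraction exceeds 0.75 and its nonzero median exceeds
  5 counts.
- **LEfSe-like** — rarefied counts are TSS-normalised and rescaled to
  per-million; features pass an uncorrected Kruskal–Wallis screen at
  **kw_alpha** (0.05) (with two groups this reduces to the rank-sum test);
  survivors get an LDA effect size averaged over **lefse_rounds** (30)
  random subsamples of ~2/3 of each class, each round fitting a two-class
  LDA with a small shrinkage ridge (**lefse_shrinkage**, 1e-3) on the
  scatter matrix. Per round the feature's effect is the average of its
  discriminant contribution (unit-norm coefficient times the projected
  class-mean difference) and its raw class-mean difference; the score is
  log10(1 + mean effect) and calls require score ≥ **lda_threshold** (2.0).
  No FDR correction is applied, matching the original biomarker-discovery
  behaviour. These internals are this package's own fully specified design;
  they mirror the published procedure's structure but are not bit-exact
  with the original implementation.
- **corncob-like** — per feature, (count, library size) is fitted by
  maximum likelihood to a beta-binomial with logit(mu) = b0 + b1·group and
  a shared logit overdispersion, so only abundance (not variability)
  differences are tested. Optimisation is Nelder–Mead with up to 3 jittered
  restarts; the Wald SE comes from the observed information computed by
  central finite differences (forward differences proved too noisy to keep
  the Hessian positive definite near the optimum). Features observed in
  only one group get no p-value (flagged "untestable") and are excluded
  from BH's m, as the original tool reports nothing for them.
- **Rank-sum tests** use the exact null distribution when both groups have
  ≤ 12 samples and the feature has no ties, otherwise the normal
  approximation with continuity and tie correction — reproducible
  small-sample behaviour at a fixed cross-over.
- Significance is q ≤ alpha inclusive; all rankings break ties by feature
  ID so repeated runs are identical.

DESeq2-, edgeR-, limma-voom- and metagenomeSeq-style engines are
deliberately not implemented; the method-adapter contract (table in,
`DAResult` out) lets external engines join the evaluation machinery
unchanged.

## Evaluation machinery

**Consensus.** Per dataset, features significant under ≥ 1 workflow are
tallied by how many workflows call them; top-20 overlap repeats the tally
on each workflow's 20 best-ranked features (ascending raw p; descending W
for the ANCOM-like test, which has no p-values; descending score then
screen p for the LEfSe-like test). Inter-tool Jaccard distances on
significant sets are averaged across datasets with equal weight and
ordinated by classical metric MDS (double-centring + eigendecomposition).
Empty significant sets are common for conservative workflows, so the
convention is explicit: two empty sets are at distance 0, empty vs
non-empty at 1.

**False-discovery simulation.** The most frequent group's samples are
retained (compositional homogeneity), then repeatedly split into random
balanced case/control halves (odd sizes differ by one; balanced splits
maximise power to detect anti-conservatism, an unbalanced option exists)
and each workflow records its percentage of significant features. Replicate
budgets are configurable per method so expensive workflows can run fewer
replicates.

**Discrimination.** Per-feature AUROC is computed by the Mann–Whitney rank
identity — deterministic, tie-aware, and equivalent to empirical ROC
integration — on both TSS and CLR abundances of the non-rarefied table,
folded to max(AUC, 1−AUC) so depletion and enrichment score alike (without
folding, a feature depleted in cases could never pass a threshold; folding
is switchable). Tool summaries treat features with AUROC strictly above the
threshold (0.7 or 0.9) as true positives; metrics with zero denominators
are reported absent rather than 0.

**Cross-study consistency.** Features collapse to genus by summing counts
(labels unclassified or carrying "sensu stricto" are excluded; matching is
exact string after trimming and case-folding — fuzzy taxonomy harmonisation
is out of scope). Studies are restricted to their common genus set. For
each tool, the observed statistic is the mean number of studies in which
each genus (significant at least once, direction ignored) is significant.
The null redraws calls independently: genus g is called in study i with
probability n_sig_i / n_common — per-study probabilities, not pooled, so
the null preserves each study's call budget in expectation. Replicates with
zero calls carry no statistic and are excluded (counted). The fold
difference is observed over the null's mean; the one-tailed p uses the
add-one formula (1+k)/(1+N), whose minimum at N = 1000 is ~0.001.

## Synthetic data generator

The generator emulates the statistical structure of 16S case-control
tables without reproducing any tested method's parametric family (fitting
the generator to one tool's model would make that tool's success circular):
baseline relative abundances are lognormal (sd 3.0 — a few dominant taxa
and a long rare tail), per-sample depths lognormal (median 10,000, sd 0.55
on the log scale, about an order of magnitude spread), counts multinomial
given the per-sample composition, with independent extra zeroing
(probability 0.25) applied before renormalisation. Defaults yield overall
sparsity near 0.55 — the lower-middle of what real amplicon tables show —
chosen so that rank and t tests remain calibrated at the default sample
size; sparser presets (for the depth-confound artifact) push toward 0.8. A
Dirichlet-multinomial alternative sits behind a flag for sensitivity
checks.

Differential taxa are spiked multiplicatively in group B and the
composition renormalised, so unspiked taxa shift slightly — genuine
compositional coupling; the truth record stores only intentional spikes.
Spike eligibility is restricted to baseline relative abundance in
[5e-4, 0.01]: below that a taxon has no observable counts to carry a
signal, above it renormalisation swamps the rest of the community instead
of creating per-taxon effects. Multi-study collections share a core
fraction of differential genera, re-draw the remainder per study, jitter
per-study baselines (lognormal, sd 0.3), and attach a shared feature→genus
taxonomy with a small "unclassified" tail to exercise exclusion rules.

What the generator does **not** emulate: phylogenetic correlation between
taxa, batch/primer effects, taxonomy disagreement between studies, and
real overdispersion structure beyond lognormal-multinomial. Tests passing
on this generator therefore show internal correctness and the qualitative
behaviours above, not performance guarantees on any particular real
dataset.

## Numerical choices and degenerate inputs

- BH correction is a native step-up with NaN entries excluded from m and
  restored in place.
- Permutation p-values throughout use (1+k)/(1+N), never zero.
- All-tied features get p = 1 with an explanatory note; zero-variance
  Welch features are "untestable" (p = 1) when means agree.
- PERMANOVA R² = SS_between/SS_total from the squared Aitchison distance
  matrix; the pseudo-F agrees with scikit-bio's implementation to machine
  precision (cross-checked in the test suite).
- `depth_cv` uses the sample (n−1) standard deviation (configurable).
- Standardised rows of the percent-significant matrix use the (n−1) sd;
  constant rows standardise to all zeros.
- Dataset "read depth range" is max − min (a ratio would be the other
  defensible reading).
- Classical MDS keeps axes with eigenvalues above 1e-10 of the largest;
  negative eigenvalues (non-Euclidean mean Jaccard matrices) are reported
  in the spectrum but yield no coordinates.

## Problem sizes used in validation

The acceptance computations use: ~10,000 feature-tests (≈65–80 datasets of
200 filtered taxa, 50+50 samples) per calibration estimate; 100
relabelling replicates (10 for the Dirichlet-instance workflow, which is
two orders of magnitude more expensive — the same economy the original
benchmarking practice applies to slow tools); 5 synthetic communities for
spike recovery; 5 studies × ~196 common genera with 1000 permutation
replicates for cross-study consistency; 10,000 replicates for the
closed-form permutation-null check.

## Known limitations

- The LEfSe-like score and the ANCOM-like outlier-zero rule are documented
  stand-ins for under-specified originals; calls near their thresholds
  will not match the original tools feature-for-feature.
- The beta-binomial Wald test shares the original's small-sample
  anti-conservatism in highly skewed regimes (rho large relative to mu).
- Covariates, random effects, and longitudinal designs are out of scope:
  every contrast is two groups, nothing else.
- The false-discovery simulation rarefies the restricted table once per
  simulation (not per replicate); replicates differ only in labels.
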