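# Methods

This note records the statistical procedures implemented in `survscreen`,
the conventions chosen where a procedure admits more than one reading, what
the synthetic-cohort generator does and does not emulate, and the known
limitations. It documents the package's own choices; every empirical claim
here is computed by the test suite or by `scripts/acceptance.py`.

## Subgrouping

Each probe is scaled affinely so its observed minimum maps to 0 and its
maximum to 1 (missing values excluded and preserved). Low and high
expressers are the closed intervals [0, 0.3] and [0.7, 1] of the *scaled
range* — boundary values inclusive on both sides. The cut is deliberately
range-based, not rank-based: group sizes are unequal whenever the
expression distribution is skewed, and membership is not invariant under
monotone transforms of the input (a property test constructs the
counter-example). A rank-based scaler (`rank_scale_probe`) is provided for
sensitivity analysis only. Probes with zero range are "degenerate" and
probes whose subgroups fall below `min_group` (default 10 — survival tests
on smaller groups are uninformative) are "underpowered"; both are excluded
from candidate lists but still reported row-by-row so no probe is silently
dropped. Scaling operates on the log2 matrix as provided.

## Survival statistics

* **Kaplan–Meier**: product-limit estimator with deaths processed before
  censorings tied at the same time. The median is the smallest observed
  event time with S(t) ≤ 0.5 and is reported as undefined — never as a
  number — when S never reaches 0.5.
* **Log-rank**: one-degree-of-freedom χ² aggregating observed-minus-expected
  events over the pooled distinct event times, hypergeometric variance,
  two-sided p from χ²(1).
* **Gehan–Wilcoxon**: the same statistic with each event time weighted by
  the pooled number at risk; emphasizes early events and is the
  censoring-aware analogue of the rank-sum comparison.
* **Wilcoxon rank-sum**: exact p by enumeration when n_A + n_B ≤ 12 with no
  ties; otherwise the normal approximation with tie-corrected variance and
  continuity correction (mid-ranks for ties). Computed via
  `scipy.stats.mannwhitneyu` with the method chosen by that rule; the test
  suite checks it against a full enumeration oracle.

The screen's default p-value is the rank-sum test applied to observed
follow-up times with censoring flags ignored, matching how such screens are
commonly run; this is a biased use of the test under differential censoring,
which is why the log-rank and Gehan tests are selectable by one flag and the
log-rank p is always printed alongside in per-biomarker reports.

## Covariate balancing

Every covariate level is tested one-vs-rest in a 2×2 Fisher exact test of
level × group membership (two-sided, point-probability rule). Binary yes/no
covariates contribute one test instead of two mirror-image tables. Age, the
only continuous covariate, is dichotomized at the pooled median; missing
categorical labels form their own "unknown" level rather than being imputed.

The rebalancing loop is greedy and fully seeded: at each iteration the most
significant level is identified; from the group where it is over-represented
one random carrier is removed — or, with probability 0.5 when
previously-removed non-carriers exist on the under-represented side, one of
them is re-admitted. Iteration stops when no level has p < α (default 0.05)
or after `max_iter` (default 1000) iterations, in which case the best groups
found are returned with `converged=False` rather than an exception. Patients
never enter a group they did not originally belong to, and removed patients
are excluded from all downstream stages. The report carries the full audit
trail, both scans, and the seed, so a run is reproducible byte-for-byte.
Equal final group sizes are not enforced. The simplest move set consistent
with "shuffle until nothing is significant" was chosen deliberately;
propensity or optimal matching is out of scope.

## Differential expression

Quantile normalization forces every column onto the cross-column rank-mean
distribution (ties receive the mean of the spanned reference values;
missing cells are filled by the column mean for ranking and restored). It
is idempotent and equalizes column means to machine precision.

The moderated t-statistic shrinks each probe's pooled variance s² (df =
n_L + n_H − 2) toward a prior: s̃² = (d₀s₀² + df·s²)/(d₀ + df), with
two-sided p from a t distribution on d₀ + df degrees of freedom (treated as
normal beyond 10⁶ df for numerical stability). The hyperparameters follow
from the scaled-F model for sample variances: with
e = log s² − ψ(df/2) + log(df/2), the model implies
Var(e) = ψ′(df/2) + ψ′(d₀/2), so d₀ is obtained by Newton inversion of the
trigamma function on the excess spread, and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the observed spread does
not exceed the χ² sampling spread, d₀ = ∞ (full shrinkage to s₀²); with
fewer than 30 probes the estimator falls back to d₀ = 0 (classical pooled
t) with a warning. d₀ = 0 reproduces the classical two-sample t exactly
(oracle-tested to 1e−12); hyperparameter recovery on simulated variances
(d₀ = 4, s₀² = 0.05, 20000 probes) is within 15%.

Differential genes satisfy |log₂FC| > 1 and BH-adjusted p < 0.05, split by
sign; the fold-change sign convention is high minus low, so positive means
elevated in high expressers. The ±1.5 volcano variant is the same rule with
`fc_cut=1.5`.

## Clustering and GSEA

Patients are clustered on d = 1 − Pearson r between their expression
profiles over the differential genes, complete linkage ("Pearson
correlation / Euclidean distance" is ambiguous; 1 − r is the default and
Euclidean-on-correlation-rows is available as `distance='euclidean-corr'`,
with the choice recorded in output metadata). Genes are clustered on
Euclidean distance between z-scored profiles. Dendrograms serialize to
Newick with merge heights as branch lengths, plus an explicit leaf order
for heatmap reproduction; heatmap export is data-only.

GSEA ranks genes by signal-to-noise, (x̄_H − x̄_L)/(σ_H + σ_L) with each σ
floored at max(0.2·|x̄|, 0.2), and computes the weighted Kolmogorov–Smirnov
running sum with weight exponent 1: hits add |score|/Σ_set|score|, misses
subtract 1/(N − N_hit); the enrichment score is the signed maximal
deviation and the leading edge contains the hits at or before it.
Significance comes from phenotype-label permutation with a fixed seed:
p = (1 + #{|ES_perm| ≥ |ES_obs|})/(1 + n_perm), NES = ES_obs divided by the
mean |ES_perm| of like sign. Permutation p-values are therefore floored at
1/(n_perm + 1). FDR across many gene sets is out of scope.

## Synthetic cohorts

Each patient carries a latent disease-state level z ~ Uniform(0, 1).
Defaults: 200 patients, 2000 probes; baseline intensities μ_g ~ N(7, 1)
log2 units with Gaussian noise sd 0.7; the biomarker probe adds 3.0·z;
overall survival is exponential with hazard 0.02·exp(1.1·z) per month
(optional Weibull shape), censoring exponential at 0.01/month (≈ 25–30%
censored); event-free survival shares z with its own noise and a 1.3×
baseline hazard; binary confounders have prevalence base + slope·z
(NPM1c-like 0.15 + 0.30·z, CEBPA-like 0.12 − 0.12·z, clipped to [0, 1]);
a survival-neutral FAB-like factor is uniform over 5 levels; age and sex
are survival-neutral.

The 30-gene module is linear in z, and its effect size `module_log2fc`
(default 2.0) is parameterized directly as the planted expression contrast
between the biomarker's realized high and low subgroups: the slope on z is
calibrated at generation time to module_log2fc/(z̄_high − z̄_low). This
makes "estimated log2 FC ≈ 2.0" an exact, testable statement about what the
differential-expression stage measures, rather than an attenuated function
of the subgroup geometry.

Randomness uses independent named SeedSequence child streams (latent,
baseline, noise, survival, covariates), so each component is individually
reproducible and, e.g., the clinical realization is identical for cohorts
that differ only in probe count.

What the generator does **not** emulate — and hence what passing tests do
not show about real data:

* Array technical structure: probe-level noise models, batch and scanner
  effects, background correction. Quantile normalization is consequently a
  near no-op on synthetic columns, and recovery analyses run on the
  generated matrix directly; on real cohort matrices normalization matters.
  Note also that quantile normalization compresses a planted contrast that
  touches a non-trivial fraction of probes (30/300 in the small test
  cohort), a known caveat of the method when many genes are truly
  differential.
* Heterogeneous fold changes within the module: all module genes share one
  slope on z, so the between-group difference is a per-patient constant
  offset across the module — exactly the component that correlation
  distance removes. Patient correlation clustering therefore cannot
  separate the subgroups on cohort data by construction, and its recovery
  tests use constructed gene-specific signatures instead.
* Dependence between covariates, non-proportional hazards, informative
  censoring, and probe-to-gene many-to-one mapping.

Detection power at the defaults is modest by design of the stated
parameters: the between-subgroup hazard ratio is exp(1.1·Δz̄) ≈ 2.1 with
groups of ~30–40, so the biomarker's rank-sum p is typically 0.01–0.05 —
reliably significant, but not expected to rank first among ~1800 null
probes, whose minimum p is ~5·10⁻⁴. The acceptance suite asserts the
stronger rank-one property and documents its failure rather than tuning
the generator toward it.

## Numerical conventions

* Fisher exact p-values use the point-probability rule (sum of
  hypergeometric probabilities ≤ the observed table's); a zero margin is
  degenerate and returns p = 1.
* BH adjustment is the standard step-up with monotonicity enforcement and
  cap at 1, order-preserving.
* Rank-sum degenerate case (all pooled values identical) returns p = 1
  with a flag; log-rank with no events in either group likewise.
* A zero posterior variance with a non-zero mean difference yields p = 0
  with a degenerate flag (constant probe differing between groups).
* Pipeline stage seeds derive from the run seed by fixed offsets, so stages
  are individually reproducible yet use independent randomness.

## Problem sizes

The default test and acceptance workloads were sized to exercise every
stage at cohort scale while staying quick on one CPU: the full recovery
analysis uses the default 200 × 2000 cohort with 1000 GSEA permutations
(~15 s), screen calibration uses 1000 probes × 500 patients, test-level
calibration uses 2000 null replicates of n = 50 + 50, and moderation
recovery uses 20000 simulated variances.
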