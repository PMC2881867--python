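# Methods

## The stemness similarity score

For an expression matrix X (probes × samples, non-negative linear-scale
intensities such as MAS5 output) and a designated set R of reference
stem-cell samples, the reference profile is the per-probe arithmetic mean
x̄_ref = mean_{j∈R}(x_j). The stemness score of sample i is the Pearson
correlation r_i = corr(x_i, x̄_ref) computed over all probes present in
both vectors. Probes with a missing value on either side are excluded
pairwise per sample, and the number of probes actually used is reported
next to every coefficient; fewer than 3 usable probes, or a zero-variance
vector on either side, is an error rather than a silent NaN.

Scores can be computed on values as provided (`transform="linear"`) or on
`log2(x + 1)` (`transform="log2"`). The linear mode reproduces how
spreadsheet-era tools correlated MAS5-scale values and is the default; the
log mode is what most current practitioners expect, since linear-scale
Pearson is dominated by the brightest probes. Which mode ran is recorded
in the score table's metadata, and both are exposed everywhere a
correlation is computed (scoring, pairwise similarity, PCA input). When
the transform is applied, it is applied to both the sample vector and the
(already averaged) reference profile; the profile is not re-averaged on
the log scale.

## Stratification and subgrouping

`median_split` assigns samples with score ≤ median to "low" and the rest
to "high"; ties at the median deterministically break toward "low" (the
direction is arbitrary; determinism is the point).

`stratify_by_score` sorts ascending by score (stable sort, so input order
breaks ties) and fills groups front-to-back: with n samples and k groups,
the first k−1 groups take ⌈n/k⌉ samples and the final, most stem-like
group absorbs the remainder, possibly smaller — 200/10 → ten groups of 20,
23/5 → (5, 5, 5, 5, 3) with the smallest group most stem-like. When
front-loading ⌈n/k⌉-sized groups would leave the last group empty
(possible only for k close to n), sizes fall back to the balanced
partition with the larger groups first.

## Compartmentalized heterogeneity

Within each stratum, every sample pair is correlated twice: over all
transcripts and over a named gene universe (typically a curated
progenitor/differentiation list). Summaries use the upper-triangle
off-diagonal coefficients only (each pair once, diagonal uninformative);
per cell the mean, SEM = sd/√n_pairs with n_pairs = k(k−1)/2, and the
coefficient list itself are reported. A zero-variance sample within a
universe yields NaN for its pairs; those pairs are flagged, logged and
dropped from summaries.

Two universe-effect tests are computed:

1. **Coefficient-level one-way ANOVA** (per stratum and pooled across
   strata), treating pairwise coefficients as independent observations.
   This is the convention in the literature this analysis follows, and it
   is reported for comparability — always accompanied by the caveat that
   coefficients sharing a sample are dependent. Degenerate inputs are
   defined exactly: identical group means give F = 0, p = 1; distinct
   means with zero within-group variance give F = ∞, p = 0.
2. **Probe-resampling permutation test** (`universe_permutation_test`).
   The statistic is the pooled mean subset-universe coefficient minus the
   pooled all-transcript mean (averaged over strata); its null
   distribution comes from random probe subsets of the same size, and
   p = (1 + #{|null| ≥ |observed|})/(n_resamples + 1) with 199 resamples
   by default.

The second test exists because the first is anticonservative *by
construction*, independent of sample size: any finite gene universe
carries a shared sampling offset — the realized baseline variance and
loading composition of its probes differ from the full array's — which
shifts all of its pairwise coefficients coherently. The coefficient-level
ANOVA, whose standard error shrinks with the number of pairs, reads that
offset as a universe effect; in simulation it rejects a true null far in
excess of its nominal level, and aggregating to per-stratum means does not
fix it. The permutation test is calibrated against exactly the right null
("does this gene set behave like a random set of equally-variable
probes?") and retains good power against planted variance inflation. Both
numbers appear in reports; conclusions about compartmentalized
heterogeneity should rest on the permutation p-value and on the direction
and size of the mean difference.

A Fisher-z option (arctanh before averaging and testing) is available and
off by default; raw coefficients match the published convention.

## Differential expression filter

`altered_gene_list` computes, per probe, the linear-scale fold change
mean(B)/mean(A) and a p-value on log2(x + 1) values from a Welch t-test
(default), a paired t-test on within-pair differences, or one-way ANOVA
(equivalent to an equal-variance t for two groups). "One-tailed" means the
tail chosen by the observed fold-change direction, i.e. half the
two-sided p. A probe passes when max(FC, 1/FC) exceeds the fold-change
threshold AND p is below the p threshold. Defaults follow the historical
analysis (FC > 1.3, p < 0.05; FC > 1.5 for the murine host comparison).
No multiple-testing correction is applied by default — fidelity to the
raw-p filtering convention — but a Benjamini–Hochberg mode is provided,
and the result always records which mode ran. Zero-variance,
zero-difference probes get p = 1 (no evidence) rather than NaN.

## PCA co-clustering and trendlines

`pca_embed` restricts the matrix to a gene list, transposes to samples ×
probes, centers each probe, and takes the top principal components (full
SVD; no unit-variance scaling by default, preserving magnitude structure;
a scaling flag exists). Per-component sign is fixed by making the
largest-magnitude probe loading positive, so output is deterministic.
Co-clustering is quantified as the mean silhouette width in component
space — a numeric operationalization of the visual "do these samples
cluster together" reading, and labeled as such in reports; singleton
labels are excluded with a warning.

`fit_exponential_trend` fits y = a·exp(b·x) by OLS on (x, ln y) — the
spreadsheet trendline convention, not nonlinear least squares — and
reports r_fit = Pearson(x, ln y). Note that for y identical to x this
r_fit is slightly below 1 (ln is concave); on realistic score ranges the
self-relation exceeds 0.995. Constant y returns (a = y, b = 0, r_fit = 0);
non-positive y and constant x are errors. `relatedness_analysis` aligns
two score tables by sample ID and fits the trend overall or per
median-split subgroup of the x-axis scores.

## Assay formulas

Percent specific lysis: 100·((mix − splenocyte_control) −
negative_control)/(positive_control − negative_control). Values below 0%
or above 100% are flagged, never clipped — out-of-range lysis is evidence
of an assay problem worth preserving. Amplification efficiency from a
standard curve: the least-squares slope of Ct against log10(relative
input) gives E = 10^(−1/slope) (E = 2 is perfect doubling; a non-negative
slope is rejected). Relative expression: E^(−(Ct_target − Ct_reference)),
normalized against a single simultaneously amplified reference gene
(GAPDH-style); a multi-reference geometric-mean generalization is easy to
layer on top but the single-reference form is what the package computes.

## Synthetic cohort generator

Log2-scale generative model, exponentiated to linear output via 2^x:

    x_gi = b_g + l_g · s_i + ε_gi

- probe baseline b_g ~ N(baseline_mean = 7, baseline_sd = 1.5);
- a fraction (default 0.4) of probes carry a stemness loading
  l_g ~ N(0, signal_sd = 1.0), the rest l_g = 0;
- latent stemness s_i ~ Uniform(0, 1) for tumor samples; the designated
  reference samples are pinned at s = 1 (continuous rather than bimodal
  stemness supports both stratified and correlation-style analyses with
  one generator);
- noise ε_gi ~ N(0, noise_sd · m_gi) with noise_sd = 0.5 (signal-to-noise
  2) and multiplier m_gi = inflation_factor for subset probes in
  designated low-stemness samples, 1 otherwise. The subset (default 200 of
  2000 probes, named "progenitor_differentiation") is drawn uniformly;
  the inflated samples are the lowest-stemness `inflated_quantile`
  (default 0.4) of tumor samples, mirroring compartmentalized
  heterogeneity concentrated in the least stem-like tumors.

The paired generator shares b_g and a per-pair random effect
u_gk ~ N(0, pair_sd = 0.5) between the pre and post member of each pair,
and adds effect_log2fc (default 1, i.e. 2-fold) to n_altered designated
probes in the post samples. With zero noise the planted linear-scale ratio
is exactly 2^effect_log2fc.

Noise magnitudes are calibration choices, not measured values: baseline
and noise sds were set once to give MAS5-like intensity ranges and
reference-sample scores near 0.95, and are documented here rather than
revisited. All draws flow from a single integer seed through named
`SeedSequence` sub-streams (PCG64), so output is bit-identical across
platforms and adding probes does not perturb the sample-level draws.

What the generator does **not** emulate: probe-level array artifacts
(PM/MM, saturation), batch and scanner effects, correlated gene modules
beyond the single latent axis, non-Gaussian heavy tails, and sample
quality variation. Passing tests therefore demonstrate that the
implementation recovers planted structure under idealized conditions —
they do not certify performance on real arrays, where the score's
behavior additionally depends on normalization quality and cohort
composition.

## Pipeline

`run_pipeline` executes simulate → score → discriminate → diffexpr → pca →
trend → heterogeneity from one validated config (YAML-loadable; validation
is explicit field-by-field Python with named-field errors, which keeps the
dependency footprint minimal while matching what a schema would check).
Requesting a subset of stages pulls in prerequisites automatically. Each
stage writes its tables to the output directory; the run report (JSON)
echoes the config, library versions and per-stage summaries, and identical
config + seed reproduces it bit-for-bit apart from the timestamp. A stage
failure aborts with the stage name and leaves a FAILED marker beside the
partial outputs. The diffexpr/pca stages run on a 6-pair paired cohort
generated alongside the main cohort; the trend stage scores the cohort
against a surrogate "post-treatment" profile averaged from the
highest-scoring non-reference samples.

## Verification scale

The test suite and `scripts/acceptance.py` exercise the pipeline at sizes
chosen to keep a full run fast on one CPU while preserving the study's
structure: oracle equivalence on 1,000 random small matrices; latent-axis
recovery on 50 cohorts of 5,000 probes × 60 samples; discrimination on 50
cohorts at the default 2,000 × 60; heterogeneity detection and null
calibration on 100 cohorts each of 1,000 probes × 50 samples (5 strata of
10); DE null calibration on 100 six-pair cohorts of 2,000 probes and
sensitivity on 25 cohorts of 5,000 probes with 100 planted 2-fold shifts.

## Known limitations

- The Pearson score inherits linear-scale sensitivity to bright probes;
  use the log2 transform unless reproducing legacy numbers.
- The coefficient-level ANOVA's miscalibration (above) means published
  asterisks based on it overstate certainty; the permutation test is the
  defensible inference route.
- Pairwise coefficients within a stratum share samples; no mixed-effects
  correction is attempted (out of scope), only the caveat and the
  permutation alternative.
- The stratification policy is one convention among several; group sizes
  other than the remainder-last rule are not offered.
- CLI and pipeline operate on whole matrices in memory; arrays beyond a
  few hundred thousand probes × thousands of samples would need chunking
  that is not implemented.
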