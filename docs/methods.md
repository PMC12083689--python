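# Methods

This note records the statistical models, defaults and numerical choices
behind `sirisurv`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic cohorts

The generator emulates the statistical structure of a radiotherapy-treated
head-and-neck cancer cohort; it does not attempt to reproduce any real
cohort's joint distribution.

**SIRI.** Log-normal. The default location is ln(1.34) and the default
scale 0.676 is obtained by matching the two reported quantiles of the
reference cohort: sigma = ln(2.19/0.88) / (2 · z₀.₇₅). A two-parameter
fit to a median and an IQR is the natural choice for a right-skewed,
positive biomarker. A second constant, `SIRI_LOG_SD_WIDE` ≈ 1.14, widens
the scale so that ~20% of subjects lie above SIRI = 3.5; it is used in all
planted-cutoff recovery and discrimination studies, because a cutoff in
the far tail of the covariate would be excluded by the pipeline's own 10%
minor-group rule no matter how well the forest localized it — the planted
truth must be admissible for recovery to be a meaningful target.

**Covariates.** KPS is categorical over {100, 80–90, ≤70} with default
frequencies (0.27, 0.64, 0.09); smoking over {never, former, current}
with (0.31, 0.54, 0.15); age is normal(61, 9.6) (matching a median of 61
and IQR 54–67); BMI is normal(28.5, 5.5), chosen so the WHO strata land
near the reported 2/22/39/35% split. Draws outside physiological ranges
are clipped (BMI ≥ 13, age in [18, 95]).

**Survival.** Exponential proportional hazards: subject rate =
`baseline_rate` · exp(Σ active log-hazard increments), with *step*
(threshold) effects — e.g. "SIRI ≥ 3.5 adds ln 2.5" — rather than linear
effects, because the pipeline's deliverable is cutoff recovery and the
ground truth must therefore be a cutoff. Censoring is the minimum of an
exponential loss-to-follow-up time (default rate 0.012/month) and an
administrative horizon (default 120 months), reproducing both
loss-to-follow-up and study-end censoring; with the default baseline rate
of 0.01/month this yields roughly 45% events and a median follow-up in the
low tens of months. The censoring process of the clinical setting being
emulated is unknown; this model is a stand-in, not an inference about it.

**Financial toxicity.** FT levels 0–3 are drawn with default probabilities
(0.40, 0.30, 0.18, 0.12) — roughly 30% FT-High, consistent with the high
prevalence of financial hardship reported in head-and-neck cancer — and
log2(SIRI) is re-centred by `shift_per_level · (level − E[level])`, so a
positive shift produces a monotone location trend without moving the
cohort-level SIRI distribution. The default shift of 0.3 per level gives
an FT-Low vs FT-High contrast of ≈ −0.59 on log2(SIRI), the same order as
the association the analysis is designed to detect.

**Seeding.** One master seed is expanded into named substreams
(`covariates`, `survival`, `ft`, `split`, `forest`, `vimp`) via
`SeedSequence` spawn keys derived from CRC32 of the label, so re-running
or adding one stage never perturbs another, and identical configs
reproduce cohorts bit-for-bit.

## Survival forest

scikit-survival's `RandomSurvivalForest` provides the ensemble: bootstrap
resampling, log-rank splitting (the conventional default for survival
forests), Nelson–Aalen cumulative-hazard estimates in the leaves.
Defaults: 1000 trees, ⌈√p⌉ candidate variables per split, minimum
terminal node size 15. Candidate thresholds at a node are the midpoints of
sorted unique in-node values, scanned exhaustively. Ordered clinical
categories are encoded ordinally (KPS ≤70/80–90/100 → 70/85/100; smoking
never/former/current → 0/1/2).

**Mortality score.** A subject's score is the mean over trees of the
tree's cumulative hazard summed over that tree's event-time grid — the
expected number of events under the ensemble. The ensemble score is
exactly the mean of the per-tree scores (asserted in the tests).

**Out-of-bag machinery.** In-bag multiplicities are reconstructed from
each tree's recorded random state, so OOB membership is exact and
reproducible. The OOB score of a subject averages the per-tree scores over
trees not containing it; permutation VIMP is the mean drop in OOB C-index
over shuffles of one covariate column (default 5 repeats).

**Discrimination.** The C-index is computed by a direct pairwise sum:
evaluable pairs are those orderable under censoring (strictly shorter time
with an event), score ties count ½. Tied times are not evaluable. The
time-dependent AUC is Uno's IPCW cumulative/dynamic estimator, with
weights 1/Ĝ(Tᵢ) from the Kaplan–Meier censoring distribution; both match
their scikit-survival counterparts to machine precision on untied data
and are validated against brute-force oracles in the tests.

## Cutoff distillation

Each internal node of a survival tree chooses the split maximizing the
log-rank statistic *conditional on the partition already built*, so
across a large ensemble the thresholds chosen for a genuinely prognostic
variable concentrate near its optimal cutpoints. The distillation
pipeline:

1. extract every (threshold, node size) pair for the variable;
2. Gaussian-kernel densities of thresholds and of training values, each
   with Silverman's rule on its own sample, evaluated on one shared
   512-point grid spanning the pooled range padded by three bandwidths
   (so each curve integrates to ≈ 1);
3. difference of the two normalized densities — equal-mass comparison
   makes the difference interpretable as over-representation of split
   locations relative to the data;
4. interior local maxima with strictly positive difference (plateaus
   report their midpoint) become candidates;
5. candidates whose induced partition of the training values leaves any
   cell under `min_group_proportion` (default 10%) are removed weakest
   first (smallest difference height), re-checking after each removal —
   the order is a design choice that preserves the strongest evidence.

Splits are counted once each, unweighted, by default; node-size weighting
is available (`weight_by_node_size=True`). Whether to weight, and how to
scale the two densities before subtraction, are genuinely open choices;
both are exposed as options rather than asserted.

Under the recovery conditions (n = 600, HR 2.5 across SIRI = 3.5,
300 trees), the distilled cutoff lands within ±0.5 of the truth in ≥ 80%
of seeds with mean bias within ±0.25 (asserted in the acceptance suite; a
weaker spurious maximum near the distribution mode frequently accompanies
it and is handled downstream by the tree).

## Risk tree and groups

Continuous variables are discretized at the distilled cutoffs
(left-closed: a value equal to a cutoff goes up). The tree is grown
greedily: at each node, for every variable, all binary partitions of its
present categories (2^(k−1) − 1 subsets, exhaustive since clinical
cardinalities are ≤ 6) are scored by the two-sample log-rank chi-square;
the best admissible split (both children ≥ `min_node_size`, default 40)
is taken, to depth ≤ 3. Leaves are ordered by mean forest mortality
score; the adjacent pair with the largest pairwise log-rank p is merged
while p > α (default 0.05), or until a requested group count remains.
In clinical practice, groups whose survival curves visibly cluster are
merged by judgment; the α-threshold rule makes that judgment explicit and
reproducible. Group indices are 1-based, increasing in risk, and group mean
mortality is strictly increasing by construction.

The 75th-percentile high-risk stratification uses the linear-interpolation
empirical quantile of the *training* scores; a subject is high-risk iff
its score strictly exceeds that cutoff.

## Validation statistics

Kaplan–Meier estimation, the k-group log-rank test (chi-square, k−1 df,
hypergeometric variance) and univariable Cox fits are delegated to
lifelines; Cox uses Efron's tie correction (better than Breslow under the
heavy ties of month-resolution times) with Wald 95% CIs and two-sided
p-values. Pairwise group comparisons run as separate two-group tests and
feed Holm's step-down procedure (statsmodels). All p-values are
two-sided at α = 0.05 unless stated.

## Financial-toxicity association

The Jonckheere–Terpstra statistic is J = Σ_{i<j} #{(u,v) : u ∈ group i,
v ∈ group j, x_u < x_v} + ½·ties. Three p-value methods:

- **normal** (default): tie-corrected normal approximation (mean
  (N² − Σnᵢ²)/4 and the standard three-term tie-corrected variance), no
  continuity correction;
- **exact** (untied data): the null distribution of J is the convolution
  of Mann–Whitney null distributions of each group against the pool of
  preceding groups (independent under H0); each Mann–Whitney count
  distribution comes from the classical recurrence
  N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1);
- **permutation**: label shuffles with add-one correction.

For two groups, J reduces exactly to the Mann–Whitney U of the second
group versus the first. The default alternative for the FT→SIRI direction
is *increasing*; the pipeline reports the two-sided version, since the
sidedness of reported trend p-values of this kind is typically not
stated.

The regression models log2(SIRI) by OLS with treatment-coded categorical
terms against declared reference levels (FT-High, age ≤ 60, never-smoker
in the pipeline), classical standard errors and t-based 95% CIs. Rank
deficiency is detected before fitting and reported as an error.

## Numerical and design notes

- Ties in forest scores: broken by strict `>` where a binary decision is
  needed (high-risk labels); counted ½ in rank statistics.
- `estimate_density` requires ≥ 2 distinct values; degenerate inputs
  raise rather than return a spike.
- When every extracted split threshold is identical (a two-valued
  covariate), that single threshold is returned directly — a density
  comparison is unnecessary and undefined.
- The log-rank splitter breaks exact ties in the chi-square by first
  encounter in (variable order, subset enumeration order), making tree
  growth deterministic.
- A zero baseline hazard is allowed in the generator (everyone censored
  at the horizon); it is rejected for model fitting, which requires
  events.
- Problem sizes in the test and acceptance suites (cohorts of 250–2000,
  forests of 60–300 trees, 20-seed replications, 2000-replicate
  calibration loops) are the package's chosen simulation scale: large
  enough for the stated statistical bands, small enough to re-run
  routinely.

## What the synthetic experiments do not show

The generator draws covariates independently of each other, uses
exponential (constant-hazard) event times, and plants clean step effects.
Real cohorts have correlated covariates (e.g. smoking and site),
non-monotone hazards, measurement error in CBC counts, and cutoff
structure that is at best approximate. Passing the recovery and
calibration suites therefore demonstrates that the implementation is
correct and well-calibrated under its stated model — not that the
distilled cutoffs or risk groups would replicate in any particular
clinical population. Cohort-specific clinical results (discrimination
indices, external-cohort hazard ratios, baseline-table and
regression-table values) depend on private patient data and are outside
what desk-scale synthetic experiments can or should reproduce.
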