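# Methods

This note documents the statistical model behind `mnemoscreen`, the
parameter defaults and why they were chosen, what the synthetic data do and
do not emulate, and the numerical conventions.  Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

One row per ER visit.  Symptom indicators are tri-state: charts written
under emergency conditions rarely enumerate absent symptoms, so "not
mentioned" is recorded as *unrecorded*, distinct from *absent*.  The
outcome (provisional diagnosis: ACS vs non-ACS) is never missing and never
imputed; rows without it are rejected at read time.  `referred_pain` is a
single indicator pooling neck, shoulder and jaw pain.  An optional
discharge ("definite") diagnosis column is read and carried but not
analyzed.  Rows are treated as independent visits; repeat visits by one
patient are not linked.

CSV encoding is `1`/`0`/`NA` (empty ≡ `NA`), configurable through a
column→role schema, so that spreadsheets produced by chart review load
directly.  Read∘write is the identity on all three states.

## The diagnostic battery

Every predictor is reduced to its 2×2 table on its own complete-case
subset — the varying per-symptom denominators (chest pain n = 2,995 but
dizziness n = 497 of 3,400) are a feature of the charts, not an error, and
each statistic honestly reports the n it used.

Confidence intervals (α = 0.05 throughout):

* proportions (Se, Sp, PPV, NPV): **Wilson score** by default,
  Clopper–Pearson selectable.  Wilson has near-nominal coverage without
  the conservatism of the exact interval; a seeded simulation in the test
  suite confirms ≥ 90% empirical coverage at n = 2,000.
* likelihood ratios: **Simel log method**
  (e.g. Var log LR+ = 1/a − 1/(a+c) + 1/b − 1/(b+d)).
* odds ratio: **Woolf log method**; the point estimate is the
  cross-product ad/bc, identical (verified to 1e−9 relative on random
  tables) to the logistic-regression MLE for a single binary predictor.

Zero cells: the Haldane–Anscombe +0.5 is added to all four cells for the
ratio statistics only, and the result's `method` label is flagged.
Non-degenerate tables are never touched.  Display rounding is 2 dp;
internal computation is full precision.

The sample-size operation implements the infinite-population proportion
formula n₀ = ⌈z²p(1−p)/d²⌉ with two inflation steps,
n = ⌈⌈n₀/prevalence⌉/(1−dropout)⌉: only a fraction *prevalence* of
screened visits carry the condition, and *dropout* of records are
unusable.  With p = 0.5, d = 0.05, α = 0.05, prevalence 0.274 and 30%
dropout this gives 385 → 2,009 chart reviews.

## Composite rules and missingness

A rule is positive iff the anchor is present **and** at least one
secondary is present.  Under missing data the default *witness* semantics
are: positive on any recorded witness; negative if the anchor is absent,
or present with every secondary recorded absent; otherwise unrecorded.
This maximizes use of partially charted visits without fabricating
negatives.  A *strict* mode (all component symptoms must be recorded) is
available for sensitivity analysis, since retrospective reports rarely
state which convention their composite denominators used; the pipeline
summary always records which mode ran.

Candidate selection uses the strict inequality OR > threshold on the point
estimate (CI-based selection is available but off by default).  Ranking
sorts by OR, then sensitivity, then fewer secondaries, then label — fully
deterministic — after excluding rules with specificity below a floor.  The
floor defaults to 0.5: a screening rule that sends more than half of
non-cases to the ER is an undue burden, while 0.5 still admits composite
rules with specificities in the 0.6–0.75 range and excludes the bare
anchor (specificity ≈ 0.41).  Subset enumeration defaults to sizes
|candidates|−1 .. |candidates|; an explicit rule list can pin any set of
composites.

## Multiple imputation

Unrecorded symptom states are multiply imputed (m = 5 by default; the
choice is conventional, and between-imputation variance enters pooling
explicitly so m matters little beyond Monte-Carlo noise).  The default
imputer is **bootstrap-EM on a latent multivariate-normal working model**
over the binary indicators (symptoms + outcome + fully observed binary
covariates): for each completion the rows are resampled with replacement,
(μ, Σ) are estimated by EM on the resample, each missing cell gets its
conditional mean given the row's observed cells, and the imputed state is
drawn Bernoulli from that predicted probability truncated to [0, 1].

Two deliberate choices here:

* The Bernoulli draw uses the truncated conditional **mean**, not a noisy
  latent draw.  Adding the latent normal residual (sd ≈ 0.45 for a binary
  indicator) before truncating pulls class-conditional probabilities
  toward 0.5 and attenuates odds ratios; the predicted-probability variant
  recovers complete-data ORs without bias in the MCAR parameter-recovery
  suite.  Parameter uncertainty (properness) comes from the bootstrap-EM
  step, and the Bernoulli draw supplies the correct binary residual
  variance.
* The outcome is always a predictor in the imputation model, so
  class-conditional symptom structure survives completion.  Imputing
  symptoms from a model that ignores the outcome is a known cause of sharp
  OR attenuation in imputed datasets.

A chained-logistic fallback (`logistic_cc`) with approximate posterior
coefficient draws is provided.  Recorded cells are never altered (checked
cell-wise in the tests); a symptom unrecorded in every row is excluded
from the model with a warning.

Pooling follows Rubin's rules on the statistic's transformed scale (log
for OR/LRs, logit for proportions): pooled point = back-transformed mean,
total variance = within + (1 + 1/m)·between, CI via Barnard–Rubin degrees
of freedom.  Degenerate per-completion estimates are continuity-adjusted
(+0.5) before transforming and flagged.  A *stacked* alternative
(concatenate the m completions and profile once) is exposed for
sensitivity analysis; its CIs are anti-conservative and it is not the
default.

## Bootstrap validation and stratified analysis

Internal validation draws B = 1,000 (default) resamples of rows with
replacement, resample size = cohort size, recomputing the rule profile on
each resample's evaluable subset; reported per statistic: original point,
replicate mean and median, 2.5/97.5 percentile interval, and bias
(mean − original).  Both mean and median are reported because percentile
summaries of ratio statistics are asymmetric.  Resamples with an empty
outcome margin are redrawn and counted; outcome-stratified resampling is
available.  Everything is deterministic under a fixed seed.  Note that for
a ratio statistic the replicate mean exceeds the original by a
second-order (Jensen) term of order OR·Var(log OR)/2 even for a perfect
implementation; bias should be judged on the log scale, which is how the
test suite asserts it.

Stratified analysis recomputes the complete-case profile per level of a
covariate; levels with an empty outcome margin are reported as
not-estimable, never silently dropped.  Two strata are compared two ways,
both always reported, since "no significant subgroup difference" claims in
this literature rarely name their procedure: (i) overlap of the two 95%
CIs, and (ii) a Wald z-test on the difference of transformed estimates
with independent-stratum SEs.  The comparison is symmetric up to sign.

## Synthetic cohorts

The generator's defaults are the reference study conditions: n = 3,400,
prevalence 415/3,400 = 12.2%, class-conditional presence probabilities
and per-symptom recording rates taken from the published per-symptom
tables (e.g. chest pain present with probability 367/401 given ACS,
1,539/2,594 given non-ACS, recorded for 2,995/3,400 visits), and
class-conditional covariate distributions from the published baseline
table.  Recording is MCAR by default; a MAR-on-outcome option inflates
recording odds for ACS visits (physicians chart more in sicker patients)
while preserving the marginal rate, to stress-test the imputer.

Symptoms are conditionally independent given the outcome by default,
because only marginal tables are published.  An optional Gaussian copula
induces joint dependence for experiments, but any correlation used is a
modeling device: composite-rule performance depends on the unknown joint
structure, so the generator cannot — and does not try to — reproduce the
published composite ORs.  The same caveat applies to the deterministic
reference fixture (`make_reference_cohort`), which fills each symptom's
quota independently within outcome class: its per-symptom 2×2 tables are
exact, its joint structure is an artifact of fill order.  Passing tests on
synthetic data therefore demonstrate correctness of the machinery under
known margins, not real-world composite performance.

Presence draws and recording masks use separate seeded substreams, so
setting all recording rates to 1 with the same seed reveals the same
underlying presence states (tested).

## Problem sizes and determinism

Test-suite simulation sizes: generator calibration at n = 100,000
(3-binomial-SE marginal recovery), MCAR parameter recovery with 200
replicate maskings of one symptom at n = 3,400 and m = 5, bootstrap checks
at B = 1,000–2,000.  These sizes give Monte-Carlo error comfortably below
the assertion margins while keeping the default suite under about a
minute.  Every stochastic component takes an explicit seed; the pipeline
spawns per-stage substreams from one top-level seed via
`numpy.random.SeedSequence`, so whole runs are reproducible while stages
stay independently seeded.

## Known limitations

* The three-valued composite semantics and the imputation-model details of
  the original chart-review analyses are not recoverable from published
  reports; both witness/strict modes and both pooling modes are exposed
  instead of guessing.
* The CI recipes behind published intervals are likewise unstated;
  defaults here (Wilson/Simel/Woolf) are field-standard but point
  estimates, not intervals, are the reproduction contract.
* The latent-normal working model is a linear approximation for binary
  conditionals; it is accurate for the moderate probabilities seen here
  but would degrade near 0/1 class-conditional frequencies.
* No ROC/AUC machinery (predictors are binary), no multivariable
  adjustment (the per-symptom ORs are univariable by design), no
  external-validation support across sites.
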