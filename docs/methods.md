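# Methods

## The measurement problem

Module-structured app interventions unlock content sequentially: a
participant is always "in" exactly one treatment stage, and every logged
tap can be classified relative to that stage.  The package operationalizes
engagement in three steps — filter raw events into meaningful
*interactions*, attribute each interaction to a stage, and model the
resulting counts — with a generator that produces data of exactly this
structure for testing and power exploration.

## Interaction identification

Raw logs contain one record per user action (`app_open`, `app_pause`,
`app_close`, `content_open`, `content_close`, `exercise_complete`,
`log_submit`), each with a UTC timestamp and an optional content id.

**Dwell rule.** Each `content_open` is paired with the earliest subsequent
close signal (`content_close`, `app_close`, or `app_pause`) from the same
participant before the next `content_open`; dwell = close − open.  Opens
with dwell < `dwell_seconds` (default 5 s) are discarded as errant.
Choices the rule's wording leaves open, resolved here and configurable:

* dwell exactly at the threshold is retained ("fewer than 5 seconds"
  excludes only strictly-below);
* an open with no close signal (process killed, battery died) is
  retained — discarding it would undercount exactly the users whose
  devices cut sessions short;
* `app_pause` counts as a close signal, like `app_close`.  This is an
  interpretation: a pause event usually means the app left the
  foreground.

**Logging deduplication.** `log_submit` events are scanned
earliest-first per participant and logging type (`schedule_activity`,
`record_activity_mood`); a submission is retained iff it is at least
`dedup_minutes` (default 30) after the **most recently retained**
submission of the same type.  The retained-anchor convention guarantees a
burst of any size yields exactly one interaction and that an arbitrarily
long slow stream keeps accruing credit; the alternative anchor ("any
prior raw submission") is available as `dedup_anchor="any"` for
sensitivity analysis.  Both rules are monotone: raising either threshold
never increases retained counts (property-tested).

Opens of logging-category content are navigational and not counted — the
submission is the interaction — so a logging act is never double-counted.

Interactions outside the half-open active-treatment window
`[enrollment, enrollment + 56 days)` are excluded.

## Stage attribution

Stage 1 begins at enrollment (the first module must be enterable on day
0); each later stage begins at 00:00 UTC of its recorded unlock date,
since unlock records carry dates rather than instants.  Intervals are
half-open, so an interaction on module k's unlock date counts toward
stage k.  The final unlocked stage extends to the end of the window; the
last module has no successor and can never be revisited.  Content from a
module above the current stage should be unreachable in the app; such
interactions are surfaced as `locked_content` anomalies, excluded from
both counts, and reported, so that `within + between + anomalies = total`
holds identically.

## Descriptives

Per-participant counts partition by attribution, by content module, and
by category (learning / practice / logging).  Cohort summaries report the
median and the 25th/75th percentiles computed by linear interpolation
between order statistics; the convention is configurable
(`percentile_method` accepts any numpy method) because IQR endpoints on a
cohort of 26 are sensitive to it.  Modes report the smallest value among
ties.

## The model battery

All 27 models are univariate by design — with two dozen participants in
the motivating design, anything more flexible would be noise-chasing —
and their 27 focal p-values are jointly BH-adjusted.

**Count models.** `count ~ 1 + x` with log link, fitted by IRLS
(tolerance 1e-8, max 50 iterations).  Point estimates equal the Poisson
MLE; overdispersion enters only through the dispersion
φ = Pearson χ²/(n−p) and the HC0 score sandwich
(X'WX)⁻¹ [Σ xᵢxᵢ'(yᵢ−μ̂ᵢ)²] (X'WX)⁻¹, W = diag(μ̂).  HC1 small-sample
scaling is available by flag.  Inference: z = b/se, normal two-sided p,
95% Wald CI.  Predictors are grand-mean centered on the participants
contributing to each model; off-app practice minutes enter as ln(x+1)
(admits zeros) before centering.

**Residual-change models.** `week8 ~ 1 + baseline_c + count` by Huber
M-estimation, tuning constant 1.345 (95% Gaussian efficiency), scale
re-estimated each iteration as MAD/0.6745.  On noiseless data the fit
reduces exactly to least squares.  The robust covariance is the
M-estimator sandwich σ² A⁻¹BA⁻¹ with A = X'diag(ψ')X, B = X'diag(ψ²)X and
an n/(n−p) correction; inference is Wald t on n−p df.  The count
coefficient is the focal quantity: the association between usage and
end-of-treatment severity after controlling for baseline.

**Reliability.** McDonald's ω_t = (Σλ)² / ((Σλ)² + Σ(1−λ²)) from a
single-factor ML fit to the Pearson correlation matrix of raw item
scores, minimising the concentrated discrepancy over uniquenesses
(L-BFGS-B, uniquenesses floored at 0.005 with a Heywood warning).
Fitting Pearson rather than polychoric correlations on ordinal items is
an interpretation, flagged here; the generator calibration (below)
compensates exactly for the ordinal attenuation, so targets are stated on
the Pearson-ω scale the package computes.

**Spearman.** scipy's average-rank implementation with the
t-approximation p-value (exact permutation p-values are not attempted).

## The synthetic generator

The generator's defaults are the study conditions: 26 participants, 8
weekly modules whose completion requirements sum to 62, reliability
targets per scale (0.68–0.93), planted effects ln(1.07) (age → revisit
rate, per year), ln(1.19) (credibility → revisit rate, per unit), and
0.23 (week-8 PHQ-9 points per revisit given baseline).  Quantities the
motivating design does not publish — errant-open rate (0.08), burst-size
distribution, session decay, the per-item allocation of the 62 — are
fixed once at values a trialist would call realistic and documented in
`CohortConfig` and the program-spec file.

**Items.** Each scale is a single-factor model: latent item value
λf + √(1−λ²)e, discretized by thresholds placed at binomial quantiles so
the expected total matches the scale's cohort mean.  Discretization
attenuates inter-item correlations, so λ is calibrated by root-finding on
the *exact* correlation of thresholded bivariate normals (Mehler/Hermite
series, order 20): at the calibrated λ the population ω of the discrete
items equals the target.  Sample ω at n = 2000 recovers every target
within ±0.03 (test-verified, typically ±0.01).

**Week-8 scores.** A target total T = μ + b·(baseline − mean) +
effect·revisits + ε is mapped to a factor score through the exact inverse
of E[total | f], so the planted regression slope is unattenuated by the
item model; ε is scaled so Var(f) ≈ 1, preserving the ω calibration.
Floor/ceiling truncation of bounded totals leaves a small (≲0.02)
attenuation of the planted 0.23.  Dropout (default 2/26) is a hard stop
day; dropped participants have no week-8 measures and truncated event
logs, mirroring retained non-completers.

**Counts.** Revisit counts are Poisson with the log-linear rate above;
lognormal-type mixing over age and credibility makes the marginal counts
overdispersed.  Within-module counts are 62 + gamma-mixed Poisson extras
(shape 0.8), also overdispersed, matching the motivation for
quasi-Poisson over Poisson.

**Event logs.** Required completions for module m are scheduled inside
week m; the next module unlocks the calendar day *after* requirements are
met (a same-date unlock would retroactively reclassify that day's work as
between-module under the midnight-boundary convention).  Optional extras
and revisits land on an early-heavy thinned Bernoulli process of session
days (decay 0.02/day); revisit targets are skewed 75% toward module 1.
Errant opens (dwell U(0.5, 4.5) s) precede real opens at the configured
rate; logging bursts put B−1 extra submissions within 25 minutes of a
retained anchor.  A small fraction of opens close via `app_pause` /
`app_close` or not at all, exercising every branch of the dwell rule.
All randomness flows from one seed through spawned per-participant
streams; identical configs give byte-identical fixtures.

**What the generator does not emulate.** Real logs have sessions
interleaving many content units, clock skew, retrograde timestamps, and
revisit patterns driven by symptom trajectories; the generator's
schedule is cleaner than any real cohort's.  Passing tests therefore
demonstrate correctness of the rules and estimators under the stated
data-generating assumptions, not robustness to real-world log pathology
beyond the malformed-line handling the reader tests cover.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to make Monte Carlo error small
relative to the tolerance being asserted: reliability recovery at
n = 2000; CI coverage and effect recovery over 100 replicate cohorts of
n = 500; type-I calibration over 1000 null cohorts of n = 250 (the
battery's rejection rate is compared to 0.05 within binomial error at
1000 replicates); oracle equivalence over 1000 random sequences.

## Known limitations

* The per-item allocation of the 62 required completions is a modeling
  choice; only the total is externally constrained.
* ω is computed on Pearson correlations of ordinal items (see above).
* Robust-regression p-values use the Wald-t sandwich approximation;
  small-sample robust inference has many variants and none is exact.
* The dedup rule's retained-anchor convention is one of two defensible
  readings; both are implemented.
* Quasi-Poisson and Huber fits assume a single predictor block as
  specified; the package deliberately offers no multivariable or
  regularized variants.
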