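# Methods

This note documents the models, conventions, numerical choices and
limitations of the `mealcontext` pipeline, and what the synthetic-data
generator does and does not emulate.

## Data model and inclusion rules

Four tables are ingested (participants, EMA surveys, meal events, CGM
readings) with strict schema, vocabulary, range and referential-integrity
validation; malformed rows fail loudly with row-level diagnostics.
Check-all-that-apply answers are sets; `alone` (companions) and `nothing`
(activities) are exclusive tokens and contradictory combinations are
rejected at ingest rather than silently repaired. When both HbA1c and
fasting glucose are present, the glycemic-status label must agree with
them (prediabetes iff not diabetic and HbA1c ≥ 5.7% or glucose ≥ 5.6
mmol/L).

Meals are retained when their clock time falls in [05:00, 24:00).
Mealtime bins are half-open — [05:00, 11:00) breakfast, [11:00, 17:00)
lunch, [17:00, 24:00) dinner — so the three categories partition the
analysis day unambiguously. Among retained meals, any location category
covering strictly less than 1% of meals is *flagged* out of
location-based analyses but kept for everything else; the flag threshold
is computed after the time filter. The exclusion log records a reason for
every dropped or flagged meal, and filtering is idempotent.

Premeal psychophysiological states take the latest rating whose
app-recorded timestamp lies in the closed window [meal − 120 min, meal].
Both boundaries are inclusive: a rating exactly two hours before, or at
the minute of, the meal qualifies. All lag and window arithmetic is in
minutes (meal times have minute resolution).

## Diet-quality score

One point for consuming each of: whole grains, seafood,
legumes-or-nuts, vegetables, fruit, dairy; one point for *not* consuming
each of: refined grains, red meat, deep-fried foods, sweet desserts;
sum in 0–10. Soy products and beans/peas/nuts/seeds feed a single
legumes-or-nuts component, so either (or both) earns exactly one point.
Chicken and eggs appear in the intake checklist but in neither scoring
list and are score-neutral. Sweet desserts are coded disjointly from
dairy. The optional `no_ssb` component (off by default) uses beverage
intake reported in the same survey as the meal as a proxy for a
sugar-sweetened beverage with the meal, extending the range to 0–11. The
score is a checklist instrument: with no portion sizes or energy, it
orders meals by food-group composition only and is not validated against
any external diet-quality index.

## Postprandial glucose

**Baseline.** Glucose at meal time by linear interpolation of the two
bracketing readings (the reading itself if one coincides). Interpolation
is unbiased with respect to the phase offset between the reading grid
and the meal; alternatives such as "last premeal reading" would
systematically lag the true meal-time level.

**iAUC.** The incremental curve g(t) − baseline is piecewise linear with
knots at the readings inside (0, 120) minutes post-meal and interpolated
endpoints at 0 and 120. `net` integrates the signed curve by trapezoids;
`positive_only` integrates max(curve, 0), splitting segments exactly at
zero-crossings. Both conventions are first-class outputs because the
field uses both; `net` is the default. Units are mmol/L·minute
throughout. The two agree whenever the incremental curve is nonnegative,
and `positive_only ≥ net` always.

**Eligibility.** A meal qualifies when (a) no other reported meal of the
same participant falls in the *open* intervals (meal − 120, meal) or
(meal, meal + 120) — so back-to-back meals exactly two hours apart remain
eligible, and fasting is judged from reported meals only; and (b) CGM
coverage of the window is complete: an anchor reading at or before the
meal at most 15 minutes old, a closing reading at or after +120 minutes,
and no inter-reading gap above 20 minutes inside the window. The 20-min
rule operationalizes "complete 15-minute data" with tolerance for
timestamp jitter; one ineligibility reason is reported per meal with
precedence pre-window, post-window, then CGM-incomplete.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: 9 days × 6
prompts inside fixed windows (08:00–09:30 … 20:30–21:30), 91% response,
~16 meals per participant (one per responded prompt with probability
0.33), location shares 60/14/11/9/2/1/3% (home, hawker, workplace, other
restaurant, fast food, friend/relative's home, other),
location-conditional food-group Bernoulli draws (e.g. refined grains 83%
at hawker centres, deep-fried 49% at fast food), companion and activity
sets drawn per location row, discretized truncated-normal psych ratings
(stress 1.57 ± 1.37, hunger 2.25 ± 1.52, tiredness 2.25 ± 1.48,
happiness 3.63 ± 1.36), fullness 3.80 ± 1.04 on 1–6, per-participant
fasting glucose 5.1 ± 0.9 mmol/L drawn consistently with the assigned
glycemic status (70/25/4% normal/prediabetes/diabetes; half the
prediabetics qualify through HbA1c with glucose still under 5.6), latent
meal iAUC 143.28 ± 137.52 mmol/L·min, 61% CGM-eligible meals and 57%
premeal-state availability. Study start days rotate across the week so
the weekday share is ~5/7. Printed 0% cells in the companion/activity
rows are treated as "< 0.5%" (0.005), not structural zeros, so logit
models remain estimable.

Design choices that matter for testing:

- **Ground truth is exact.** Context effects on fullness and iAUC are
  injected *additively on the latent outcome scale* and stored with the
  dataset, together with per-participant random intercepts (intra-class
  correlation 0.1 by default, split between participant and meal-level
  variance). Diet-quality differences between locations are *not*
  injected: they emerge mechanistically from the location-conditional
  food probabilities, and the generator reports the implied closed-form
  expectation Σ P(component) per location.
- **Exclusive-token sets.** `alone`/`nothing` fire with their configured
  probability; otherwise the remaining tokens fire independently with
  marginals rescaled by 1/(1 − p_exclusive), an empty draw falling back
  to the exclusive token. The realized alone share therefore has the
  closed form a + (1 − a)·Π(1 − p̃_c), which the tests check; the
  non-exclusive marginals are approximate, since no independent scheme
  can match all row margins under the exclusivity constraint.
- **Premeal availability is exact by construction.** Each meal carries a
  rating with the configured probability, placed 2–115 minutes before it
  and constrained away from the 2-h windows of neighbouring meals, so the
  extraction rule recovers exactly the intended fraction.
- **CGM rendering inverts the measurement.** Each meal adds a
  piecewise-linear excursion (rise to peak at 45 min, decay to zero by
  150 min) on a per-participant reading grid with a uniform 0–15 min
  phase offset. The amplitude is calibrated per meal by inverting the
  *measured* net iAUC of a unit excursion on that exact grid — including
  the sampling of the shape at the knots and the contamination of the
  interpolated baseline by the excursion's early rise (about a 9%
  effect). Without noise the pipeline recovers each meal's target iAUC to
  reading-rounding precision. Residual discrepancies on full cohorts come
  from reading noise (SD 0.1 mmol/L), a small diurnal sinusoid (amplitude
  0.15 mmol/L), and the tails of excursions from meals just over two
  hours earlier; the cohort mean stays within Monte-Carlo error of the
  target.
- **Eligibility calibration.** Spacing ineligibility arises naturally
  from simulated meal times; the generator then deletes a 30-minute block
  of readings (+40 to +70 min) at a calibrated fraction of the
  spacing-eligible meals so the overall eligible fraction matches the
  configured 61% in expectation.
- **Determinism.** All randomness flows from one integer seed through a
  single `numpy.random.Generator`; identical configs give byte-identical
  fixtures.

What the generator does **not** emulate: real glucose physiology (no
insulin kinetics or mixed-meal modelling — excursions are stylized
shapes), joint dependence of companions/activities beyond
location-conditional independence, within-person autocorrelation of
psych states, portion sizes, or free-text food reporting (inputs arrive
pre-coded to the 13-group vocabulary). Passing tests therefore
demonstrate that the *estimators and plumbing* are correct under the
assumed statistical structure, not that the structure matches any real
cohort.

## Association estimation

GEE fits use statsmodels with meals as observations, participants as
clusters, identity link for numeric outcomes and logit for binary ones,
and cluster-robust sandwich covariance. The independent working
correlation is primary; exchangeable and AR(1) (within-participant meal
order as the time index) are sensitivity re-runs. CIs are normal-theory
β ± 1.96·SE — cluster counts here are in the hundreds, so small-sample t
corrections would change little. Reference levels: home (location),
alone (companions, as the all-zero indicator pattern of non-exclusive
companion indicators), only-eating (activities), breakfast (mealtime).
Complete-case estimation per model, no imputation: premeal-state models
restrict to meals with states, glucose models to CGM-eligible meals.
Designs are screened for rank deficiency; orchestration drops
unsupported or aliased indicators (e.g. a covariate class absent from a
small cohort) before fitting, while the direct `fit_gee` call raises a
named error. Constant outcomes yield a degenerate fit with zero slopes
and zero SEs rather than an exception. No multiplicity adjustment is
applied anywhere; reports carry the number of tests run.

**Wald comparisons.** Context-block screening computes the robust Wald
chi-square b′V⁻¹b on the added coefficients with the sandwich covariance
block, df = number of added terms. The statistic is invariant to
nonsingular reparameterization of the null-model covariates. With very
small cohorts and near-empty location × context cells the logit version
can quasi-separate and the statistic becomes unstable; at realistic
cohort sizes (hundreds of participants) it is well behaved.

**Cluster bootstrap.** Crude premeal-state correlations are tested by
resampling participants with replacement (10,000 replicates by default)
and recomputing Pearson r per replicate from per-cluster sufficient
statistics — algebraically identical to concatenating the resampled rows
but orders of magnitude faster. The two-sided p is
2·min(P(r* ≤ 0), P(r* ≥ 0)) with an add-one correction over n_boot + 1,
so p is never exactly zero; the CI is percentile 2.5/97.5. Resampling
whole participants is the coherent unit under clustering; plain
meal-level resampling is available as `unit="meal"` and coincides with
the cluster version when every cluster has one meal. The percentile test
is mildly anticonservative (empirical size ≈ 5.5–6.5% at a few hundred
clusters), a known property of percentile bootstrap tests; it stays
within the 3–7% calibration band used in validation.

**Marginal estimates.** Adjusted means per focal level by G-computation:
set every row's focal indicators to the level's pattern, average the
model prediction over the observed covariate distribution, delta-method
CI from the robust covariance. With no adjustment covariates this
reproduces raw group means exactly.

**VIF.** Per-term variance inflation factors from auxiliary
least-squares regressions with intercept; R² = 1 flags infinite VIF.

## Validation scale choices

Simulation studies in the test suite run at 300 participants per cohort
(100 cohorts for coverage/bias recovery of an injected +30 mmol/L·min
hawker effect; 500 cohorts for type-I error of the Wald and bootstrap
tests under the global null, bootstrap at 2,000 replicates) and 500
participants for single-cohort generator calibration. These sizes keep
the Monte-Carlo error of each check several times smaller than the
tolerance being asserted. Family-wise (Bonferroni-adjusted) thresholds
are used where a dozen or more marginals are checked against one seeded
dataset.

## Known limitations

- The fasting restriction sees only *reported* meals; unreported intake
  would contaminate postprandial windows in real data.
- The iAUC convention of the underlying measurement literature (signed
  vs positive-only) is ambiguous; both are computed, neither asserted as
  canonical.
- Whether a rating at exactly meal time is "premeal" is a boundary
  convention (inclusive here) that shifts availability negligibly but is
  exposed for sensitivity analysis.
- The score treats all portions equally and ignores beverages except via
  the proxy SSB flag.
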