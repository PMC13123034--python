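# mealcontext

Eating-context analysis of smartphone EMA meal reports and continuous
glucose monitoring (CGM) in free-living adults: from raw survey and
sensor tables to meal-level diet-quality scores, 2-hour postprandial
glucose responses, and estimates of how meal location, companions,
concurrent activities, and premeal psychophysiological states relate to
what and how people eat.

## The scientific problem

Where a meal is eaten (at home, at a hawker centre, at a fast-food
restaurant, at work), who it is eaten with, what else is going on during
the meal, and how hungry, stressed, tired or happy the eater felt
beforehand all plausibly shape both the composition of the meal and the
glycemic response to it. Ecological momentary assessment (EMA) studies
capture these factors in real time: participants answer up to six
smartphone prompts per day over nine days, reporting each eating occasion
with a check-all-that-apply food-group list, its location, companions,
activities, and a post-meal fullness rating, while a masked CGM sensor
records interstitial glucose every 15 minutes.

This package implements the full analysis pipeline for such a study, plus
a synthetic-cohort generator that emulates the study's statistical
structure with injectable ground-truth effects — so every stage is
testable end-to-end without access to any participant data.

## Methods at a glance

- **Diet quality.** Each meal receives a DASH-adapted score
  `S = Σ_h 1[h consumed] + Σ_u 1[u not consumed]` over six healthy
  components (whole grains, seafood, legumes-or-nuts, vegetables, fruit,
  dairy) and four unhealthy ones (refined grains, red meat, deep-fried
  foods, sweet desserts), range 0–10. An optional eleventh component
  credits non-consumption of sugar-sweetened beverages.
- **Postprandial glucose.** The 2-h incremental area under the curve,
  `iAUC = ∫₀¹²⁰ (g(t) − g₀) dt` in mmol/L·min, by the trapezoidal rule on
  the piecewise-linear CGM trace, with the baseline `g₀` interpolated at
  meal time. Both the signed (`net`) and positive-part (`positive_only`)
  conventions are provided. Meals qualify only with 2 h of fasting on
  either side (open intervals) and complete CGM coverage of the window.
- **Premeal states.** The latest stress/hunger/tiredness/happiness
  ratings (0–6) recorded within the closed 2-h window before the meal.
- **Association estimation.** Generalized estimating equations with
  meals as observations and participants as clusters: identity or logit
  link, independent working correlation (exchangeable and AR(1) as
  sensitivity re-runs), cluster-robust sandwich covariance, normal-theory
  95% CIs. Context blocks are screened with robust Wald chi-square tests
  against null models; crude premeal-state correlations are tested with a
  participant-level cluster bootstrap (percentile CI, add-one two-sided
  p); adjusted marginal estimates come from G-computation over the
  observed covariate distribution; variance inflation factors screen the
  multivariable design.

## Worked example

```python
from mealcontext import synthetic_data as sd, data_model as dm, \
    diet_quality as dq, cgm_linkage as cl, association as assoc

cfg = sd.SimulationConfig(n_participants=200, seed=7,
                          excursion_effects={"location:hawker": 30.0})
bundle, truth = sd.simulate_cohort(cfg)          # EMA + CGM tables
meals, _ = dm.filter_meals(bundle.meals)         # 05:00-24:00 window
scores = dq.score_dataset(meals)                 # per-meal 0-10 score
pp = cl.link_all(meals, bundle.cgm)              # eligibility + 2-h iAUC
pm = dm.extract_premeal_states(meals, bundle.surveys)

tab = assoc.build_analysis_table(bundle.participants, meals, scores, pp, pm)
tab = tab[~tab.location_excluded]
terms = assoc.prunable_terms(
    tab, assoc.BASELINE_ADJUSTMENT_TERMS + assoc.COMPANION_TERMS
    + assoc.ACTIVITY_TERMS + assoc.LOCATION_TERMS)
fit = assoc.fit_gee(tab[tab.eligible],
                    assoc.ModelSpec(outcome="iauc_net", terms=terms))
print(fit.table().loc["loc_hawker"])
```

Output (abridged):

```
meals: 3166  premeal states: 1824 (57.6%)
CGM-eligible: 1985 (62.7%)  net iAUC mean (SD): 143.5 (139.1) mmol/L*min
diet-quality mean (SD): 4.03 (1.19)
hawker vs home, iAUC beta (95% CI): 33.67 (13.35, 53.99), p=0.0012
```

The generator injected a +30 mmol/L·min glucose effect for hawker-centre
meals; the multivariable GEE recovers it (33.7, CI covering 30) from the
rendered CGM traces alone. The diet-quality and availability figures
match the generator's configured study conditions (~57% of meals with
premeal states, ~61% CGM-eligible, cohort mean iAUC ≈ 143 mmol/L·min).

A command-line interface wraps the same stages:

```bash
mealcontext simulate --n-participants 100 --seed 7 --out fixture/
mealcontext all --sim-config config.yaml --seed 7 --out run/
```

`run/` then contains the stage CSVs (`scores.csv`, `postprandial.csv`,
`results.csv`, `marginals.csv`, `wald.csv`, `bootstrap.csv`), descriptive
tables, a JSON-lines run log with counts at every filter, and a manifest.

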