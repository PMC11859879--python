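# Methods

## Exposure model

Drug exposure is reconstructed from dispensing events alone. The days of
supply of one dispensing are `n_packages × DDDs_per_package`: the WHO
defined daily dose is taken as one day of therapy. This is an assumed
average maintenance dose — actual prescribed posology is not observed in
claims, so therapy durations are approximate by construction; the package
makes no attempt to correct for dose-adjusted regimens.

Dates are handled as integer day offsets from 1 January of the
observation year; all intervals are half-open `[start, end)`, which makes
day counting unambiguous (a one-day supply dispensed on day `d` covers
exactly day `d`). Fills dispensed in the preceding year are chained
together with observation-year fills and the result clipped to the year,
so supply carried over the year boundary is retained; coverage shifted
past 31 December of the observation year is discarded.

### Shift-on-overlap

All drugs within one ATC 4th-level class (first five characters of the
code) are interchangeable. Fills of a class are processed in
`(dispense_day, record_id)` order; each starts at its dispensing day or
at the end of the class's current coverage, whichever is later. The rule
conserves supply exactly — no day is double-counted and none is lost —
and is equivalent to a day-by-day simulation that banks early refills and
consumes one DDD per day (the test suite asserts this equivalence against
a brute-force oracle on randomized instances). Same-day same-class fills
queue in stable `record_id` order. Stockpiling through repeated early
refills is unbounded; no cap is applied.

### Numerical choices

* Fractional days of supply round half-up with a floor of one day;
  `floor` and `ceil` are available as configuration options
  (`rounding`). Claims DDD totals are frequently fractional and no
  convention is universal, so the choice is exposed.
* Cumulative annual DDDs (for the `DDD_GE_60` definition) sum the
  dispensed DDDs of fills contributing at least one covered day to the
  year, consistent with the cohort-entry treatment of carried-over
  look-back fills; `ddd_attribution: dispensed` switches to
  dispensed-in-year attribution.

## Counting and aggregation

A class counts in a calendar window (year / quarter / month) when at
least one of its covered days falls inside it. Calendar windows only —
no rolling windows. Sub-annual counts collapse to one patient summary by:

* `MAX` (primary): the polypharmacy flag is the maximum count across
  windows reaching the threshold;
* `MEAN`: the unrounded mean compared to the same thresholds, and binned
  by the same cutpoints (`[5, 6) → bin 5`, ...) without rounding;
* `COVERED_FRACTION` *f*: flagged only if at least `ceil(f × windows)`
  windows individually reach the threshold (for monthly windows,
  f = 0.5/0.8/1.0 correspond to 6/10/12 qualifying months). Under this
  rule the class bin still reports the maximum count, so bins remain
  comparable across aggregation rules; the flags, not the bin, carry the
  covered-fraction semantics.

Patients with no counted class under a restrictive definition fall in the
1–4 bin: cohort entry guarantees one dispensed drug overall, not one per
definition. A dispensing-date-only counting mode (no coverage, no
shifting) is provided as a sensitivity contrast.

## Outcome model

The outcome is any all-cause admission in the first half of the year
after the observation year (default window 1 January–30 June; the end
date is configurable because "first half" conventions differ). Multiple
admissions count once. Excluded from the models: patients dying before
the end of that follow-up year, and patients whose only follow-up-year
admissions fall in its second half — their "non-hospitalized" label
within the outcome window would be misleading. Prior hospitalizations
count admissions over the four calendar years ending with the observation
year, regardless of outcome. Discharge records with a discharge date
before admission are rejected with a warning.

Models are maximum-likelihood logistic regressions (statsmodels). Age
enters as completed years at 31 December of the observation year and the
prior-hospitalization count as a continuous covariate; confidence
intervals are Wald intervals on the log-odds scale. Class-bin models use
1–4 as reference with indicators for 5, 6, 7, 8, 9, ≥10; empty bins are
dropped from the design and reported as non-converged terms rather than
crashing the fit. The >7-day sensitivity keeps stays strictly longer than
seven days.

## Synthetic-claims generator

The generator emulates the three administrative archives for a cohort
aged ≥40 with at least one dispensing in the observation year (2017 by
default). Defaults, chosen as typical of an adult general-practice
claims population:

| Parameter | Default | Meaning |
|---|---|---|
| `mean_chronic_classes_per_patient` | 3.0 | Poisson mean of distinct chronic ATC4 classes (≈18% of patients carry ≥5) |
| `refill_jitter_days` | 5 | integer jitter (±days) on each refill interval; negative draws create the overlaps the shift rule resolves |
| `mean_acute_courses_per_patient` | 1.5 | short courses (≤14 DDDs) from the excluded short-term families |
| `true_outcome_or` | 2.5 | odds ratio linking the ≥5-chronic-class exposure to hospitalization |
| `baseline_outcome_prob` | 0.08 | first-half-follow-up admission probability among the unexposed |
| `prior_hosp_rate` | 0.4 | Poisson mean of prior admissions over the four look-back years |
| `death_prob`, `second_half_admission_prob` | 0.01, 0.03 | follow-up-year nuisance events exercising the exclusion rules |

Chronic streams are anchored at a uniform start day (look-back year
included) and refilled every class interval (defaulting to the package's
days of supply) plus jitter; acute courses land uniformly in the year.
Patients whose streams produce no in-year fill receive a single filler
analgesic course, preserving the cohort-entry guarantee. The outcome
follows a logistic model with linear predictor
`logit(baseline) + log(OR)·exposed` plus small sex and age effects, so
adjusted models have real covariates to absorb. Confounding and severity
dials (`prior_hosp_exposed_multiplier`, `outcome_prior_log_or`,
`los_exposed_multiplier`) default to neutral — the crude odds ratio then
targets `true_outcome_or` up to the slight non-collapsibility of the
logistic marginal — and are switched on explicitly in the directional
tests (adjusted < crude under confounding; higher odds ratios after the
long-stay filter).

Randomness derives one substream per patient index from the master seed,
so enlarging a cohort never changes already-generated patients and a seed
fully determines every table.

### What the generator does not emulate

A realistic national drug-market mix (the class pools are a small curated
set), marketing-authorization codes, costs, seasonality of acute
prescribing, dose titration, or dependence of chronic burden on age and
sex. Passing recovery tests therefore demonstrates that the pipeline
measures what the generator encodes — exposure misclassification
processes present in real claims (unreimbursed and over-the-counter
drugs, dose deviations from the DDD) are out of scope and would bias real
analyses in ways these tests cannot detect.

## Problem sizes

Validation uses randomized instances of ≤20 fills against brute-force
oracles, populations of 2,000–12,000 patients for distributional and
directional checks, and 50,000 patients for odds-ratio recovery (crude
and adjusted estimates within the Monte-Carlo error of the configured
2.5). The acceptance script uses the same 50,000-patient size for its
main run and 5,000 for the sensitivity contrasts.

## Known limitations

* DDD-based durations misestimate therapy length wherever prescribed
  doses deviate from one DDD/day.
* The shift rule attributes all same-class overlap to early refilling;
  true duplication of therapy within a class is indistinguishable in
  claims and is folded into the same coverage timeline.
* Whether annual DDD totals should be attributed by coverage or by
  dispensing year is convention; both are implemented, coverage is the
  default.
* Wald intervals can be poor in tiny strata; non-convergence and empty
  bins are reported, not silently dropped.
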