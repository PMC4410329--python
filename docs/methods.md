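# Methods

## Estimand and procedure

The package estimates the annual healthcare cost avoided per participant of a
chronic disease self-management program, and projects totals under changed
reach. It is an accounting model, not an inferential one: it prices observed
pre/post changes in self-reported utilization, and produces estimates, not
measured savings.

1. **Utilization reductions.** A closed cohort reports any ER visit and any
   hospitalization in the prior 6 months at baseline, 6 and 12 months. Wave
   proportions are computed over wave- and category-specific respondents
   (attrition shrinks denominators; nothing is imputed) and rounded to whole
   percentage points *before* differencing, so the deltas agree with the wave
   percentages a reader sees. Both periods are referenced to baseline, not
   chained. Negative deltas (utilization rose) are legal, propagate as
   negative savings, and add a report warning.
2. **Age-adjusted costs.** Mean per-event costs by age bin (18–44 / 45–64 /
   65+; defaults from 2010 MEPS) are directly standardized to a chosen age
   distribution — a weighted mean, so the result always lies between the
   minimum and maximum bin cost and is monotone in each.
3. **Annual savings.** Each period's delta prices at delta/100 × adjusted
   cost; the annual figure is the sum of the four *unrounded* components
   (hence 75.6525 + 75.6525 renders as 151.31 while each cell renders 75.65).
4. **Program cost.** Workshop cost / class size, rounded half-away-from-zero
   to whole dollars (the $3,500 default gives the menu 219/250/292/350/438/583
   at class sizes 16/14/12/10/8/6); an explicit per-participant override wins.
5. **Net savings.** Annual savings minus program cost; may be negative.
6. **Projection.** National: eligible adults × reach fraction × net, with
   every factor unrounded. Local: an expected enrollment by age bin; the cost
   schedules are re-standardized to the new mix and the *observed* reductions
   reapplied — a stated modeling assumption (behavior change is not
   re-estimated by age), echoed in the report output.

## Rounding and numerics

Internal arithmetic is double precision carried unrounded end to end.
Rounding is a rendering concern — half-away-from-zero at display precision
(cents for currency, whole persons for populations) — with exactly two
in-chain exceptions, adopted because the published worksheet demonstrably
rounds there: whole-percent reductions (Step 1) and the whole-dollar program
cost (Step 4). The half-away-from-zero mode is implemented over the shortest
decimal representation of the float (218.75 → 219, 437.5 → 438,
562.5054 → 562.51), never banker's rounding. Reports are deterministic:
identical inputs render byte-identical documents.

Two documented quirks of the source worksheet are resolved as follows:

* Its narrative once prints $562.50 (= 0.03 × 18,750) where the worksheet
  cell prints $562.51 (= 0.03 × 18,750.18, to cents); the unrounded-chain
  value 562.51 is used.
* Its printed eligible-adult count, 180,614,335, equals the Census adult
  total × the overall 77% prevalence, while its narrative describes an
  age-specific sum (≈186.4 million). The overall method is therefore the
  default (`chronic_population_method: "overall"`); the age-specific formula
  is implemented behind the explicit `"age_specific"` flag, and the two agree
  whenever all bin prevalences equal the overall one.

## Key parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| Age bins | 18–44, 45–64, 65+ | years | the program targets adults; under-18 records are rejected at ingestion |
| Cost schedules | ER 1465/1738/1403; hosp. 11501/21462/18554 | 2010 USD per event | 2010 MEPS means, contemporaneous with the 2010–2012 study |
| Age distribution | 0.10 / 0.31 / 0.59 | fractions | the national study cohort's mix |
| Workshop cost / class size | $3,500 / 10 | USD, persons | field-reported delivery economics → $350 per participant |
| Population profile | 234,564,071 adults; prevalence 77% (71/84/94 by bin) | persons, fractions | 2010 Census + MEPS |
| Stability threshold | 100 | baseline participants | below it, whole-percent rates are too coarse; a warning (never an error) attaches to the report |

The age distribution used for standardization is always the configured one —
in the worksheet it is its own input cell — while the observed cohort mix is
computed and shown alongside it. This matters because a finite cohort cannot
always realize a rounded mix exactly (no 1,170-person cohort has exactly 31%
in 45–64), and it is what makes an estimate from a generated national cohort
identical to the default run. Callers wanting observed-mix standardization
set the config distribution from the aggregated counts.

All dollar figures are nominal 2010 USD; no inflation indexing, discounting,
cost-effectiveness ratios or significance testing are in scope.

## Synthetic cohorts

The fixtures module generates participant files so the whole pipeline is
testable offline.

* **EXACT mode** realizes target counts deterministically: targets (retention
  × n, rate × denominator, mix × n) are rounded to whole persons; the spec is
  infeasible — a named error — if the rounded bin counts do not sum to the
  cohort size or rounded events exceed their denominator. Events and
  follow-up response are assigned to the lexicographically first participants,
  so generation needs no seed and `generate → aggregate` inverts any feasible
  spec.
* **STOCHASTIC mode** draws age bin, wave response and events independently
  per participant from the spec's fractions, with a mandatory integer seed
  (no wall-clock default); identical (spec, seed) gives bit-identical
  cohorts. Follow-up response at 12 months is drawn independently of the
  6-month response — an assumption, matching data where the 12-month
  respondent set is not stated to nest in the 6-month one.

What the generator emulates: wave denominators, event proportions and the age
mix. What it does not: event counts per person beyond "any", cost
heterogeneity within age bins, correlated attrition, or reporting bias in
self-reported utilization. Tests passing on synthetic cohorts therefore
validate the arithmetic and plumbing, not the accuracy of self-report or the
transportability of the national reductions to other sites.

## Problem sizes and verification

Everything is desk-scale and closed-form: the test suite regenerates the
1,170-participant national cohort, a 10,000-participant stochastic cohort
(for 3-binomial-SE rate checks), and ~100-iteration randomized property
sweeps, and completes in a few seconds. The acceptance script recomputes the
national chain end to end from a generated cohort and both case studies from
their printed inputs.

## Limitations

* Self-reported utilization; no claims linkage or survey weighting.
* Static 2010 costs, prevalences and Census counts; no inflation adjustment.
* Local projections reuse observed reductions under a new age mix.
* The local scenario takes a projected headcount, not a fraction of a
  community population.
* Below 100 baseline participants the whole-percent pipeline is coarse; the
  tool warns but still computes.
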