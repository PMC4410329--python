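# cdsmp-savings

A tested library and command-line tool for estimating the healthcare cost
savings of a chronic disease self-management program (CDSMP) — the six-week,
peer-led workshop for adults with chronic conditions. It is aimed at program
administrators and evaluators who track participants' self-reported emergency
room (ER) visits and hospitalizations at baseline, 6 and 12 months and want a
defensible dollar figure for what the program averts, net of delivery cost,
and a projection of what expanded reach would save.

## The model

For each utilization category *c* ∈ {ER, hospitalization} the cohort yields
wave proportions *p₀*, *p₁*, *p₂* (share of respondents reporting any event in
the prior 6 months, rounded to whole percent). Reductions are
baseline-referenced: Δ₁ = p₀ − p₁, Δ₂ = p₀ − p₂ (percentage points).

Per-event costs come from 2010 MEPS means by age bin, directly standardized to
an age distribution **w** = (w₁₈₋₄₄, w₄₅₋₆₄, w₆₅₊):

  C̄_c = w · (C_c,18-44, C_c,45-64, C_c,65+)

Annual per-participant savings and the net of program cost are

  S = Σ_c (Δ₁ᶜ + Δ₂ᶜ)/100 · C̄_c,    net = S − cost_pp,

where cost_pp is a fixed workshop cost divided by class size (whole dollars),
e.g. $3,500 / 10 = $350. Step 6 scales the net: nationally, eligible adults
(Census total × chronic-condition prevalence) × reach fraction × net; locally,
an expected enrollment with a new age mix, under which the cost schedules are
re-standardized and the observed reductions reapplied.

All intermediate arithmetic is carried unrounded; rounding (half away from
zero) happens at display, except the whole-percent reductions and whole-dollar
program cost, which the chain itself rounds before use. All dollars are
nominal 2010 USD.

## Worked example

Running the national defaults with a 5% reach projection:

```
cdsmp-savings project --reach 0.05
```

prints the full worksheet; its key lines are

```
    age-adjusted cost: 1,513.05      # ER, under the 10/31/59 age mix
    age-adjusted cost: 18,750.18     # hospitalization
3. ANNUAL HEALTH CARE SAVINGS PER PARTICIPANT
  713.81
5. NET SAVINGS PER PARTICIPANT
  363.81
6. NATIONAL EXTRAPOLATION
  Adults 18+ with at least one chronic condition: 180,614,335
  Savings if you could reach ALL of them: 65,709,373,342.03
  Reach: 5%
  Projected savings at this reach: 3,285,468,667.10
```

Reading: a cohort of 1,170 participants cut ER visits by 5 points in each
6-month period and hospitalizations by 3 points in the first, worth $713.81
per participant per year at age-adjusted MEPS costs; after the $350 delivery
cost, $363.81 net — about $3.3 billion if 5% of the 180.6 million eligible
adults enrolled.

Your own data goes in as a JSON config (any omitted field keeps its national
default) and/or a participant CSV:

```
cdsmp-savings estimate --config my_site.json --participants cohort.csv
cdsmp-savings project  --config my_site.json --expected-counts 670 260 70
```

`cdsmp-savings fixtures --spec spec.json --seed 7 --out cohort.csv` writes a
synthetic participant file (exact or stochastic) for testing a pipeline
offline. Library access mirrors the CLI: see `cdsmp_savings.build_report`,
`cdsmp_savings.local_projection` and friends.

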