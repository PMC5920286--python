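# Methods

## Model structure

`morbisim` is a discrete-time dynamic microsimulation: a closed population
of individuals aged 35+ evolves month by month from a mid-2014 start to a
configurable horizon (default 2035). Within a month each alive individual
is processed in a fixed order:

1. **survival** — Bernoulli draw at monthly survival (1 − q)^(1/12), where
   q is the annual death probability for current age, sex and calendar
   year; mortality depends on nothing else (no individual-level risk
   loading);
2. **ageing** — age advances one month;
3. **characteristic updates** — one categorical draw per stochastic
   characteristic in registry order (marital status, smoking, inactivity,
   BMI; then diseases; then hearing, vision and cognition), each draw
   conditioning on already-updated values of earlier characteristics in
   the same month.

The update order is a modelling choice; it is fixed, documented and
deterministic so that any run is reproducible from (inputs, seed). Annual
snapshots are taken at the start of July to approximate mid-year period
prevalence; the snapshot month is configurable. Nobody enters the
population after the start — the 65+ population of a later year is the
ageing of the base population, so incoming old-age cohorts carry their own
simulated risk-factor history rather than an assumed profile.

## Characteristics and transition models

Sex, education, socio-economic status and residence are fixed; age is
deterministic; everything else is stochastic. Transition models are
regressions of the wave-2 state on wave-1 covariates in a two-wave panel of
survivors (interval 24 months by default):

* binary logistic for two-state characteristics. Ever-diagnosed diseases
  (all but depression) are **absorbing**: the model is fitted on the
  at-risk subset as an onset model, and a present state never reverts.
  Recoverable binaries (depression, inactivity, hearing, vision) include
  their own wave-1 state as a predictor, so one model carries both onset
  and persistence. Depression is treated as recoverable because projected
  counts of a strictly absorbing condition could never fall while survival
  improves, and its reported dynamics do fall;
* proportional-odds (ordered logit) for BMI category and the 3-band MMSE
  state;
* multinomial logit for marital status and smoking, with the first state
  as reference and own-state dummies as predictors.

Ordinal covariates enter the linear predictor as numeric scores; age enters
as (years − 65)/10 so coefficients are per decade. The exact per-survey
predictor lists behind the original model are not public; the registry
ships a documented default (age, sex, education, SES, behaviours, plus a
few cross-disease effects such as hypertension→stroke) and accepts
overrides.

Fits are maximum likelihood via statsmodels; a constant outcome raises an
explicit degenerate-fit error, and separation or non-convergence triggers a
warning and an L2-penalised refit (scikit-learn, C = 100) recorded in the
fit metadata. Dementia never appears as outcome or predictor: it is
assigned after the simulation (below).

**Monthly conversion.** The fitted 2-year probability p of each
off-diagonal move is converted by the constant-hazard formula
m = 1 − (1 − p)^(1/24); the stay probability takes the remainder. For a
binary characteristic with fixed covariates this round-trips exactly
(compounding m for 24 months gives p back, tested to 1e−9). For
multi-state characteristics each destination is converted independently —
a competing-risks approximation whose error is second order in the monthly
probabilities; the resulting distribution is renormalised and tested to sum
to 1. Covariates are frozen at their current values each month (no
within-interval interpolation), and transition rates do not depend on
calendar time.

## Mortality and lifetables

A schedule of annual death probabilities by calendar year, sex and single
year of age (35 to a terminal age of 105, q = 1 at the terminal age) drives
both the engine and the period lifetable: l_{x+1} = l_x(1 − q_x),
L_x = l_x − ½d_x (deaths mid-interval), e_x = Σ L_y / l_x. The national
projection schedule the design assumes is external data; the packaged
stand-in is Gompertz (hazard A·e^{0.105·age}) with a 1.5%/year calendar
improvement, with A set so that period e65 in 2015 is ≈18.6 y (men) and
≈21.2 y (women) — the English magnitudes for that year. A mortality-only
simulated cohort reproduces the analytic lifetable survivorship within
binomial error (tested at n = 50 000).

## Dementia allocation

Dementia prevalence information is assumed to come from a separate source
and is imposed **outwith** the simulation: an allocation table gives
P(dementia) by age group (35–64/65–74/75–84/85+), MMSE band
(26–30/21–25/0–20) and community/care-home residence. Each individual
draws one persistent uniform quantile u per run and carries
dementia = (u < p_cell) in every snapshot. With a table that rises with age
and falls with MMSE, p_cell is non-decreasing along a trajectory whose MMSE
does not improve, so onset is effectively monotone while each cell's
expected prevalence equals its table probability. An
independent-per-snapshot mode is provided as the alternative reading. The
packaged default table is synthetic (rising with age, low MMSE and
care-home residence); the survey-derived original is not public.

Cognitive impairment no dementia (CIND) is MMSE ≤ 20 without dementia, so
it can never overlap dementia by construction.

## Outputs

* **Prevalence / count tables** by year and age group (65–74, 75–84, 85+,
  65+): percentage of the alive stratum (1 dp) and counts scaled by the
  persons-per-sample-person factor (default 100), rounded to the nearest
  hundred. Rounding happens only at this reporting layer.
* **Multi-morbidity distributions** over {0, 1, 2, 3, 4+} conditions plus
  a 2+ aggregate, for two condition sets: the 9 diseases only, or diseases
  plus impairments (hearing, vision, CIND).
* **Percent change** between reported years, half-away-from-zero to 1 dp,
  computed on the scaled counts.
* **Mental ill-health overlap** (dementia, depression or CIND) within each
  morbidity-count category; by default the mental conditions count toward
  the category total, with a toggle to count "other" conditions only —
  the source description is ambiguous on this point.
* **Sullivan health expectancy** at 65 from a category-prevalence surface
  estimated from a snapshot, pooled over 5-year age bands (single-year
  cells are too noisy at reduced n; the last populated band extends to the
  terminal age), applied to the lifetable of the same calendar year.
* **Decomposition** of the 2015→2035 change in category years into
  mortality and prevalence components by symmetric two-way stepwise
  replacement: each component averages the two single-swap contrasts, so
  the split is order-independent and exactly additive. Only additivity and
  sign conventions are asserted; other decomposition algorithms differ at
  second order.

## Synthetic study conditions

Restricted survey microdata cannot ship with the package, so the
`synthetic` module defines the study conditions:

* base population default n = 30 000 (the full-scale design is a 1% sample
  of the national 35+ population, ≈303 589; n is configurable), with an
  England-2014-like age–sex structure, cohort-graded education, and
  logistic-in-age prevalence curves per condition whose intercepts are set
  so 65+ prevalence matches published 2015 magnitudes (arthritis ≈49%,
  hypertension ≈49%, cancer ≈13%, stroke ≈7%, …). Behaviours are linked to
  disease presence through odds multipliers (inactivity 1.4, obesity 1.5,
  current smoking 1.6) applied on the logit scale;
* a **ground-truth transition bundle** with hand-set, plausible
  coefficients (e.g. arthritis onset ≈6%/2y at 65 rising with age, stroke
  ≈0.3%/2y, strong own-state persistence for recoverable states), chosen
  once so that simulated 2015→2035 growth in 65+ multi-morbidity is of the
  published order (2+: ≈55→64%; 4+: ≈9→13%);
* a panel generator that applies the truth bundle either month-by-month
  with engine semantics (default, so fitting sees data generated exactly
  as production simulates) or as one interval-level draw at frozen wave-1
  covariates. Parameter-recovery tests use the interval mode: monthly
  generation with a drifting age covariate shifts the estimand slightly
  (ages seen during the 24 months average one year older than wave 1),
  which is a property of that data-generating choice, not of the fitting
  machinery under test. Coverage achieved: ≥90% of binary-model
  coefficients inside their fitted 95% CI at n = 50 000.

What the generator does **not** emulate: survey design weights, clustering,
non-response, item missingness, harmonisation artefacts, disease-dependent
mortality, care-home transitions, migration or births. Passing tests
demonstrate the correctness of the machinery under known dynamics, not the
real-world accuracy of any absolute prevalence level; absolute projections
require the restricted base data and the external mortality schedule.

## Numerical and design notes

* All randomness flows from named substreams of a single seed
  (`default_rng([seed, tag, …])` with non-zero tags — trailing-zero
  entropy words would alias the parent stream); replicate r of a run is
  reproducible in isolation.
* Monte-Carlo stability: across 10 replicates at n = 30 000 the range of
  65+ 2+ prevalence is ≈0.7 pp at 2015 and 2035 and ≈1.2 pp at mid-horizon
  2025, where transition flux (and hence per-individual outcome variance)
  peaks; the across-replicate sd scales as n^(−1/2), so at the full-scale
  design n the range would be ≈0.3 pp.
* Degenerate inputs are loud: constant outcomes, missing covariates
  (named), incomplete mortality schedules, uncovered allocation cells and
  empty strata all raise typed errors or warnings rather than propagating
  NaNs; empty reporting strata emit null rows, never divide by zero.
* Problem sizes in the tests (2 000–50 000 individuals, horizons of 1–21
  years) are chosen so the full suite exercises every contract at
  realistic scale while remaining quick to run.
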