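# Methods

`dm2burden` projects the burden of type-2 diabetes (DM2) in an aging
population along three tracks: growth and doubling time of the diabetic
elderly population, the diabetic share of hospitalization and outpatient
costs, and years of life lost to diabetes at age 60. Every input is
synthetic with known ground truth, so each estimator in the chain has a
recovery target. This note records the models, the parameter choices and
why they were made, and what the synthetic results do and do not show.

## Age grids

All tables live on abridged 5-year age grids ending in an open group:
`FULL_GRID` (0–4 … 95+) for mortality surfaces and life tables from birth,
`ADULT_GRID` (30–34 … 95+) for the prevalence projection (30 is the type-1
exclusion cutoff: only diagnoses at 30+ count as DM2), and `ELDERLY_GRID`
(60–64 … 95+) for cohort estimation and e60.

## Synthetic cohort

The generator emulates the *design* of a three-wave national aging cohort:
n = 2827 subjects aged 60+, baseline 2006, registry-linked mortality over
12 years of follow-up, lognormal survey weights normalized to mean 1
(dispersion 0.3 — plausible design-effect scale, no claim of fidelity to
any real survey's weighting). Two diabetes-assignment modes exist:

- **prescribed prevalence**: baseline status drawn per age group from a
  prevalence schedule; diagnosis ages imputed uniform(30, baseline age),
  the least-informative choice given only the 30+ filter;
- **incidence mode** (used by the analyses): first-diagnosis ages simulated
  from age 30 by a piecewise-exponential process on the incidence schedule,
  with no survival selection. Here prevalence, diagnosis ages and incidence
  are mutually consistent, making the incidence schedule an exact recovery
  target for the retrospective estimator.

Follow-up mortality is piecewise-exponential with the non-diabetic schedule
times a hazard ratio of 1.5 for (current) diabetics — mid-range for elderly
DM2 cohorts. Non-diabetics can convert during follow-up and switch hazard
at conversion. Among deaths of diabetic subjects, the death certificate
says "diabetes" with probability 0.25 (a per-age Bernoulli would work the
same way; a scalar is enough for what the life tables consume). Default
schedules (annual rates): incidence rises from 0.002 at 30–34 to 0.015 at
65–69 then declines; non-diabetic mortality is Gompertz-like from 0.010 at
60–64 to 0.30 at 95+.

## Rate estimation

"Longitudinal regression models" are operationalized as weighted
occurrence/exposure (person-years) estimation per age group — the saturated
piecewise-exponential model at its maximum likelihood. Retrospective
incidence exposure runs diabetes-free from 30 to min(diagnosis age,
baseline age), assuming no survival selection. Cause-specific hazards
(diabetes-caused vs other) share one exposure denominator, so they sum to
the all-cause rate exactly. Empty cells propagate as missing and must be
filled from a national schedule — never silently zero-filled. Central
rates convert to interval probabilities by q = n·m / (1 + (n − nax)·m),
capped at 1, with nax = n/2 in closed groups (the classical infant/child
adjustments matter only below age 5; the e0 tables accept an nax vector and
use 1.5 for ages 0–4).

## Population projection

The projection couples a cohort across a 5-year step. Writing d for the
5-year incidence risk per total person (annual rates convert by
d = 1 − exp(−5h); the incidence multipliers of the scenario sweep scale the
annual rate before conversion) and q for the 5-year death probability of
the diabetic population:

    forward:  N_{x+5}^d(Y+5) = N_x^d(Y) · s_x + N_x(Y) · d_x
    backward: N_x^d(Y)       = [N_{x+5}^d(Y+5) − N_x(Y) · d_x] / s_x

The two directions are exact algebraic inverses. Two readings of the
survival factor are implemented:

- `denominator="survival"` (default): s = 1 − q — diabetics survive the
  interval with probability 1 − q, incident cases are counted at the end of
  the interval. This is the demographically coherent reading.
- `denominator="product"`: s = 1 − d·q, the literal typeset form found in
  the source formula. It implies 5-year diabetic survival of ≈ 0.995 even
  at ages 90+, which drives elderly prevalence towards 1 within two
  decades; we read the product as a typesetting artifact of a superscript
  (q^d) and do not use it as the default, but it remains runnable, as does
  the choice of q (diabetic vs all-cause) via `formula_qx`.

Boundary behavior: entrants to the youngest group carry a fixed prevalence
(default: the baseline state's youngest-group prevalence). The open 95+
group keeps its own survivors and receives the 90–94 inflow; going
backward this terminal pair is underdetermined by one equation and is
closed by holding the open group's prevalence stationary across the step —
exact when the population sits at the constant-rates fixed point, an
approximation otherwise. Negative back-projected counts are floored at
zero with a warning; fractional persons are kept until report time.

Total populations are an exogenous input (null migration). The default
world uses a stable pyramid (each 5-year cohort 15% larger than the one
before it, aged under the all-cause schedule, which is the mixture of the
two strata at the default prevalence and hazard ratio) and a forward
totals series with constant entrant cohorts — the fertility-slowdown
regime whose aging inertia drives the growth of the diabetic stock.

Doubling time assumes constant linear (arithmetic) growth: the mean of the
per-period slopes of the series, divided into the reference-year size;
reported raw and at half-year granularity. Non-positive growth returns a
distinct "does not double" result, not an exception.

## Two-part cost model

Any-use is a maximum-likelihood logistic fit (IRLS, implemented in-module
and cross-checked against an external GLM in the tests); the positive part
defaults to saturated stratum means over diabetes status × age stratum
(60–69 / 70–79 / 80+), so the two-part expected value equals the empirical
stratum mean by construction. A log-linear Poisson intensity on
(count − 1) is available for coefficient-level questions. Reported stratum
means always use cell-level P(use) × E[count | use]; the regressions carry
the inferential summaries. Costs attach per episode via fixed 2011-USD
unit costs from the provider perspective (defaults: 1450 USD per
hospitalization episode, 52 USD per outpatient visit — plausible
middle-income-country provider costs); utilization patterns are held
constant over the horizon, so the diabetic cost share moves with projected
prevalence and is invariant to rescaling unit costs.

## Lee-Carter forecasting

log m(x,t) = a_x + b_x·k_t + ε, estimated by SVD of the row-centered
log-rate matrix with the original normalization (Σb = 1, Σk = 0; the sign
convention makes b non-negative on average). k_t is forecast as a random
walk with drift; the drift MLE is the mean first difference, its standard
error σ/√(T−1). Simulations resample the drift from its estimation
distribution by default, so the intervals carry trend uncertainty as well
as innovation noise; percentile surfaces are element-wise across
simulations (never analytic). A second-stage re-estimation of k_t to match
observed total deaths is implemented and switches on automatically when
deaths and exposures accompany the surface; the synthetic surfaces carry
rates only, so it is off in the analyses. Fits accept a calendar-year
window; the analyses use 1980–2010 and forecast 25 years to 2035,
excluding earlier decades whose one-off mortality declines should not be
allowed to repeat. A time-constant surface returns a flagged degenerate
fit (uniform b, k ≡ 0) instead of failing.

The default synthetic surface uses a drift of −0.3/yr with innovation
scale 0.3 and observation noise 0.01: with the default level and age
pattern this walks e0 from ≈ 77 (1980) to ≈ 80.6 (2010) to ≈ 82.9 (2035)
and e60 from ≈ 23.9 to ≈ 25.2 — the magnitude of a healthy
middle-income-country trajectory.

## Life tables and years of life lost

Abridged tables use radix 100,000, the q-conversion above, and close the
open group with L = l/m (so a constant-hazard table returns exactly 1/m).
Three e60 scenarios: (1) all-cause; (2) cause-deleted, m·(1 − f), with f
the age-specific fraction of deaths attributed to diabetes (time-constant
by assumption); (3) cause-deleted plus re-insertion of the diabetes-caused
hazard h from the cohort's competing-risks estimates, m·(1 − f) + h.
Deletion/re-insertion is applied to the forecast all-cause schedule at the
target year (the hazard-arithmetic reading); the alternative — forecasting
a separately fitted cause-deleted surface — is what the e0 stream uses, so
both orders are exercised. Years of life lost at 60 is e60(1) − e60(3),
reported signed (scenario 2 shows the sign can flip by construction), with
percentile intervals computed per simulated trajectory (at least 100
trajectories required). When h exceeds the deleted hazard f·m the ordering
e60(3) < e60(1) < e60(2) is forced by hazard monotonicity — the structure
the published table shows.

## Numerical choices and tolerances

- All randomness flows from one integer seed per call through a single
  `numpy.random.Generator`; the pipeline derives per-stage sub-seeds
  (< 2³¹) from the run seed. Fixed seed ⇒ bit-identical outputs.
- IRLS runs to a 1e-10 coefficient tolerance; variances are clipped at
  1e-10 to survive fitted probabilities near 0/1. Complete separation in a
  stratum is reported and the regression (not the cell means) is skipped.
- The life-table oracle in the tests integrates a smooth Gompertz hazard
  on a weekly grid; abridged e60 agrees within 0.05 years when the exact
  separation factors from the same hazard are supplied, within 0.1 with
  the n/2 default.
- The back-projection oracle burns the forward map into its fixed point
  before the microsimulated step, because the terminal-group closure is
  exact only there; at 100,000 persons the Monte-Carlo error per group is
  ≈ 0.5–1%, inside the 2% recovery check with margin.
- Forecast-interval calibration is checked over 200 seeded replicates: the
  realized latent index is simulated through the target year and the 95%
  interval must cover the YLL it implies in 95% ± 5% of replicates
  (measured: 95.0%).

## Problem sizes

The default analyses use the cohort at n = 2827, 1000 forecast
trajectories, and 5-year steps 1996–2026 with a 2035 forecast horizon.
Recovery tests use n = 50,000 cohorts (rates), n = 20,000 (two-part
models), 100,000 persons (back-projection oracle), 10 replicate surfaces
(Lee-Carter), and 200 replicates × 400 trajectories (coverage) — sizes at
which Monte-Carlo error is comfortably below each test's tolerance.

## What the synthetic world does and does not show

Passing tests show the machinery is correct: estimators recover the
generator's parameters, the projection inverts exactly, the life-table
arithmetic matches independent integration, and the forecast intervals are
calibrated. They do not show that any real population behaves like the
defaults. Known artifacts of the synthetic conditions, visible in the demo
outputs and deliberately left unpatched:

- The incidence-mode cohort has no survival selection at baseline, so its
  prevalence profile rises with age; the projection dynamics (diabetic
  excess mortality) would bend that profile down. Back-projecting from
  such a baseline therefore shows mildly *declining* prevalence into the
  baseline year, and the doubling time of the synthetic world
  (≈ 60–100 years) is far longer than an off-equilibrium real population
  would show. The scenario sweep's orderings — the tested structure — are
  unaffected.
- Back-projection amplifies noise at the oldest ages by 1/(1 − q) per
  step; with cohort-estimated mortality at 90+ this factor reaches ≈ 5–10.
  Real applications feed smoothed national schedules into those cells.
- Cost levels scale with the synthetic utilization coefficients and unit
  costs; only orderings (diabetic > non-diabetic per capita) and the
  share–prevalence link are meaningful.

## Limitations

No migration, no covariate-adjusted hazards, no payer/patient cost
perspective, no discounting, no uncertainty on the population projection
itself (only on the mortality forecast), and a single deleted/re-inserted
cause. The competing-risks "model hazard" is any age-indexed schedule; the
in-package producer is the cause-specific occurrence/exposure estimator.
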