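# dm2burden

Projection machinery for the burden of type-2 diabetes (DM2) in an aging
population: how fast the diabetic elderly population grows and doubles,
what share of hospitalization and outpatient costs it will carry, and how
many years of life diabetes removes at age 60.

It is written for demographers and health economists who need the full
chain — cohort-based rate estimation, illness-death population projection,
two-part healthcare cost models, Lee-Carter stochastic mortality
forecasting, and cause-deleted / competing-risks life tables — as tested,
reusable parts. All inputs are generated synthetically with known ground
truth, so every stage has a parameter-recovery test.

## The models

**Population projection.** With `d_x` the 5-year diabetes incidence risk
(per total person aged x to x+5) and `q_x` the 5-year death probability of
the diabetic population, a cohort's diabetic count evolves as

    N_{x+5}^d(Y+5) = N_x^d(Y) · (1 − q_x) + N_x(Y) · d_x

under null migration and constant rates; back-projection inverts this
exactly, and the doubling time N(ref)/r uses the mean linear growth r of
the back-projected series. Hypothetical scenarios scale incidence by
0.25–1.75.

**Costs.** Two-part models — logistic any-use × positive-count intensity —
give expected annual episodes per (diabetes status × age stratum), priced
at fixed 2011-USD per-episode unit costs (provider perspective) and held
constant over the horizon, so the diabetic cost share moves with projected
prevalence.

**Mortality and years of life lost.** Lee-Carter, log m(x,t) = a_x +
b_x·k_t, fitted by SVD on 1980–2010 and forecast 25 years with k_t a random
walk with drift (drift uncertainty included); intervals are simulation
percentiles. Abridged life tables on the forecast schedules give e0 and
e60 for three scenarios: all-cause, diabetes deleted (m·(1−f)), and
diabetes deleted plus the competing-risks model hazard re-inserted
(m·(1−f)+h). Years of life lost at 60 = e60(all) − e60(delete+re-insert).

## Worked example

The analysis is a numbered chain; each script prints what it found and
writes tables under `results/analysis/`:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_estimate_rates.py
python analysis/03_project_population.py
python analysis/04_project_costs.py
python analysis/05_forecast_mortality.py --seed 1
python analysis/06_years_of_life_lost.py --seed 1
```

With seed 1 this prints, among other things:

```
cohort: 2827 subjects, 1437 deaths, 28.7% diabetic at baseline
elderly incidence (per 1000 py): [14.5 14.5 12.6 11.1  7.8  5.3  4.8 10.5]
 year  diabetic_60plus  prevalence_60plus
 2006       137383.989              0.283
 2026       262729.759              0.309
hospitalizations: per-capita annual cost at 60-69, diabetic 431 vs non-diabetic 209 2011 USD
all-cause fit: drift -0.378 (se 0.049), sigma 0.267, first component explains 99.8% of variance
                  (1) e60 all-cause  2035 26.20 (25.52-26.84)
               (2) e60 deleting DM2  2035 26.69 (26.01-27.33)
(3) e60 deleting DM2 + model hazard  2035 25.08 (24.52-25.61)
         (1)-(3) years of life lost  2035    1.11 (1.00-1.22)
e0 in 2035: 84.40 all-cause, 84.90 deleting diabetes (+0.50 years)
```

Reading it: the estimated incidence tracks the generator's schedule
(14.5/1000 at 60–69); the diabetic elderly population nearly doubles by
2026 while prevalence moves 28→31%; diabetic per-capita hospitalization
cost is about twice the non-diabetic level; the fitted mortality trend
(−0.378 ± 0.049) covers the generating drift of −0.3 at 2 SE; and deleting
diabetes but re-inserting its competing-risks hazard costs 1.11 years of
e60 in 2035, with the scenario ordering e60(3) < e60(1) < e60(2) forced by
the re-inserted hazard exceeding the deleted one. The single-command
equivalent is `dm2burden.pipeline.run_pipeline(RunConfig(seed=1))`.

Magnitudes are properties of the synthetic world; see `docs/methods.md`
for which features carry over to real data and which do not.

## Layout

```
src/dm2burden/      agegrid, synthetic, rates, projection, costs,
                    leecarter, lifetables, pipeline
analysis/           numbered narrative drivers (the study, end to end)
tests/              unit, property and acceptance suites
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
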