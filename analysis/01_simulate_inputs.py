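#!/usr/bin/env python
"""Generate the synthetic study inputs.

Fabricates everything the downstream analyses need: a national-aging-study-style
elderly cohort (n = 2827, baseline 2006, ~12 years of mortality follow-up) with
diagnosis histories driven by the ground-truth incidence schedule, annual
hospitalization / outpatient counts from known two-part coefficients, a
1980-2010 all-cause mortality surface with Lee-Carter structure, the
companion diabetes-attributed death fractions, and a national population
table. Ground-truth parameters go to a YAML sidecar for the recovery suite.
"""

import argparse
from pathlib import Path

from dm2burden.pipeline import _subseeds
from dm2burden.synthetic import (
    default_cohort_spec,
    default_population_totals,
    default_surface_spec,
    default_utilization_coefs,
    generate_cohort,
    generate_mortality_surface,
    generate_utilization,
    write_cohort_csv,
    write_truth_yaml,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    s_cohort, s_hosp, s_outp, s_surface = _subseeds(seed, 6)[:4]

    cohort = generate_cohort(default_cohort_spec(seed=s_cohort, incidence_mode=True))
    coefs = default_utilization_coefs()
    for service, s_use in (("hospitalizations", s_hosp), ("outpatient_visits", s_outp)):
        cohort = generate_utilization(
            cohort, coefs[service]["participation"], coefs[service]["intensity"],
            seed=s_use, column=service,
        )
    write_cohort_csv(cohort, OUT / "cohort.csv")
    print(f"cohort: {len(cohort)} subjects, {int(cohort['died'].sum())} deaths, "
          f"{cohort['diabetic_at_baseline'].mean():.1%} diabetic at baseline")

    surf = generate_mortality_surface(default_surface_spec(seed=s_surface))
    surf.surface.to_csv(OUT / "mortality_surface.csv")
    write_truth_yaml(surf.truth, OUT / "truth.yaml")
    print(f"mortality surface: {surf.surface.m.shape[0]} age groups x "
          f"{surf.surface.m.shape[1]} years ({surf.surface.years[0]}-{surf.surface.years[-1]})")

    totals = default_population_totals()
    totals.to_csv(OUT / "population_2006.csv", index=False)
    elderly = totals[totals["age_start"] >= 60]["n_total"].sum()
    print(f"population 2006: {totals['n_total'].sum():,.0f} aged 30+, {elderly:,.0f} aged 60+")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
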