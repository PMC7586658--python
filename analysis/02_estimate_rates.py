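#!/usr/bin/env python
"""Estimate age-specific rates from the synthetic cohort.

Weighted occurrence/exposure estimation of: diabetes prevalence at baseline,
retrospective incidence from ages at diagnosis (30+, no-survival-selection
assumption), all-cause mortality of the diabetic stratum, and cause-specific
(diabetes vs other) hazards. Ages 30-59 come from the national-style
schedules, as cohort coverage starts at 60. Writes the combined rate table
the projection consumes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dm2burden.agegrid import ADULT_GRID, ELDERLY_GRID
from dm2burden.rates import (
    cause_specific_hazards,
    estimate_diabetic_mortality,
    estimate_incidence,
    estimate_prevalence,
    fill_missing,
    rate_table_to_csv,
)
from dm2burden.synthetic import (
    default_adult_incidence,
    default_adult_mortality,
    default_adult_prevalence,
    read_cohort_csv,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    prev = estimate_prevalence(cohort, ELDERLY_GRID)
    inc = estimate_incidence(cohort, ELDERLY_GRID)
    mort = estimate_diabetic_mortality(cohort, ELDERLY_GRID)
    dm2, other = cause_specific_hazards(cohort, ELDERLY_GRID)

    n_young = ADULT_GRID.n_groups - ELDERLY_GRID.n_groups
    adult = pd.DataFrame({"age_start": list(ADULT_GRID.starts),
                          "age_width": list(ADULT_GRID.widths)})
    nat_prev, nat_inc, nat_mort = (default_adult_prevalence(),
                                   default_adult_incidence(),
                                   default_adult_mortality())
    adult["prevalence"] = np.concatenate([nat_prev[:n_young], prev["prevalence"]])
    adult["incidence"] = np.concatenate([nat_inc[:n_young], inc["incidence"]])
    adult["m_diabetic"] = np.concatenate([nat_mort[:n_young], mort["m_diabetic"]])
    adult["m_allcause"] = nat_mort
    adult = fill_missing(adult, "prevalence", nat_prev)
    adult = fill_missing(adult, "incidence", nat_inc)
    adult = fill_missing(adult, "m_diabetic", nat_mort * 1.5)
    rate_table_to_csv(adult, OUT / "rates.csv")
    dm2.to_csv(OUT / "hazard_dm2_caused.csv", index=False)
    other.to_csv(OUT / "hazard_other_caused.csv", index=False)

    elderly = adult[adult["age_start"] >= 60]
    print("elderly prevalence by group:",
          np.round(elderly["prevalence"].to_numpy(), 3))
    print("elderly incidence (per 1000 py):",
          np.round(1000 * elderly["incidence"].to_numpy(), 1))
    print("diabetic mortality vs all-cause ratio:",
          np.round((elderly["m_diabetic"] / elderly["m_allcause"]).to_numpy(), 2))


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
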