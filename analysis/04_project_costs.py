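#!/usr/bin/env python
"""Two-part utilization models and the projected diabetic cost share.

Fits the two-part (any-use logistic x positive-count intensity) models for
hospitalizations and outpatient consultations, converts stratum means into
per-capita annual costs with fixed 2011-USD unit costs (provider
perspective), and attaches them to the projected population states. Under
constant utilization patterns the diabetic share of total cost rises exactly
when projected prevalence rises.
"""

import argparse
from pathlib import Path

import pandas as pd

from dm2burden.agegrid import ADULT_GRID
from dm2burden.costs import expected_cost_per_capita, fit_two_part, project_costs
from dm2burden.projection import PopulationState
from dm2burden.synthetic import default_unit_costs, read_cohort_csv

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SERVICES = ("hospitalizations", "outpatient_visits")


def load_states():
    states = []
    for path in sorted(OUT.glob("state_*.csv")):
        df = pd.read_csv(path)
        states.append(PopulationState(
            int(df["year"].iloc[0]), ADULT_GRID,
            df["n_total"].to_numpy(), df["n_diabetic"].to_numpy(),
        ))
    return sorted(states, key=lambda s: s.year)


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    states = load_states()
    unit = default_unit_costs()
    parts = []
    for service in SERVICES:
        fit = fit_two_part(cohort, service)
        pc = expected_cost_per_capita(fit, unit)
        pc.to_csv(OUT / f"per_capita_{service}.csv", index=False)
        proj = project_costs(states, pc, service)
        parts.append(proj)
        d60 = fit.mean_for(True, "60-69") * unit[service]
        n60 = fit.mean_for(False, "60-69") * unit[service]
        print(f"{service}: per-capita annual cost at 60-69, diabetic "
              f"{d60:.0f} vs non-diabetic {n60:.0f} 2011 USD")
    costs = pd.concat(parts, ignore_index=True)
    costs.to_csv(OUT / "cost_series.csv", index=False)
    for service in SERVICES:
        sub = costs[costs["service"] == service].set_index("year")
        print(f"{service}: diabetic share "
              f"{sub['diabetic_share'].iloc[0]:.1%} ({sub.index[0]}) -> "
              f"{sub['diabetic_share'].iloc[-1]:.1%} ({sub.index[-1]})")


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
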