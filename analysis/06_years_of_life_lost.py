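#!/usr/bin/env python
"""Life tables from the forecast rates; years of life lost to diabetes at 60.

Builds abridged life tables on the simulated forecast trajectories for three
scenarios at 2025 and 2035: (1) all-cause mortality, (2) diabetes deleted as
a cause of death, (3) diabetes deleted and the diabetes-caused hazard from
the cohort's competing-risks estimates re-inserted. Years of life lost at 60
is the e60 gap (1)-(3); 95% intervals come from the trajectory percentiles.
Also reports e0 for the two forecast streams.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dm2burden.agegrid import FULL_GRID
from dm2burden.leecarter import MortalitySurface, cause_deleted_surface, fit_lc, forecast
from dm2burden.lifetables import e_at_confidence_interval, life_expectancy, yll_confidence_interval
from dm2burden.pipeline import _subseeds
from dm2burden.synthetic import default_surface_spec

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int, n_sims: int) -> None:
    surface = MortalitySurface.from_csv(OUT / "mortality_surface.csv", FULL_GRID)
    f_full = default_surface_spec().diabetes_fraction_by_age
    s_all, s_del = _subseeds(seed, 6)[4:6]

    fc = forecast(fit_lc(surface, year_window=(1980, 2010)),
                  horizon=25, n_sims=n_sims, seed=s_all)
    fc_del = forecast(fit_lc(cause_deleted_surface(surface, f_full),
                             year_window=(1980, 2010)),
                      horizon=25, n_sims=n_sims, seed=s_del)

    mask60 = FULL_GRID.mask_from(60)
    f = f_full[mask60]
    dm2 = pd.read_csv(OUT / "hazard_dm2_caused.csv")
    h = dm2["m"].to_numpy(dtype=float)
    h = np.where(np.isfinite(h), h, f * fc.median[mask60, -1])
    fc60 = fc.subset_ages(60)

    rows = []
    for year in (2025, 2035):
        e1 = e_at_confidence_interval(fc60, year, at_age=60)
        sims = fc60.at_year(year).T
        grid60 = FULL_GRID.subset(60)
        e2v = life_expectancy(sims * (1 - f[:, None]), grid60, at_age=60)
        e3v = life_expectancy(sims * (1 - f[:, None]) + h[:, None], grid60, at_age=60)
        pct = lambda v: (float(np.median(v)), float(np.percentile(v, 2.5)),
                         float(np.percentile(v, 97.5)))
        yll = yll_confidence_interval(fc60, f, h, year)
        for label, trip in [("(1) e60 all-cause", e1),
                            ("(2) e60 deleting DM2", pct(e2v)),
                            ("(3) e60 deleting DM2 + model hazard", pct(e3v)),
                            ("(1)-(3) years of life lost", yll)]:
            rows.append({"forecast": label, "year": year, "estimate": trip[0],
                         "lower": trip[1], "upper": trip[2],
                         "cell": f"{trip[0]:.2f} ({trip[1]:.2f}-{trip[2]:.2f})"})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "table_e60_yll.csv", index=False)
    print(table[["forecast", "year", "cell"]].to_string(index=False))

    nax0 = np.array([1.5] + [2.5] * (FULL_GRID.n_groups - 2) + [np.nan])
    e0_all = life_expectancy(fc.median[:, -1], FULL_GRID, at_age=0, nax=nax0)
    e0_del = life_expectancy(fc_del.median[:, -1], FULL_GRID, at_age=0, nax=nax0)
    print(f"e0 in 2035: {e0_all:.2f} all-cause, {e0_del:.2f} deleting diabetes "
          f"(+{e0_del - e0_all:.2f} years)")
    yll35 = table[(table['year'] == 2035) &
                  (table['forecast'] == '(1)-(3) years of life lost')]['estimate'].iloc[0]
    print(f"years of life lost to diabetes at 60 in 2035: {yll35:.2f} "
          f"(~{yll35 * 12:.0f} months)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sims", type=int, default=1000)
    a = ap.parse_args()
    main(a.seed, a.n_sims)
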