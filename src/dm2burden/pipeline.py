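"""End-to-end orchestration: generate -> estimate -> project -> cost -> forecast -> life tables.

One :class:`RunConfig` (YAML-serializable) drives the whole run; every stage
writes its table into the run directory and a manifest records the config
hash and seed, so identical config+seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agegrid import ADULT_GRID, ELDERLY_GRID, FULL_GRID
from .costs import expected_cost_per_capita, fit_two_part, project_costs
from .leecarter import cause_deleted_surface, fit_lc, forecast
from .lifetables import e_at_confidence_interval, life_expectancy, yll_confidence_interval
from .projection import PopulationState, back_project, doubling_time, forward_project, prevalence_series, scenario_sweep
from .rates import cause_specific_hazards, estimate_diabetic_mortality, estimate_incidence, estimate_prevalence, fill_missing, rate_table_to_csv
from .synthetic import (
    DEFAULT_COHORT_GROWTH,
    default_adult_incidence,
    default_adult_mortality,
    default_adult_prevalence,
    default_cohort_spec,
    default_population_totals,
    default_surface_spec,
    default_unit_costs,
    default_utilization_coefs,
    generate_cohort,
    generate_mortality_surface,
    generate_utilization,
    historical_totals,
    project_totals,
    write_cohort_csv,
    write_truth_yaml,
)

log = logging.getLogger("dm2burden")

__all__ = ["RunConfig", "run_pipeline"]

SERVICES = ("hospitalizations", "outpatient_visits")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    n_subjects: int = 2827
    baseline_year: int = 2006
    horizon_year: int = 2026
    fit_years: tuple = (1980, 2010)
    forecast_horizon: int = 25
    n_sims: int = 1000
    ci_level: float = 95.0
    formula_qx: str = "diabetic"
    denominator: str = "survival"
    multipliers: tuple = (0.25, 0.50, 0.75, 1.00, 1.25, 1.50, 1.75)
    intensity: str = "saturated"
    weighted: bool = True
    target_years: tuple = (2025, 2035)

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.fit_years[1] + self.forecast_horizon <= self.fit_years[1]:
            raise ValueError("forecast horizon must extend past the fit window")
        if self.horizon_year <= self.baseline_year:
            raise ValueError("projection horizon must lie after the baseline year")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k in ("fit_years", "multipliers", "target_years"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subseeds(seed: int, n: int) -> list:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the in-memory results and
    writes all tables plus a manifest under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    s_cohort, s_hosp, s_outp, s_surface, s_forecast_all, s_forecast_del = _subseeds(config.seed, 6)
    results: dict = {}

    # -- stage 1: synthetic inputs -----------------------------------------
    log.info("stage synthetic: cohort n=%d seed=%d", config.n_subjects, s_cohort)
    spec = default_cohort_spec(seed=s_cohort, n_subjects=config.n_subjects, incidence_mode=True)
    spec.baseline_year = config.baseline_year
    cohort = generate_cohort(spec)
    coefs = default_utilization_coefs()
    cohort = generate_utilization(
        cohort, coefs["hospitalizations"]["participation"], coefs["hospitalizations"]["intensity"],
        seed=s_hosp, column="hospitalizations",
    )
    cohort = generate_utilization(
        cohort, coefs["outpatient_visits"]["participation"], coefs["outpatient_visits"]["intensity"],
        seed=s_outp, column="outpatient_visits",
    )
    write_cohort_csv(cohort, out / "cohort.csv")
    log.info("stage synthetic: %d rows, %d deaths", len(cohort), int(cohort["died"].sum()))

    surf_spec = default_surface_spec(seed=s_surface)
    surf = generate_mortality_surface(surf_spec)
    surf.surface.to_csv(out / "mortality_surface.csv")
    write_truth_yaml(surf.truth, out / "truth.yaml")
    results["cohort"] = cohort
    results["surface"] = surf

    # -- stage 2: rates -----------------------------------------------------
    prev_e = estimate_prevalence(cohort, ELDERLY_GRID, weighted=config.weighted)
    inc_e = estimate_incidence(cohort, ELDERLY_GRID, weighted=config.weighted)
    mort_e = estimate_diabetic_mortality(cohort, ELDERLY_GRID, weighted=config.weighted)
    dm2_e, other_e = cause_specific_hazards(cohort, ELDERLY_GRID, weighted=config.weighted)

    n_young = ADULT_GRID.n_groups - ELDERLY_GRID.n_groups
    adult = pd.DataFrame({"age_start": list(ADULT_GRID.starts), "age_width": list(ADULT_GRID.widths)})
    nat_prev = default_adult_prevalence()
    nat_inc = default_adult_incidence()
    nat_mort = default_adult_mortality()
    adult["prevalence"] = np.concatenate([nat_prev[:n_young], prev_e["prevalence"].to_numpy()])
    adult["incidence"] = np.concatenate([nat_inc[:n_young], inc_e["incidence"].to_numpy()])
    # diabetic mortality below 60 follows national all-cause levels
    adult["m_diabetic"] = np.concatenate([nat_mort[:n_young], mort_e["m_diabetic"].to_numpy()])
    adult["m_allcause"] = nat_mort
    adult = fill_missing(adult, "prevalence", nat_prev)
    adult = fill_missing(adult, "incidence", nat_inc)
    adult = fill_missing(adult, "m_diabetic", nat_mort * 1.5)  # HR-style fallback for empty cells
    rate_table_to_csv(adult, out / "rates.csv")
    results["rates"] = adult
    log.info("stage rates: elderly prevalence %.3f", float(np.average(
        prev_e["prevalence"].fillna(0.0),
        weights=default_population_totals()["n_total"].to_numpy()[n_young:])))

    # -- stage 3: projection ------------------------------------------------
    totals = default_population_totals()["n_total"].to_numpy()
    baseline = PopulationState(
        year=config.baseline_year, grid=ADULT_GRID,
        n_total=totals, n_diabetic=totals * adult["prevalence"].to_numpy(),
    )
    proj_kw = dict(formula_qx=config.formula_qx, denominator=config.denominator)
    b1 = back_project(baseline, adult, historical_totals(totals, DEFAULT_COHORT_GROWTH, 1), **proj_kw)
    b2 = back_project(b1, adult, historical_totals(totals, DEFAULT_COHORT_GROWTH, 2), **proj_kw)
    totals_by_year = project_totals(
        totals, adult["m_allcause"].to_numpy(),
        np.arange(config.baseline_year, config.horizon_year + 1, 5),
    )
    forward = forward_project(baseline, adult, totals_by_year, config.horizon_year, **proj_kw)
    series = [b2, b1] + forward
    dt = doubling_time([b2, b1, baseline], config.baseline_year)
    sweep = scenario_sweep(baseline, adult, config.multipliers, config.horizon_year, totals_by_year, **proj_kw)
    sweep.to_csv(out / "table2_scenarios.csv", index=False)
    prev_path = prevalence_series(series)
    fig2 = pd.DataFrame(
        {
            "year": [s.year for s in series],
            "diabetic_60plus": [s.diabetic_total(60) for s in series],
            "prevalence_60plus": prev_path.values,
        }
    )
    fig2.to_csv(out / "fig2_projection_series.csv", index=False)
    results.update(baseline_state=baseline, back_states=[b1, b2], forward_states=forward,
                   doubling=dt, sweep=sweep, fig2=fig2)
    log.info("stage projection: doubling time %.1f years", dt.years)

    # -- stage 4: costs -----------------------------------------------------
    unit = default_unit_costs()
    fig3_parts = []
    results["cost_fits"] = {}
    for service in SERVICES:
        fit = fit_two_part(cohort, service, intensity=config.intensity, weighted=config.weighted)
        pc = expected_cost_per_capita(fit, unit)
        proj = project_costs(series, pc, service)
        fig3_parts.append(proj)
        results["cost_fits"][service] = fit
    fig3 = pd.concat(fig3_parts, ignore_index=True)
    fig3.to_csv(out / "fig3_cost_series.csv", index=False)
    results["costs"] = fig3
    log.info("stage costs: %d rows", len(fig3))

    # -- stage 5: mortality forecast ----------------------------------------
    fitted = fit_lc(surf.surface, year_window=config.fit_years)
    fc_all = forecast(fitted, config.forecast_horizon, n_sims=config.n_sims,
                      seed=s_forecast_all, level=config.ci_level)
    deleted = cause_deleted_surface(surf.surface, surf.diabetes_fraction)
    fit_del = fit_lc(deleted, year_window=config.fit_years)
    fc_del = forecast(fit_del, config.forecast_horizon, n_sims=config.n_sims,
                      seed=s_forecast_del, level=config.ci_level)
    pd.DataFrame(fc_all.median, index=FULL_GRID.labels, columns=fc_all.years).to_csv(out / "forecast_median.csv")
    pd.DataFrame(fc_all.lower, index=FULL_GRID.labels, columns=fc_all.years).to_csv(out / "forecast_lower.csv")
    pd.DataFrame(fc_all.upper, index=FULL_GRID.labels, columns=fc_all.years).to_csv(out / "forecast_upper.csv")
    results.update(lc_fit=fitted, forecast_all=fc_all, forecast_deleted=fc_del)
    log.info("stage forecast: drift %.3f (se %.3f)", fitted.drift, fitted.se_drift)

    # -- stage 6: life tables and years of life lost -------------------------
    nax_full = np.array([1.5] + [2.5] * (FULL_GRID.n_groups - 2) + [np.nan])  # infant separation factor
    f_full = surf.diabetes_fraction
    mask60 = FULL_GRID.mask_from(60)
    f_eld = f_full[mask60]
    h_model = dm2_e["m"].to_numpy(dtype=float)
    # empty cells fall back to the registry-deleted level (net-zero re-insertion)
    med_2035 = fc_all.median[:, -1]
    h_fallback = f_eld * med_2035[mask60]
    h_model = np.where(np.isfinite(h_model), h_model, h_fallback)

    fc_eld = fc_all.subset_ages(60)
    results["dm2_fraction_elderly"] = f_eld
    results["h_model"] = h_model
    rows = []
    for year in config.target_years:
        e60_all = e_at_confidence_interval(fc_eld, year, at_age=60, level=config.ci_level)
        # scenario (2): registry deletion applied to the forecast schedules
        sims = fc_eld.at_year(year).T * (1.0 - f_eld[:, None])
        e2 = life_expectancy(sims, ELDERLY_GRID, at_age=60)
        e60_del = (float(np.median(e2)),
                   float(np.percentile(e2, (100 - config.ci_level) / 2)),
                   float(np.percentile(e2, 100 - (100 - config.ci_level) / 2)))
        sims3 = fc_eld.at_year(year).T * (1.0 - f_eld[:, None]) + h_model[:, None]
        e3 = life_expectancy(sims3, ELDERLY_GRID, at_age=60)
        e60_s3 = (float(np.median(e3)),
                  float(np.percentile(e3, (100 - config.ci_level) / 2)),
                  float(np.percentile(e3, 100 - (100 - config.ci_level) / 2)))
        yll = yll_confidence_interval(fc_eld, f_eld, h_model, year, level=config.ci_level)
        for label, trip in [
            ("(1) e60 all-cause", e60_all),
            ("(2) e60 deleting DM2", e60_del),
            ("(3) e60 deleting DM2 + model hazard", e60_s3),
            ("(1)-(3) years of life lost", yll),
        ]:
            rows.append({"forecast": label, "year": year,
                         "estimate": trip[0], "lower": trip[1], "upper": trip[2],
                         "cell": f"{trip[0]:.2f} ({trip[1]:.2f}-{trip[2]:.2f})"})
    table3 = pd.DataFrame(rows)
    table3.to_csv(out / "table3_e60_yll.csv", index=False)
    results["table3"] = table3

    # e0 streams (median forecast at the last horizon year)
    e0_all = float(life_expectancy(fc_all.median[:, -1], FULL_GRID, at_age=0, nax=nax_full))
    e0_del = float(life_expectancy(fc_del.median[:, -1], FULL_GRID, at_age=0, nax=nax_full))
    results["e0"] = {"all_cause_2035": e0_all, "delete_dm2_2035": e0_del}
    log.info("stage lifetables: e0 %.2f -> %.2f without DM2", e0_all, e0_del)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
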