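"""Back- and forward-projection of the diabetic population by age group.

The core recurrence links the diabetic count of a cohort across a 5-year
step: observed at age x+t in year Y, the cohort descends from age x in year
Y-t via

    N_x^d(Y-t) = [N_{x+t}^d(Y) - N_x(Y-t) * t_d_x] / (1 - t_d_x * t_q_x)

where t_d_x is the t-year incidence risk (new cases per total person) and
t_q_x the t-year death probability of the diabetic population. Forward
projection is the exact algebraic inverse, aging survivors and adding
incident cases, with entrants to the youngest group taken from a supplied
total-population series. Two readings of the denominator are supported
(see ``denominator``); migration is assumed null and rates constant in time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegrid import AgeGrid
from .rates import mx_to_qx

__all__ = [
    "PopulationState",
    "ScenarioSpec",
    "interval_risk",
    "back_project",
    "forward_project",
    "prevalence_series",
    "doubling_time",
    "DoublingResult",
    "scenario_sweep",
]

CANONICAL_MULTIPLIERS = (0.25, 0.50, 0.75, 1.00, 1.25, 1.50, 1.75)


@dataclass
class PopulationState:
    """Total and diabetic counts by age group at one calendar year."""

    year: int
    grid: AgeGrid
    n_total: np.ndarray
    n_diabetic: np.ndarray

    def __post_init__(self):
        self.n_total = np.asarray(self.n_total, dtype=float)
        self.n_diabetic = np.asarray(self.n_diabetic, dtype=float)
        if self.n_total.shape != (self.grid.n_groups,) or self.n_diabetic.shape != (self.grid.n_groups,):
            raise ValueError("counts must have one entry per age group")
        if np.any(self.n_total < 0) or np.any(self.n_diabetic < -1e-9):
            raise ValueError("negative population counts")
        if np.any(self.n_diabetic > self.n_total + 1e-6):
            warnings.warn("diabetic counts exceed totals in some groups; capping")
            self.n_diabetic = np.minimum(self.n_diabetic, self.n_total)

    @property
    def n_nondiabetic(self) -> np.ndarray:
        return self.n_total - self.n_diabetic

    def diabetic_total(self, min_age: int = 60) -> float:
        return float(self.n_diabetic[self.grid.mask_from(min_age)].sum())

    def population_total(self, min_age: int = 60) -> float:
        return float(self.n_total[self.grid.mask_from(min_age)].sum())

    def prevalence(self, min_age: int = 60) -> float:
        denom = self.population_total(min_age)
        if denom <= 0:
            raise ValueError("zero population denominator")
        return self.diabetic_total(min_age) / denom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": list(self.grid.starts),
                "age_width": list(self.grid.widths),
                "year": self.year,
                "n_total": self.n_total,
                "n_diabetic": self.n_diabetic,
                "n_nondiabetic": self.n_nondiabetic,
            }
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """A hypothetical incidence level: rates scaled by a positive multiplier."""

    incidence_multiplier: float
    label: str = ""

    def __post_init__(self):
        if self.incidence_multiplier <= 0:
            raise ValueError("incidence multiplier must be positive")


def interval_risk(annual_rate, t: float) -> np.ndarray:
    """Convert an annual rate h to the t-year risk 1 - exp(-t h)."""
    return 1.0 - np.exp(-t * np.asarray(annual_rate, dtype=float))


def _step_inputs(rates: pd.DataFrame, t: float, multiplier: float, formula_qx: str):
    """Interval incidence risk d and death probability q per age group."""
    h = rates["incidence"].to_numpy(dtype=float)
    if np.any(~np.isfinite(h)):
        raise ValueError("missing incidence rates (fill from a national table first)")
    d = interval_risk(h * multiplier, t)
    col = {"diabetic": "m_diabetic", "allcause": "m_allcause"}[formula_qx]
    m = rates[col].to_numpy(dtype=float)
    if np.any(~np.isfinite(m)):
        raise ValueError(f"missing {col} rates (fill from a national table first)")
    n = np.full_like(m, t)
    q = mx_to_qx(m, n, n / 2.0)
    return d, q


def _survival_factor(d, q, denominator: str):
    if denominator == "product":
        return 1.0 - d * q   # the recurrence as printed
    if denominator == "survival":
        return 1.0 - q       # the demographically literal reading
    raise ValueError("denominator must be 'product' or 'survival'")


def back_project(
    state: PopulationState,
    rates: pd.DataFrame,
    totals_prior: np.ndarray,
    t: int = 5,
    multiplier: float = 1.0,
    formula_qx: str = "diabetic",
    denominator: str = "survival",
) -> PopulationState:
    """One t-year step back: recover the diabetic population at year - t.

    The interior groups invert the cohort recurrence exactly. The terminal
    pair (last closed group feeding the open group, and the open group's own
    survivors) is underdetermined by one equation; it is closed by holding
    the open group's prevalence stationary across the step, which is exact
    when the population sits at the constant-rates fixed point.
    """
    grid = state.grid
    if t not in {int(w) for w in grid.widths[:-1]}:
        raise ValueError("step t must match the grid width")
    totals_prior = np.asarray(totals_prior, dtype=float)
    d, q = _step_inputs(rates, t, multiplier, formula_qx)
    s = _survival_factor(d, q, denominator)
    # the open group's factor is only ever a multiplier; we divide by the rest
    bad = np.where(s[:-1] <= 0)[0]
    if len(bad):
        raise ValueError(f"non-positive denominator in age group(s) {[grid.labels[i] for i in bad]}")

    L = grid.n_groups - 1
    nd_prev = np.empty(grid.n_groups)
    for i in range(L - 1):
        nd_prev[i] = (state.n_diabetic[i + 1] - totals_prior[i] * d[i]) / s[i]
    # open-group closure: stationary prevalence in the open group
    p_open = state.n_diabetic[L] / state.n_total[L] if state.n_total[L] > 0 else 0.0
    nd_prev[L] = p_open * totals_prior[L]
    nd_prev[L - 1] = (
        state.n_diabetic[L]
        - nd_prev[L] * s[L]
        - totals_prior[L] * d[L]
        - totals_prior[L - 1] * d[L - 1]
    ) / s[L - 1]

    if np.any(nd_prev < 0):
        warnings.warn("negative back-projected diabetic counts floored at 0")
        nd_prev = np.maximum(nd_prev, 0.0)
    return PopulationState(year=state.year - t, grid=grid, n_total=totals_prior, n_diabetic=nd_prev)


def _forward_step(
    state: PopulationState,
    totals_next: np.ndarray,
    d: np.ndarray,
    s: np.ndarray,
    entrant_prevalence: float,
) -> PopulationState:
    grid = state.grid
    L = grid.n_groups - 1
    nd = np.empty(grid.n_groups)
    nd[0] = totals_next[0] * entrant_prevalence
    for i in range(1, L):
        nd[i] = state.n_diabetic[i - 1] * s[i - 1] + state.n_total[i - 1] * d[i - 1]
    nd[L] = (
        state.n_diabetic[L - 1] * s[L - 1]
        + state.n_total[L - 1] * d[L - 1]
        + state.n_diabetic[L] * s[L]
        + state.n_total[L] * d[L]
    )
    t = int(grid.widths[0])
    return PopulationState(year=state.year + t, grid=grid, n_total=np.asarray(totals_next, dtype=float), n_diabetic=nd)


def forward_project(
    state: PopulationState,
    rates: pd.DataFrame,
    totals_by_year: dict,
    horizon_year: int,
    scenario: ScenarioSpec | None = None,
    t: int = 5,
    formula_qx: str = "diabetic",
    denominator: str = "survival",
    entrant_prevalence: float | None = None,
) -> list:
    """Project forward in t-year steps to ``horizon_year`` (inclusive).

    ``totals_by_year`` maps each needed calendar year to the total-population
    counts per age group (an exogenous forecast; no migration or fertility is
    modelled here). Diabetic entrants to the youngest group carry the
    baseline youngest-group prevalence unless ``entrant_prevalence`` is set.
    Returns the list of states, baseline first.
    """
    if horizon_year <= state.year:
        raise ValueError("horizon must lie after the baseline year")
    if (horizon_year - state.year) % t != 0:
        raise ValueError("horizon - baseline year must be divisible by the step")
    multiplier = scenario.incidence_multiplier if scenario is not None else 1.0
    d, q = _step_inputs(rates, t, multiplier, formula_qx)
    s = _survival_factor(d, q, denominator)
    if entrant_prevalence is None:
        entrant_prevalence = (
            state.n_diabetic[0] / state.n_total[0] if state.n_total[0] > 0 else 0.0
        )
    states = [state]
    cur = state
    for year in range(state.year + t, horizon_year + 1, t):
        if year not in totals_by_year:
            raise ValueError(f"total-population series missing year {year}")
        cur = _forward_step(cur, totals_by_year[year], d, s, entrant_prevalence)
        states.append(cur)
    return states


def prevalence_series(states, min_age: int = 60) -> pd.Series:
    """Prevalence among the population aged ``min_age``+ per calendar year."""
    return pd.Series(
        {s.year: s.prevalence(min_age) for s in states}, name=f"prevalence_{min_age}plus"
    ).sort_index()


@dataclass
class DoublingResult:
    doubles: bool
    years: float                  # raw value; inf if growth is not positive
    years_rounded: float          # nearest half-year, the table's granularity
    mean_slope: float             # persons per calendar year
    reference_size: float
    reference_year: int


def doubling_time(states, reference_year: int, min_age: int = 60) -> DoublingResult:
    """Years for the diabetic population to double under constant linear growth.

    The annualized absolute growth r averages the per-period slopes of the
    supplied series; doubling time is N(reference_year) / r (the time to add
    another N at constant arithmetic growth). Non-positive growth is
    signalled with ``doubles=False`` rather than an exception.
    """
    states = sorted(states, key=lambda s: s.year)
    if len(states) < 2:
        raise ValueError("need at least two states")
    sizes = np.array([s.diabetic_total(min_age) for s in states])
    years = np.array([s.year for s in states], dtype=float)
    slopes = np.diff(sizes) / np.diff(years)
    r = float(slopes.mean())
    ref = [s for s in states if s.year == reference_year]
    if not ref:
        raise ValueError(f"no state at reference year {reference_year}")
    n_ref = ref[0].diabetic_total(min_age)
    if n_ref <= 0:
        raise ValueError("reference diabetic population must be positive")
    if r <= 0:
        return DoublingResult(False, math.inf, math.inf, r, n_ref, reference_year)
    raw = n_ref / r
    return DoublingResult(True, raw, round(raw * 2.0) / 2.0, r, n_ref, reference_year)


def scenario_sweep(
    baseline_state: PopulationState,
    rates: pd.DataFrame,
    multipliers,
    horizon_year: int,
    totals_by_year: dict,
    min_age: int = 60,
    **kwargs,
) -> pd.DataFrame:
    """One forward projection per incidence multiplier, Table-2-shaped output.

    Columns: multiplier, size_at_horizon, prevalence_at_horizon,
    doubling_time_years (raw) and doubling_time_rounded (half-year grain),
    with doubling measured from the baseline year of each projected series.
    """
    rows = []
    for mult in multipliers:
        spec = ScenarioSpec(incidence_multiplier=float(mult), label=f"incidence x{mult:g}")
        states = forward_project(
            baseline_state, rates, totals_by_year, horizon_year, scenario=spec, **kwargs
        )
        dt = doubling_time(states, baseline_state.year, min_age=min_age)
        final = states[-1]
        rows.append(
            {
                "multiplier": float(mult),
                "label": spec.label,
                "size_at_horizon": final.diabetic_total(min_age),
                "prevalence_at_horizon": final.prevalence(min_age),
                "doubling_time_years": dt.years,
                "doubling_time_rounded": dt.years_rounded,
            }
        )
    return pd.DataFrame(rows)
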