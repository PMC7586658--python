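"""Synthetic inputs with known ground truth.

This module fabricates everything the projection pipeline consumes — an
elderly longitudinal cohort with survey weights and mortality follow-up, a
national population-count table, a historical mortality surface with
Lee-Carter structure plus an age-specific diabetes-attributed death
fraction, and per-person annual healthcare utilization — so that every
downstream estimator has a recovery target. It emulates the *design* of a
three-wave national aging cohort (baseline around 2005, registry-linked
deaths over ~12 years of follow-up); it makes no claim of matching any real
survey's marginal distributions.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per call; fixed seed implies bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegrid import ADULT_GRID, ELDERLY_GRID, FULL_GRID, AgeGrid
from .leecarter import MortalitySurface

__all__ = [
    "CohortSpec",
    "MortalitySurfaceSpec",
    "generate_cohort",
    "generate_mortality_surface",
    "generate_population_counts",
    "generate_utilization",
    "default_cohort_spec",
    "default_surface_spec",
    "default_population_totals",
    "default_unit_costs",
    "default_utilization_coefs",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_truth_yaml",
]


# --------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Parameters of the synthetic longitudinal cohort.

    If ``prevalence_by_age`` is given, baseline diabetes is assigned by those
    probabilities and diagnosis ages are imputed uniform(30, baseline age).
    If it is None, the whole diagnosis history is simulated retrospectively
    from ``incidence_by_age`` (piecewise-exponential first-diagnosis time
    from age 30, no survival selection), making the incidence schedule the
    exact recovery target of the incidence estimator.
    """

    n_subjects: int = 2827
    baseline_year: int = 2006
    age_range: tuple = (60, 104)
    sex_ratio: float = 0.525            # fraction female
    prevalence_by_age: np.ndarray | None = None   # per CohortSpec.grid group
    incidence_by_age: np.ndarray | None = None    # annual rate per grid group
    baseline_mortality_by_age: np.ndarray | None = None  # non-diabetic annual hazard
    hr_diabetes_mortality: float = 1.5
    diabetes_death_fraction: float = 0.25  # P(cause=diabetes | diabetic death)
    followup_years: float = 12.0
    weight_dispersion: float = 0.3
    age_concentration: float = 0.06     # exp decay of the baseline age pyramid
    grid: AgeGrid = field(default_factory=lambda: ELDERLY_GRID)
    seed: int = 0

    def validate(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.hr_diabetes_mortality <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.grid.n_groups == 0:
            raise ValueError("empty age grid")
        if not (0 < self.sex_ratio < 1):
            raise ValueError("sex_ratio must be in (0,1)")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")
        for name in ("prevalence_by_age", "incidence_by_age", "baseline_mortality_by_age"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != self.grid.n_groups:
                    raise ValueError(f"{name} must have one entry per grid group")
                if np.any(~np.isfinite(v)) or np.any(v < 0):
                    raise ValueError(f"{name} entries must be finite and >= 0")
                if name == "prevalence_by_age" and np.any(v > 1):
                    raise ValueError("prevalence must be in [0,1]")
                setattr(self, name, v)
        if not (0 <= self.diabetes_death_fraction <= 1):
            raise ValueError("diabetes_death_fraction must be in [0,1]")


def _first_event_age(entry, exit_, hazard_by_group, grid: AgeGrid, rng) -> np.ndarray:
    """Piecewise-exponential first-event ages on [entry, exit); NaN if none.

    ``hazard_by_group`` is an (n, G) matrix of per-subject, per-group annual
    hazards (rows may differ, e.g. by diabetes status).
    """
    from .rates import person_years

    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    py = person_years(entry, exit_, grid)
    inc = py * hazard_by_group
    cum = np.cumsum(inc, axis=1)
    total = cum[:, -1]
    e = rng.exponential(size=len(entry))
    event = e < total
    ages = np.full(len(entry), np.nan)
    if event.any():
        # first group where the cumulative hazard crosses the draw
        crossed = cum[event] >= e[event, None]
        g = np.argmax(crossed, axis=1)
        prev = np.where(g > 0, np.take_along_axis(cum[event], (g - 1)[:, None], axis=1)[:, 0], 0.0)
        rate = np.take_along_axis(hazard_by_group[event], g[:, None], axis=1)[:, 0]
        within = (e[event] - prev) / rate
        start_in_group = np.maximum(entry[event], np.array(grid.starts)[g])
        ages[event] = start_in_group + within
    return ages


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the longitudinal cohort described by ``spec``.

    Returns one row per subject with columns: id, weight, sex,
    age_at_baseline, diabetic_at_baseline, age_at_diagnosis,
    incident_diagnosis_age, died, age_at_death, cause_of_death,
    age_at_end_of_followup.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    grid = spec.grid

    lo, hi = spec.age_range
    years = np.arange(lo, hi + 1)
    pyramid = np.exp(-spec.age_concentration * (years - lo))
    pyramid /= pyramid.sum()
    ages = years[rng.choice(len(years), size=n, p=pyramid)] + rng.uniform(0, 1, size=n)
    ages = np.minimum(ages, hi + 0.999)

    sex = np.where(rng.uniform(size=n) < spec.sex_ratio, "female", "male")
    if spec.weight_dispersion > 0:
        w = rng.lognormal(mean=0.0, sigma=spec.weight_dispersion, size=n)
        w /= w.mean()
    else:
        w = np.ones(n)

    gi = grid.index_of(ages)

    # --- diabetes history ---------------------------------------------------
    diag_age = np.full(n, np.nan)
    if spec.prevalence_by_age is not None:
        p = spec.prevalence_by_age[gi]
        diabetic = rng.uniform(size=n) < p
        # least-informative imputation: uniform between the type-1 cutoff and baseline
        diag_age[diabetic] = rng.uniform(30.0, ages[diabetic])
    elif spec.incidence_by_age is not None:
        # retrospective simulation from age 30 on a grid extended down to 30
        retro_grid = AgeGrid.from_range(30, grid.starts[-1]) if grid.starts[0] > 30 else grid
        inc_full = np.zeros(retro_grid.n_groups)
        # incidence below the cohort grid follows the adult default ramp
        adult_inc = _DEFAULT_ADULT_INCIDENCE
        for k, s in enumerate(retro_grid.starts):
            if s >= grid.starts[0]:
                inc_full[k] = spec.incidence_by_age[grid.index_of(s)]
            else:
                inc_full[k] = adult_inc[ADULT_GRID.index_of(s)]
        haz = np.tile(inc_full, (n, 1))
        diag_age = _first_event_age(np.full(n, 30.0), ages, haz, retro_grid, rng)
        diabetic = np.isfinite(diag_age)
    else:
        diabetic = np.zeros(n, dtype=bool)

    # --- mortality follow-up ------------------------------------------------
    end_age = ages + spec.followup_years
    death_age = np.full(n, np.nan)
    incident_diag = np.full(n, np.nan)
    if spec.baseline_mortality_by_age is not None:
        base_m = spec.baseline_mortality_by_age
        hr = spec.hr_diabetes_mortality
        haz_nd = np.tile(base_m, (n, 1))
        haz_d = haz_nd * hr

        is_d = diabetic.copy()
        death_age[is_d] = _first_event_age(ages[is_d], end_age[is_d], haz_d[is_d], grid, rng)

        nd = ~diabetic
        if nd.any() and spec.incidence_by_age is not None:
            conv = _first_event_age(
                ages[nd], end_age[nd], np.tile(spec.incidence_by_age, (nd.sum(), 1)), grid, rng
            )
        else:
            conv = np.full(nd.sum(), np.nan)
        # phase 1: non-diabetic hazard until conversion (or end)
        phase1_end = np.where(np.isfinite(conv), conv, end_age[nd])
        d1 = _first_event_age(ages[nd], phase1_end, haz_nd[nd], grid, rng)
        death_nd = d1.copy()
        # phase 2: diabetic hazard from conversion to end, for converts who survived phase 1
        alive_conv = np.isfinite(conv) & ~np.isfinite(d1)
        if alive_conv.any():
            idx_nd = np.where(nd)[0]
            sub = idx_nd[alive_conv]
            d2 = _first_event_age(conv[alive_conv], end_age[sub], haz_d[sub], grid, rng)
            death_nd[alive_conv] = d2
            incident_diag[sub] = conv[alive_conv]
        converted = np.isfinite(conv)
        # converts who died before conversion never converted
        died_pre = np.isfinite(d1) & converted
        incident_only = converted & ~died_pre
        idx_nd = np.where(nd)[0]
        incident_diag[idx_nd[~incident_only]] = np.nan
        death_age[nd] = death_nd

    died = np.isfinite(death_age)
    diabetic_at_death = diabetic | np.isfinite(incident_diag)
    cause = np.full(n, None, dtype=object)
    dd = died & diabetic_at_death
    cause[dd] = np.where(
        rng.uniform(size=int(dd.sum())) < spec.diabetes_death_fraction, "diabetes", "other"
    )
    cause[died & ~diabetic_at_death] = "other"

    diag_all = diag_age.copy()
    take = np.isfinite(incident_diag)
    diag_all[take] = incident_diag[take]

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "weight": w,
            "sex": sex,
            "age_at_baseline": ages,
            "diabetic_at_baseline": diabetic,
            "age_at_diagnosis": np.where(diabetic, diag_age, np.nan),
            "incident_diagnosis_age": incident_diag,
            "died": died,
            "age_at_death": death_age,
            "cause_of_death": cause,
            "age_at_end_of_followup": end_age,
            "ever_diagnosis_age": diag_all,
        }
    )


# --------------------------------------------------------------------------
# mortality surface


@dataclass
class MortalitySurfaceSpec:
    """Ground-truth Lee-Carter structure for the historical mortality surface.

    log m(x,t) = ax + bx * kt + obs noise, with kt a random walk with drift.
    ``future_years`` extends the *latent* kt path beyond the observed window
    (no observed surface there) so forecast-calibration suites can compare
    against the realized continuation.
    """

    grid: AgeGrid = field(default_factory=lambda: FULL_GRID)
    years: np.ndarray = field(default_factory=lambda: np.arange(1980, 2011))
    true_ax: np.ndarray | None = None
    true_bx: np.ndarray | None = None
    true_drift: float = -0.3
    sigma_kt: float = 0.3
    obs_noise: float = 0.01
    diabetes_fraction_by_age: np.ndarray | None = None
    future_years: int = 0
    seed: int = 0

    def validate(self):
        if self.true_ax is None or self.true_bx is None:
            raise ValueError("true_ax and true_bx are required")
        self.true_ax = np.asarray(self.true_ax, dtype=float)
        self.true_bx = np.asarray(self.true_bx, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if len(self.true_ax) != self.grid.n_groups or len(self.true_bx) != self.grid.n_groups:
            raise ValueError("ax/bx must have one entry per age group")
        if abs(self.true_bx.sum() - 1.0) > 1e-8:
            raise ValueError("true_bx must sum to 1 (|sum - 1| <= 1e-8)")
        if self.sigma_kt < 0 or self.obs_noise < 0:
            raise ValueError("noise scales must be >= 0")
        if self.diabetes_fraction_by_age is not None:
            f = np.asarray(self.diabetes_fraction_by_age, dtype=float)
            if np.any(f < 0) or np.any(f >= 1):
                raise ValueError("diabetes fraction must lie in [0,1)")
            below30 = np.array(self.grid.starts) < 30
            if np.any(f[below30] != 0):
                raise ValueError("diabetes fraction must be 0 below age 30")
            self.diabetes_fraction_by_age = f


@dataclass
class SurfaceResult:
    surface: MortalitySurface
    diabetes_fraction: np.ndarray
    truth: dict


def generate_mortality_surface(spec: MortalitySurfaceSpec) -> SurfaceResult:
    """Simulate an all-cause log-rate surface with Lee-Carter structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_years = len(spec.years)
    total = n_years + spec.future_years
    steps = spec.true_drift + rng.normal(0.0, spec.sigma_kt, size=total - 1)
    kt = np.concatenate([[0.0], np.cumsum(steps)])
    kt_obs, kt_future = kt[:n_years], kt[n_years:]
    logm = spec.true_ax[:, None] + spec.true_bx[:, None] * kt_obs[None, :]
    if spec.obs_noise > 0:
        logm = logm + rng.normal(0.0, spec.obs_noise, size=logm.shape)
    surface = MortalitySurface(grid=spec.grid, years=spec.years.copy(), m=np.exp(logm))
    frac = (
        spec.diabetes_fraction_by_age
        if spec.diabetes_fraction_by_age is not None
        else np.zeros(spec.grid.n_groups)
    )
    truth = {
        "ax": spec.true_ax.copy(),
        "bx": spec.true_bx.copy(),
        "kt": kt_obs,
        "kt_future": kt_future,
        "drift": spec.true_drift,
        "sigma_kt": spec.sigma_kt,
        "obs_noise": spec.obs_noise,
    }
    return SurfaceResult(surface=surface, diabetes_fraction=frac, truth=truth)


# --------------------------------------------------------------------------
# population counts


def generate_population_counts(grid: AgeGrid, totals_by_age, year: int) -> pd.DataFrame:
    """National population counts N_x per age group for one calendar year."""
    totals = np.asarray(totals_by_age, dtype=float)
    if len(totals) != grid.n_groups:
        raise ValueError("one total per age group required")
    if np.any(totals < 0):
        raise ValueError("negative population counts")
    return pd.DataFrame(
        {
            "age_start": list(grid.starts),
            "age_width": list(grid.widths),
            "year": year,
            "n_total": totals,
        }
    )


# --------------------------------------------------------------------------
# utilization


def _design_matrix(cohort: pd.DataFrame):
    """Intercept + diabetic flag + coarse age-stratum dummies (60-69 ref)."""
    age = cohort["age_at_baseline"].to_numpy(dtype=float)
    dia = cohort["diabetic_at_baseline"].to_numpy(dtype=bool).astype(float)
    a70 = ((age >= 70) & (age < 80)).astype(float)
    a80 = (age >= 80).astype(float)
    X = np.column_stack([np.ones(len(cohort)), dia, a70, a80])
    names = ["intercept", "diabetic", "age_70_79", "age_80p"]
    return X, names


def _coef_vector(coefs: dict, names) -> np.ndarray:
    missing = [k for k in names if k not in coefs]
    if missing:
        raise ValueError(f"malformed coefficients, missing {missing}")
    return np.array([coefs[k] for k in names], dtype=float)


def generate_utilization(
    cohort: pd.DataFrame,
    participation_coefs: dict,
    intensity_coefs: dict,
    seed: int,
    column: str = "hospitalizations",
) -> pd.DataFrame:
    """Annual utilization counts via a two-part mechanism.

    count = Bernoulli(logistic(X beta)) * (1 + Poisson(exp(X gamma))).
    Returns a copy of the cohort with the new count column.
    """
    rng = np.random.default_rng(seed)
    X, names = _design_matrix(cohort)
    beta = _coef_vector(participation_coefs, names)
    gamma = _coef_vector(intensity_coefs, names)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    users = rng.uniform(size=len(cohort)) < p
    counts = np.zeros(len(cohort), dtype=int)
    counts[users] = 1 + rng.poisson(np.exp(X[users] @ gamma))
    out = cohort.copy()
    out[column] = counts
    return out


# --------------------------------------------------------------------------
# defaults: the study conditions every analysis and test runs under

_DEFAULT_ADULT_INCIDENCE = np.array(
    [0.002, 0.003, 0.005, 0.007, 0.010, 0.012, 0.014, 0.015, 0.014, 0.012, 0.010, 0.008, 0.006, 0.005]
)  # annual first-diagnosis rate, ADULT_GRID (30-34 ... 95+)

_DEFAULT_ADULT_PREVALENCE = np.array(
    [0.02, 0.03, 0.05, 0.08, 0.11, 0.15, 0.23, 0.22, 0.21, 0.20, 0.18, 0.16, 0.14, 0.12]
)  # prevalence declines with age within the elderly, as observed in the region

_DEFAULT_ELDERLY_MORTALITY = np.array(
    [0.010, 0.016, 0.025, 0.042, 0.070, 0.115, 0.185, 0.30]
)  # non-diabetic annual all-cause hazard, ELDERLY_GRID

_DEFAULT_ADULT_NONDIABETIC_MORTALITY = np.concatenate(
    [np.array([0.0012, 0.0015, 0.0020, 0.0030, 0.0045, 0.0065]), _DEFAULT_ELDERLY_MORTALITY]
)  # ADULT_GRID non-diabetic schedule (30-59 from national-style levels)

# national all-cause mortality = mixture of the two strata at the default
# prevalence profile and hazard ratio, so population totals age coherently
_DEFAULT_ADULT_MORTALITY = _DEFAULT_ADULT_NONDIABETIC_MORTALITY * (
    1.0 + _DEFAULT_ADULT_PREVALENCE * (1.5 - 1.0)
)

# plausible mid-1990s jump-off central death rates by 5-year group, 0-4 ... 95+
_DEFAULT_M0 = np.array(
    [0.003, 0.0003, 0.0003, 0.0006, 0.0010, 0.0012, 0.0014, 0.0017, 0.0022, 0.0032,
     0.0050, 0.0075, 0.011, 0.017, 0.027, 0.044, 0.072, 0.115, 0.18, 0.29]
)

_DEFAULT_BX_RAW = np.array(
    [3.0, 2.5, 2.2, 2.0, 1.8, 1.6, 1.4, 1.3, 1.2, 1.1, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5,
     0.45, 0.4, 0.35, 0.3]
)  # mortality decline loads on young ages, as in most fitted schedules

_DEFAULT_DM2_FRACTION = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.005, 0.008, 0.012, 0.018, 0.025, 0.032,
     0.040, 0.048, 0.055, 0.060, 0.062, 0.058, 0.050, 0.040]
)  # share of deaths attributed to diabetes, FULL_GRID; 0 below 30

def stable_population(
    grid: AgeGrid,
    m_allcause: np.ndarray,
    entrant: float = 340_000.0,
    cohort_growth: float = 0.15,
) -> np.ndarray:
    """Stable-population age pyramid consistent with a mortality schedule.

    Each 5-year cohort is ``(1 + cohort_growth)`` times larger than the one
    born 5 years earlier (historical population growth), and cohorts age
    under the all-cause schedule with 5-year survival exp(-5 m). The open
    group holds the survivors' remaining person-years, entrant/m steady-state.
    """
    m = np.asarray(m_allcause, dtype=float)
    surv = np.exp(-5.0 * m)
    n = np.empty(grid.n_groups)
    n[0] = entrant
    for i in range(1, grid.n_groups - 1):
        n[i] = n[i - 1] * surv[i - 1] / (1.0 + cohort_growth)
    # open group: geometric steady state of inflow under its own survival
    inflow = n[-2] * surv[-2] / (1.0 + cohort_growth)
    s_open = surv[-1] / (1.0 + cohort_growth)
    n[-1] = inflow / (1.0 - s_open)
    return n


def project_totals(
    base_totals: np.ndarray,
    m_allcause: np.ndarray,
    years: np.ndarray,
    entrant_growth: float = 0.0,
) -> dict:
    """Exogenous total-population forecast: age the pyramid, no migration.

    Entrant cohorts at the youngest group grow at ``entrant_growth`` per
    5-year step (0 = the fertility-slowdown regime that drives population
    aging). Returns {year: counts} including the base year.
    """
    m = np.asarray(m_allcause, dtype=float)
    surv = np.exp(-5.0 * m)
    out = {int(years[0]): np.asarray(base_totals, dtype=float).copy()}
    cur = out[int(years[0])]
    for y in years[1:]:
        nxt = np.empty_like(cur)
        nxt[0] = cur[0] * (1.0 + entrant_growth)
        nxt[1:-1] = cur[:-2] * surv[:-2]
        nxt[-1] = cur[-2] * surv[-2] + cur[-1] * surv[-1]
        out[int(y)] = nxt
        cur = nxt
    return out


def historical_totals(base_totals: np.ndarray, cohort_growth: float, steps_back: int) -> np.ndarray:
    """Pyramid ``steps_back`` 5-year steps before the base year of a stable
    population: the whole pyramid scales by (1+g)^-k."""
    return np.asarray(base_totals, dtype=float) / (1.0 + cohort_growth) ** steps_back


def default_cohort_spec(seed: int = 0, n_subjects: int = 2827, incidence_mode: bool = False) -> CohortSpec:
    """The canonical elderly-cohort conditions used by the analyses."""
    elderly = ELDERLY_GRID
    prev = None if incidence_mode else _DEFAULT_ADULT_PREVALENCE[-elderly.n_groups:]
    return CohortSpec(
        n_subjects=n_subjects,
        prevalence_by_age=prev,
        incidence_by_age=_DEFAULT_ADULT_INCIDENCE[-elderly.n_groups:],
        baseline_mortality_by_age=_DEFAULT_ELDERLY_MORTALITY.copy(),
        seed=seed,
    )


def default_surface_spec(seed: int = 0, **overrides) -> MortalitySurfaceSpec:
    bx = _DEFAULT_BX_RAW / _DEFAULT_BX_RAW.sum()
    kwargs = dict(
        true_ax=np.log(_DEFAULT_M0),
        true_bx=bx,
        diabetes_fraction_by_age=_DEFAULT_DM2_FRACTION.copy(),
        seed=seed,
    )
    kwargs.update(overrides)
    return MortalitySurfaceSpec(**kwargs)


DEFAULT_COHORT_GROWTH = 0.15  # historical growth per 5-year cohort


def default_population_totals() -> pd.DataFrame:
    """2006-style national counts on ADULT_GRID from the stable pyramid."""
    totals = stable_population(ADULT_GRID, _DEFAULT_ADULT_MORTALITY, cohort_growth=DEFAULT_COHORT_GROWTH)
    return generate_population_counts(ADULT_GRID, totals, 2006)


def default_adult_prevalence() -> np.ndarray:
    return _DEFAULT_ADULT_PREVALENCE.copy()


def default_adult_incidence() -> np.ndarray:
    return _DEFAULT_ADULT_INCIDENCE.copy()


def default_adult_mortality() -> np.ndarray:
    return _DEFAULT_ADULT_MORTALITY.copy()


def default_unit_costs() -> dict:
    """Per-episode provider costs in 2011 USD."""
    return {"hospitalizations": 1450.0, "outpatient_visits": 52.0}


def default_utilization_coefs() -> dict:
    """Ground-truth two-part coefficients per service (logit / log scale)."""
    return {
        "hospitalizations": {
            "participation": {"intercept": -2.0, "diabetic": 0.7, "age_70_79": 0.35, "age_80p": 0.7},
            "intensity": {"intercept": -1.05, "diabetic": 0.25, "age_70_79": 0.15, "age_80p": 0.3},
        },
        "outpatient_visits": {
            "participation": {"intercept": 1.1, "diabetic": 0.6, "age_70_79": 0.1, "age_80p": 0.2},
            "intensity": {"intercept": 1.25, "diabetic": 0.18, "age_70_79": 0.05, "age_80p": 0.08},
        },
    }


# --------------------------------------------------------------------------
# I/O


def write_cohort_csv(cohort: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["diabetic_at_baseline"] = df["diabetic_at_baseline"].astype(bool)
    df["died"] = df["died"].astype(bool)
    return df


def write_truth_yaml(truth: dict, path):
    """Ground-truth sidecar for parameter-recovery tests."""
    clean = {}
    for k, v in truth.items():
        clean[k] = v.tolist() if isinstance(v, np.ndarray) else v
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh)
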