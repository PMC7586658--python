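"""Age-specific rate estimation from a longitudinal cohort.

Prevalence, diabetes incidence (retrospectively reconstructed from age at
diagnosis), mortality of the diabetic stratum, and cause-specific hazards
are all estimated as weighted occurrence/exposure rates on an abridged age
grid — the saturated piecewise-exponential model, with survey weights.

Central death rates are converted to interval death probabilities with the
classical separation-factor relation q = n*m / (1 + (n - nax)*m).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .agegrid import AgeGrid

__all__ = [
    "mx_to_qx",
    "person_years",
    "estimate_prevalence",
    "estimate_incidence",
    "estimate_diabetic_mortality",
    "cause_specific_hazards",
    "rate_table_to_csv",
    "rate_table_from_csv",
    "fill_missing",
]

MIN_DIAGNOSIS_AGE = 30.0  # diagnoses below 30 are treated as type-1 and rejected


def mx_to_qx(m, n, nax=None):
    """Convert central death rate(s) m to interval death probabilities.

    q = n*m / (1 + (n - nax)*m) for closed intervals, capped at 1.
    Open intervals (``n`` = inf or nan) return 1 by life-table convention.

    Parameters
    ----------
    m : float or array
        Central death rate(s), per year, >= 0.
    n : float or array
        Interval width(s) in years; inf/nan marks the open interval.
    nax : float or array, optional
        Average years lived in the interval by those dying in it.
        Defaults to n/2. Must satisfy 0 < nax <= n.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(m < 0):
        raise ValueError("negative death rate")
    open_bin = ~np.isfinite(n)
    if nax is None:
        nax = np.where(open_bin, 1.0, n / 2.0)
    nax = np.asarray(nax, dtype=float)
    closed = ~open_bin
    if np.any((nax[closed] <= 0) | (nax[closed] > n[closed])):
        raise ValueError("separation factor nax must lie in (0, n]")
    with np.errstate(invalid="ignore"):
        q = np.where(closed, n * m / (1.0 + (n - nax) * m), 1.0)
    q = np.minimum(q, 1.0)
    if q.ndim == 0:
        return float(q)
    return q


def person_years(entry_age, exit_age, grid: AgeGrid) -> np.ndarray:
    """Years lived in each age group between entry and exit age, per subject.

    Returns an array of shape (n_subjects, n_groups). Exposure below the grid
    start is dropped; the open group absorbs everything above it.
    """
    entry = np.atleast_1d(np.asarray(entry_age, dtype=float))
    exit_ = np.atleast_1d(np.asarray(exit_age, dtype=float))
    if np.any(exit_ < entry):
        raise ValueError("exit age before entry age (negative person-years)")
    bounds = grid.boundaries()
    lo = np.maximum(entry[:, None], bounds[:-1][None, :])
    hi = np.minimum(exit_[:, None], bounds[1:][None, :])
    return np.clip(hi - lo, 0.0, None)


def _empty_table(grid: AgeGrid) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_start": list(grid.starts),
            "age_width": list(grid.widths),
        }
    )


def _weights(cohort: pd.DataFrame, weighted: bool) -> np.ndarray:
    if not weighted:
        return np.ones(len(cohort))
    w = cohort["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def estimate_prevalence(cohort: pd.DataFrame, grid: AgeGrid, weighted: bool = True) -> pd.DataFrame:
    """Weighted proportion diabetic at baseline per age group.

    Groups with zero weighted denominator come back as NaN (missing), never
    as zero: they must be filled from an external source before projection.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    w = _weights(cohort, weighted)
    if w.sum() == 0:
        raise ValueError("all-zero weights")
    idx = grid.index_of(cohort["age_at_baseline"].to_numpy(dtype=float))
    dia = cohort["diabetic_at_baseline"].to_numpy(dtype=bool)
    num = np.bincount(idx, weights=w * dia, minlength=grid.n_groups)
    den = np.bincount(idx, weights=w, minlength=grid.n_groups)
    out = _empty_table(grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prevalence"] = np.where(den > 0, num / den, np.nan)
    out["source"] = "cohort-estimated"
    return out


def estimate_incidence(cohort: pd.DataFrame, grid: AgeGrid, weighted: bool = True) -> pd.DataFrame:
    """Retrospective incidence from ages at diagnosis, per age group.

    Exposure for each subject runs diabetes-free from age 30 to
    min(diagnosis age, baseline age); events are the reported diagnoses,
    placed in the group where they occurred. Assumes no survival selection:
    the baseline sample stands in for the cohort that generated the
    diagnoses. Annual rates = weighted events / weighted person-years.
    """
    w = _weights(cohort, weighted)
    base = cohort["age_at_baseline"].to_numpy(dtype=float)
    diag = cohort["age_at_diagnosis"].to_numpy(dtype=float)  # NaN if never
    has = np.isfinite(diag)
    if np.any(diag[has] < MIN_DIAGNOSIS_AGE):
        raise ValueError("diagnosis age below 30 violates the type-1 exclusion filter")
    exit_age = np.where(has, np.minimum(diag, base), base)
    entry_age = np.full_like(exit_age, MIN_DIAGNOSIS_AGE)
    exit_age = np.maximum(exit_age, entry_age)
    py = person_years(entry_age, exit_age, grid)
    exposure = (py * w[:, None]).sum(axis=0)
    events = np.zeros(grid.n_groups)
    # only diagnoses before (or at) baseline enter the retrospective window
    retro = has & (diag <= base) & (diag >= grid.starts[0])
    if retro.any():
        gi = grid.index_of(diag[retro])
        events = np.bincount(gi, weights=w[retro], minlength=grid.n_groups)
    out = _empty_table(grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["incidence"] = np.where(exposure > 0, events / exposure, np.nan)
    out["events"] = events
    out["exposure"] = exposure
    out["source"] = "cohort-estimated"
    return out


def _followup_window(cohort: pd.DataFrame):
    base = cohort["age_at_baseline"].to_numpy(dtype=float)
    death = cohort["age_at_death"].to_numpy(dtype=float)  # NaN if alive
    end = cohort["age_at_end_of_followup"].to_numpy(dtype=float)
    died = np.isfinite(death)
    if np.any(death[died] <= base[died]):
        raise ValueError("death at or before baseline age")
    exit_age = np.where(died, death, end)
    return base, exit_age, died, death


def estimate_diabetic_mortality(cohort: pd.DataFrame, grid: AgeGrid, weighted: bool = True) -> pd.DataFrame:
    """All-cause occurrence/exposure death rates in the baseline-diabetic stratum."""
    dia = cohort["diabetic_at_baseline"].to_numpy(dtype=bool)
    sub = cohort.loc[dia]
    out = _empty_table(grid)
    if len(sub) == 0:
        out["m_diabetic"] = np.nan
        out["source"] = "cohort-estimated"
        return out
    w = _weights(sub, weighted)
    base, exit_age, died, death = _followup_window(sub)
    py = person_years(base, exit_age, grid)
    exposure = (py * w[:, None]).sum(axis=0)
    events = np.zeros(grid.n_groups)
    if died.any():
        gi = grid.index_of(death[died])
        events = np.bincount(gi, weights=w[died], minlength=grid.n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["m_diabetic"] = np.where(exposure > 0, events / exposure, np.nan)
    out["events"] = events
    out["exposure"] = exposure
    out["source"] = "cohort-estimated"
    return out


def cause_specific_hazards(cohort: pd.DataFrame, grid: AgeGrid, weighted: bool = True):
    """Cause-specific death rates (diabetes-caused vs any other cause).

    Both causes share the same person-years denominator, so the two rates
    sum exactly to the all-cause rate in every age group. Returns
    ``(diabetes_caused, other_caused)`` tables, each with an ``m`` column.
    """
    w = _weights(cohort, weighted)
    base, exit_age, died, death = _followup_window(cohort)
    cause = cohort["cause_of_death"].to_numpy(dtype=object)
    if died.any():
        missing = died & ~np.isin(cause, ["diabetes", "other"])
        if missing.any():
            raise ValueError("death lacking a cause flag")
    py = person_years(base, exit_age, grid)
    exposure = (py * w[:, None]).sum(axis=0)

    tables = []
    for label in ("diabetes", "other"):
        sel = died & (cause == label)
        events = np.zeros(grid.n_groups)
        if sel.any():
            gi = grid.index_of(death[sel])
            events = np.bincount(gi, weights=w[sel], minlength=grid.n_groups)
        t = _empty_table(grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            t["m"] = np.where(exposure > 0, events / exposure, np.nan)
        t["events"] = events
        t["exposure"] = exposure
        t["cause"] = label
        tables.append(t)
    return tables[0], tables[1]


def fill_missing(table: pd.DataFrame, column: str, fallback, source: str = "national") -> pd.DataFrame:
    """Fill NaN entries of ``column`` from a fallback per-group array.

    Missing groups are never silently zero-filled: they are replaced from an
    external (e.g. national) schedule, and the ``source`` tag records it.
    """
    out = table.copy()
    fallback = np.asarray(fallback, dtype=float)
    vals = out[column].to_numpy(dtype=float)
    miss = ~np.isfinite(vals)
    vals[miss] = fallback[miss]
    out[column] = vals
    if "source" in out.columns:
        src = out["source"].to_numpy(dtype=object)
        src[miss] = source
        out["source"] = src
    return out


def rate_table_to_csv(table: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def rate_table_from_csv(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    # inf widths survive the round trip as the string "inf"
    t["age_width"] = t["age_width"].astype(float)
    return t


def grid_from_table(table: pd.DataFrame) -> AgeGrid:
    widths = [math.inf if not np.isfinite(w) else w for w in table["age_width"]]
    return AgeGrid(tuple(int(s) for s in table["age_start"]), tuple(widths))
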