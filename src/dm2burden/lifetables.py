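"""Abridged period life tables, cause deletion, and years of life lost.

Tables are built from central death rates m_x on a 5-year abridged grid
with an open final group, radix 100,000. Cause deletion removes an
age-specific fraction of the all-cause rate; the competing-risks scenario
re-inserts a cause-specific hazard schedule on top of the deleted rates.
Years of life lost at 60 is the e60 gap between the all-cause table and the
deleted-plus-reinserted table; its confidence interval is read off the set
of simulated forecast trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegrid import AgeGrid
from .leecarter import ForecastSet
from .rates import mx_to_qx

__all__ = [
    "LifeTable",
    "build_life_table",
    "life_expectancy",
    "scenario_schedule",
    "yll_at_60",
    "yll_confidence_interval",
]

RADIX = 100_000.0


def _lifetable_columns(mx, grid: AgeGrid, nax=None):
    """Core arithmetic; mx may be (G,) or (G, S) for S parallel schedules."""
    mx = np.asarray(mx, dtype=float)
    vec = mx.ndim == 1
    if vec:
        mx = mx[:, None]
    if mx.shape[0] != grid.n_groups:
        raise ValueError("one rate per age group required")
    if np.any(mx[-1] <= 0):
        raise ValueError("open-group rate must be positive (table cannot close)")
    if np.any(mx < 0) or not np.all(np.isfinite(mx)):
        raise ValueError("rates must be finite and >= 0")
    n = np.array(grid.widths, dtype=float)
    if nax is None:
        nax = np.where(np.isfinite(n), n / 2.0, np.nan)
    nax = np.asarray(nax, dtype=float)
    qx = np.empty_like(mx)
    for s in range(mx.shape[1]):
        qx[:, s] = mx_to_qx(mx[:, s], n, np.where(np.isfinite(n), nax, 1.0))
    qx[-1, :] = 1.0
    px = 1.0 - qx
    lx = np.empty_like(mx)
    lx[0] = RADIX
    for i in range(1, len(n)):
        lx[i] = lx[i - 1] * px[i - 1]
    dx = lx * qx
    Lx = np.empty_like(mx)
    closed = np.isfinite(n)
    for i in range(len(n)):
        if closed[i]:
            Lx[i] = n[i] * (lx[i] - dx[i]) + nax[i] * dx[i]
        else:
            Lx[i] = np.where(lx[i] > 0, lx[i] / mx[i], 0.0)
    Tx = np.cumsum(Lx[::-1], axis=0)[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    cols = dict(mx=mx, nax=np.broadcast_to(nax[:, None], mx.shape), qx=qx, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex)
    if vec:
        cols = {k: v[:, 0] for k, v in cols.items()}
    return cols


@dataclass
class LifeTable:
    grid: AgeGrid
    table: pd.DataFrame  # columns x, n, mx, nax, qx, lx, ndx, nLx, Tx, ex

    def e_at(self, age: int) -> float:
        """Remaining life expectancy at the exact age opening a group."""
        if age not in self.grid.starts:
            raise ValueError(f"age {age} does not open a group of this grid")
        i = self.grid.starts.index(age)
        return float(self.table["ex"].iloc[i])

    @property
    def e0(self) -> float:
        return float(self.table["ex"].iloc[0])


def build_life_table(mx, grid: AgeGrid, nax=None) -> LifeTable:
    """Standard abridged life table from a schedule of central death rates.

    ``nax`` defaults to n/2 in closed groups (the adjustment schedules that
    matter at infant ages can be supplied explicitly for tables from birth);
    the open group is closed by nLx = lx / mx.
    """
    cols = _lifetable_columns(mx, grid, nax)
    df = pd.DataFrame(
        {
            "x": list(grid.starts),
            "n": list(grid.widths),
            "mx": cols["mx"],
            "nax": cols["nax"],
            "qx": cols["qx"],
            "lx": cols["lx"],
            "ndx": cols["dx"],
            "nLx": cols["Lx"],
            "Tx": cols["Tx"],
            "ex": cols["ex"],
        }
    )
    return LifeTable(grid=grid, table=df)


def life_expectancy(mx, grid: AgeGrid, at_age: int = 0, nax=None) -> np.ndarray | float:
    """e_x at the group opening ``at_age``; vectorized over trailing axes.

    ``mx`` of shape (G,) gives a float; (G, S) gives S values at once.
    """
    if at_age not in grid.starts:
        raise ValueError(f"age {at_age} does not open a group of this grid")
    cols = _lifetable_columns(mx, grid, nax)
    i = grid.starts.index(at_age)
    ex = cols["ex"]
    return float(ex[i]) if np.ndim(ex) == 1 else ex[i]


def scenario_schedule(all_cause_mx, dm2_fraction, dm2_model_hazard, label: str) -> np.ndarray:
    """Mortality schedule for one of the three life-expectancy scenarios.

    - ``all_cause``: the schedule untouched.
    - ``delete_dm2``: remove the registry-attributed diabetes share,
      mx * (1 - f).
    - ``delete_dm2_add_model``: remove the registry share and re-insert the
      diabetes-caused hazard from a competing-risks model,
      mx * (1 - f) + h.
    """
    mx = np.asarray(all_cause_mx, dtype=float)
    f = np.zeros_like(mx) if dm2_fraction is None else np.asarray(dm2_fraction, dtype=float)
    h = np.zeros_like(mx) if dm2_model_hazard is None else np.asarray(dm2_model_hazard, dtype=float)
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("cause fractions must lie in [0, 1)")
    if np.any(h < 0):
        raise ValueError("model hazard must be >= 0")
    if label == "all_cause":
        out = mx.copy()
    elif label == "delete_dm2":
        out = mx * (1.0 - f)
    elif label == "delete_dm2_add_model":
        out = mx * (1.0 - f) + h
    else:
        raise ValueError(f"unknown scenario label {label!r}")
    if out[-1] <= 0:
        raise ValueError("scenario schedule non-positive in open group")
    return out


def yll_at_60(table_all: LifeTable, table_scenario3: LifeTable) -> float:
    """Years of life lost to the cause: e60(all-cause) - e60(delete+re-insert).

    A negative value (scenario mortality below all-cause) is returned as-is.
    """
    if table_all.grid != table_scenario3.grid:
        raise ValueError("life tables built on different grids")
    return table_all.e_at(60) - table_scenario3.e_at(60)


def yll_confidence_interval(
    forecasts_all: ForecastSet,
    dm2_fraction,
    dm2_model_hazard,
    year: int,
    level: float = 95.0,
    nax=None,
):
    """Percentile interval for YLL at 60 across forecast trajectories.

    For each simulated all-cause schedule at ``year`` the all-cause and
    delete-plus-reinsert tables are built and their e60 gap recorded; the
    interval is the (alpha/2, 1-alpha/2) percentile band.
    Returns (median, lower, upper).
    """
    sims = forecasts_all.at_year(year)  # (n_sims, G)
    if sims.shape[0] < 100:
        raise ValueError("need at least 100 trajectories for an interval")
    grid = forecasts_all.grid
    f = np.asarray(dm2_fraction, dtype=float)
    h = np.asarray(dm2_model_hazard, dtype=float)
    mx_all = sims.T                                   # (G, n_sims)
    mx_s3 = mx_all * (1.0 - f[:, None]) + h[:, None]
    e_all = life_expectancy(mx_all, grid, at_age=60, nax=nax)
    e_s3 = life_expectancy(mx_s3, grid, at_age=60, nax=nax)
    yll = e_all - e_s3
    alpha = (100.0 - level) / 2.0
    return (
        float(np.median(yll)),
        float(np.percentile(yll, alpha)),
        float(np.percentile(yll, 100.0 - alpha)),
    )


def e_at_confidence_interval(forecasts: ForecastSet, year: int, at_age: int = 60, level: float = 95.0, nax=None):
    """Percentile interval for e_x at ``at_age`` across forecast trajectories."""
    sims = forecasts.at_year(year)
    ex = life_expectancy(sims.T, forecasts.grid, at_age=at_age, nax=nax)
    alpha = (100.0 - level) / 2.0
    return (
        float(np.median(ex)),
        float(np.percentile(ex, alpha)),
        float(np.percentile(ex, 100.0 - alpha)),
    )
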