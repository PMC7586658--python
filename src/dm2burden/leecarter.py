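"""Lee-Carter estimation and stochastic mortality forecasting.

The model is log m(x,t) = a_x + b_x k_t + eps, estimated by SVD of the
row-centered log-rate matrix under the original normalization
(sum b_x = 1, sum k_t = 0). The mortality index k_t is forecast as a random
walk with drift; simulated trajectories map back to rates, and median /
percentile surfaces are read off the simulation set. An optional
second-stage adjustment re-fits k_t year by year so the model reproduces
observed total deaths when deaths and exposures are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .agegrid import AgeGrid

__all__ = ["MortalitySurface", "LCFit", "ForecastSet", "fit_lc", "forecast", "cause_deleted_surface"]


@dataclass
class MortalitySurface:
    """Central death rates on an age grid x calendar years."""

    grid: AgeGrid
    years: np.ndarray
    m: np.ndarray                     # (n_ages, n_years), strictly positive
    deaths: np.ndarray | None = None
    exposures: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (self.grid.n_groups, len(self.years)):
            raise ValueError("surface dimensions inconsistent with grid/years")
        if not np.all(np.isfinite(self.m)) or np.any(self.m <= 0):
            raise ValueError("central death rates must be finite and strictly positive")

    def window(self, first: int | None = None, last: int | None = None) -> "MortalitySurface":
        """Restrict to a calendar-year window (e.g. drop pre-1980 declines)."""
        keep = np.ones(len(self.years), dtype=bool)
        if first is not None:
            keep &= self.years >= first
        if last is not None:
            keep &= self.years <= last
        return MortalitySurface(
            grid=self.grid,
            years=self.years[keep],
            m=self.m[:, keep],
            deaths=None if self.deaths is None else self.deaths[:, keep],
            exposures=None if self.exposures is None else self.exposures[:, keep],
        )

    def to_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.m, index=self.grid.labels, columns=self.years).to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: AgeGrid) -> "MortalitySurface":
        df = pd.read_csv(path, index_col=0)
        return cls(grid=grid, years=np.array([int(c) for c in df.columns]), m=df.to_numpy())


@dataclass
class LCFit:
    grid: AgeGrid
    years: np.ndarray
    ax: np.ndarray
    bx: np.ndarray          # sum = 1
    kt: np.ndarray          # sum = 0
    drift: float
    sigma: float            # innovation sd of the random walk
    se_drift: float
    explained_variance: float
    degenerate: bool = False

    def reconstruct(self) -> np.ndarray:
        return np.exp(self.ax[:, None] + self.bx[:, None] * self.kt[None, :])


@dataclass
class ForecastSet:
    grid: AgeGrid
    years: np.ndarray                 # forecast calendar years
    trajectories: np.ndarray          # (n_sims, n_ages, n_years)
    median: np.ndarray                # (n_ages, n_years)
    lower: np.ndarray
    upper: np.ndarray
    level: float
    seed: int

    def at_year(self, year: int) -> np.ndarray:
        """All simulated rate schedules for one calendar year: (n_sims, n_ages)."""
        j = int(np.where(self.years == year)[0][0])
        return self.trajectories[:, :, j]

    def subset_ages(self, min_age: int) -> "ForecastSet":
        """Restrict to age groups starting at or above ``min_age``."""
        mask = self.grid.mask_from(min_age)
        return ForecastSet(
            grid=self.grid.subset(min_age),
            years=self.years,
            trajectories=self.trajectories[:, mask, :],
            median=self.median[mask, :],
            lower=self.lower[mask, :],
            upper=self.upper[mask, :],
            level=self.level,
            seed=self.seed,
        )


def fit_lc(
    surface: MortalitySurface,
    year_window: tuple | None = None,
    adjust_to_deaths: bool | None = None,
) -> LCFit:
    """Estimate the Lee-Carter components of a mortality surface.

    ``year_window=(first, last)`` restricts the fit to those calendar years
    (used to honor exclusions of early decades with unrepeatable declines).
    ``adjust_to_deaths`` switches on the second-stage re-estimation of k_t to
    match observed total deaths; default is on exactly when the surface
    carries deaths and exposures.
    """
    if year_window is not None:
        surface = surface.window(*year_window)
    if len(surface.years) < 3:
        raise ValueError("need at least 3 years to fit")
    if surface.grid.n_groups < 2:
        raise ValueError("need at least 2 age groups to fit")

    logm = np.log(surface.m)
    ax = logm.mean(axis=1)
    Z = logm - ax[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if S[0] <= 1e-12 * max(1.0, np.abs(logm).max()):
        # constant-in-time surface: no trend to extract
        warnings.warn("degenerate (time-constant) surface; returning flat fit")
        G, T = Z.shape
        return LCFit(
            grid=surface.grid, years=surface.years, ax=ax,
            bx=np.full(G, 1.0 / G), kt=np.zeros(T),
            drift=0.0, sigma=0.0, se_drift=0.0,
            explained_variance=1.0, degenerate=True,
        )
    bx = U[:, 0]
    kt = S[0] * Vt[0, :]
    # sign convention: bx non-negative on average (mortality falls as kt falls)
    if bx.sum() < 0:
        bx, kt = -bx, -kt
    scale = bx.sum()
    bx = bx / scale
    kt = kt * scale
    explained = S[0] ** 2 / (S**2).sum()

    deaths, exposures = surface.deaths, surface.exposures
    if adjust_to_deaths is None:
        adjust_to_deaths = deaths is not None and exposures is not None
    if adjust_to_deaths:
        if deaths is None or exposures is None:
            raise ValueError("death-matching adjustment needs deaths and exposures")
        kt = _adjust_kt_to_deaths(ax, bx, kt, deaths, exposures)
        kt = kt - kt.mean()  # keep sum(kt)=0; absorb nothing into ax (mean shift is tiny)

    diffs = np.diff(kt)
    drift = float(diffs.mean())
    sigma = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    se_drift = sigma / np.sqrt(len(diffs)) if len(diffs) > 0 else 0.0
    return LCFit(
        grid=surface.grid, years=surface.years, ax=ax, bx=bx, kt=kt,
        drift=drift, sigma=sigma, se_drift=se_drift,
        explained_variance=float(explained),
    )


def _adjust_kt_to_deaths(ax, bx, kt, deaths, exposures) -> np.ndarray:
    """Second stage: per year, solve for kt matching total observed deaths."""
    out = kt.copy()
    for j in range(len(kt)):
        D = deaths[:, j].sum()

        def gap(k):
            return (exposures[:, j] * np.exp(ax + bx * k)).sum() - D

        lo, hi = out[j] - 50, out[j] + 50
        if gap(lo) * gap(hi) < 0:
            out[j] = brentq(gap, lo, hi, xtol=1e-10)
    return out


def forecast(
    fit: LCFit,
    horizon: int,
    n_sims: int = 1000,
    seed: int = 0,
    level: float = 95.0,
    drift_uncertainty: bool = True,
) -> ForecastSet:
    """Simulate the mortality index forward and map to rate surfaces.

    k_{T+h} follows a random walk with drift; when ``drift_uncertainty`` is
    on, each trajectory resamples its drift from N(drift, se_drift^2) so the
    intervals reflect estimation error of the trend as well as innovation
    noise. Percentile surfaces are elementwise across simulations.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if n_sims < 2:
        raise ValueError("need n_sims >= 2 for percentile intervals")
    rng = np.random.default_rng(seed)
    drifts = (
        rng.normal(fit.drift, fit.se_drift, size=n_sims)
        if drift_uncertainty and fit.se_drift > 0
        else np.full(n_sims, fit.drift)
    )
    eps = rng.normal(0.0, fit.sigma, size=(n_sims, horizon)) if fit.sigma > 0 else np.zeros((n_sims, horizon))
    steps = drifts[:, None] + eps
    kt_paths = fit.kt[-1] + np.cumsum(steps, axis=1)           # (n_sims, horizon)
    # rates: exp(ax + bx * kt) -> (n_sims, G, horizon)
    logm = fit.ax[None, :, None] + fit.bx[None, :, None] * kt_paths[:, None, :]
    traj = np.exp(logm)
    alpha = (100.0 - level) / 2.0
    med = np.median(traj, axis=0)
    lower = np.percentile(traj, alpha, axis=0)
    upper = np.percentile(traj, 100.0 - alpha, axis=0)
    years = fit.years[-1] + np.arange(1, horizon + 1)
    return ForecastSet(
        grid=fit.grid, years=years, trajectories=traj,
        median=med, lower=lower, upper=upper, level=level, seed=seed,
    )


def cause_deleted_surface(surface: MortalitySurface, fraction_by_age) -> MortalitySurface:
    """Proportionally remove one cause: m'(x,t) = m(x,t) * (1 - f(x))."""
    f = np.asarray(fraction_by_age, dtype=float)
    if len(f) != surface.grid.n_groups:
        raise ValueError("one fraction per age group required")
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("cause fractions must lie in [0, 1)")
    return MortalitySurface(grid=surface.grid, years=surface.years.copy(), m=surface.m * (1.0 - f[:, None]))
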