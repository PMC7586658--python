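"""Two-part healthcare-utilization models and cost projection.

Hospitalizations and outpatient consultations are modelled in two parts, as
is standard in health economics: a logistic model for any use in a calendar
year, and a positive-part intensity model for the number of episodes among
users. Expected annual episodes per (diabetes status x age stratum) times a
per-episode unit cost (provider perspective, fixed 2011 USD) give per-capita
costs, which attach to projected population states to yield total costs and
the diabetic share per year. Utilization patterns are held constant over the
projection horizon.

The GLM fits (logistic and Poisson, by iteratively reweighted least
squares) are implemented here directly; they are deliberately minimal —
intercept, diabetes indicator and coarse age strata (60-69 reference,
70-79, 80+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import _design_matrix

__all__ = [
    "TwoPartFit",
    "fit_two_part",
    "expected_cost_per_capita",
    "project_costs",
    "coarse_stratum",
    "STRATA",
]

STRATA = ("60-69", "70-79", "80+")
COEF_NAMES = ("intercept", "diabetic", "age_70_79", "age_80p")


def coarse_stratum(age) -> np.ndarray:
    """Map exact ages (or group start ages) to the cost strata."""
    age = np.asarray(age, dtype=float)
    out = np.where(age < 70, STRATA[0], np.where(age < 80, STRATA[1], STRATA[2]))
    return out


def _irls_glm(X, y, w, family: str, max_iter: int = 100, tol: float = 1e-10):
    """Weighted GLM by IRLS; returns (beta, covariance).

    family 'binomial': logit link on y in {0,1};
    family 'poisson': log link on counts >= 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            var = np.clip(mu * (1.0 - mu), 1e-10, None)
        elif family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            var = np.clip(mu, 1e-10, None)
        else:
            raise ValueError(family)
        z = eta + (y - mu) / var          # working response (canonical links)
        W = w * var
        WX = X * W[:, None]
        H = X.T @ WX
        beta_new = np.linalg.solve(H, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(H)
    return beta, cov


@dataclass
class TwoPartFit:
    service: str
    participation_coefs: dict | None      # logit scale; None on separation fallback
    participation_cov: np.ndarray | None
    intensity_coefs: dict | None          # log scale for the (count-1) mean; None if saturated
    intensity_cov: np.ndarray | None
    strata_means: pd.DataFrame            # diabetic, stratum, p_use, mean_given_use, mean
    separation: list = field(default_factory=list)

    def mean_for(self, diabetic: bool, stratum: str) -> float:
        t = self.strata_means
        row = t[(t["diabetic"] == diabetic) & (t["stratum"] == stratum)]
        if len(row) == 0:
            raise KeyError(f"missing stratum ({diabetic}, {stratum})")
        return float(row["mean"].iloc[0])


def fit_two_part(
    cohort: pd.DataFrame,
    service: str,
    intensity: str = "saturated",
    weighted: bool = True,
) -> TwoPartFit:
    """Fit the two-part utilization model for one service column.

    Part 1 is a maximum-likelihood logistic fit for any use; part 2 models
    episodes among users, either as saturated stratum means (default — the
    minimal assumption, making the two-part expected value identical to the
    empirical stratum mean) or as a log-linear fit on (count - 1)
    (``intensity='loglinear'``).

    ``strata_means`` always reports cell-level P(use) x E[episodes | use],
    so expected values per (diabetic x age stratum) never depend on the
    participation model being saturated.

    Complete separation in a cell (all-zero or all-positive use) is reported
    in ``separation`` and the participation regression is skipped; the cell
    empirical means still stand.
    """
    y = cohort[service].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("utilization counts must be >= 0")
    u = (y > 0).astype(float)
    w = cohort["weight"].to_numpy(dtype=float) if weighted else np.ones(len(cohort))
    dia = cohort["diabetic_at_baseline"].to_numpy(dtype=bool)
    strat = coarse_stratum(cohort["age_at_baseline"].to_numpy(dtype=float))

    rows, separation = [], []
    for d in (False, True):
        for s in STRATA:
            sel = (dia == d) & (strat == s)
            if sel.sum() == 0:
                continue
            ws = w[sel]
            p_use = float(np.average(u[sel], weights=ws))
            users = sel & (y > 0)
            mgu = float(np.average(y[users], weights=w[users])) if users.any() else 0.0
            if p_use in (0.0, 1.0):
                separation.append((d, s))
            rows.append({"diabetic": d, "stratum": s, "p_use": p_use, "mean_given_use": mgu})
    strata = pd.DataFrame(rows)

    beta_dict, cov = None, None
    if not separation:
        X, names = _design_matrix(cohort)
        beta, cov = _irls_glm(X, u, w, "binomial")
        beta_dict = dict(zip(names, beta))

    gamma_dict, gamma_cov = None, None
    if intensity == "loglinear":
        users = y > 0
        if users.sum() >= len(COEF_NAMES):
            X, names = _design_matrix(cohort.loc[users])
            gamma, gamma_cov = _irls_glm(X, y[users] - 1.0, w[users], "poisson")
            gamma_dict = dict(zip(names, gamma))
            # model-based positive mean per cell
            for i, row in strata.iterrows():
                x = np.array(
                    [1.0, float(row["diabetic"]),
                     1.0 if row["stratum"] == "70-79" else 0.0,
                     1.0 if row["stratum"] == "80+" else 0.0]
                )
                strata.loc[i, "mean_given_use"] = 1.0 + float(np.exp(x @ gamma))
    elif intensity != "saturated":
        raise ValueError("intensity must be 'saturated' or 'loglinear'")

    strata["mean"] = strata["p_use"] * strata["mean_given_use"]
    return TwoPartFit(
        service=service,
        participation_coefs=beta_dict,
        participation_cov=cov,
        intensity_coefs=gamma_dict,
        intensity_cov=gamma_cov,
        strata_means=strata,
        separation=separation,
    )


def expected_cost_per_capita(fit: TwoPartFit, unit_costs: dict) -> pd.DataFrame:
    """Per-person annual cost (2011 USD) per (diabetic x age stratum)."""
    if fit.service not in unit_costs:
        raise KeyError(f"no unit cost for service {fit.service!r}")
    c = float(unit_costs[fit.service])
    if c < 0:
        raise ValueError("unit cost must be >= 0")
    out = fit.strata_means.copy()
    out["service"] = fit.service
    out["annual_cost"] = out["mean"] * c
    return out[["service", "diabetic", "stratum", "mean", "annual_cost"]]


def project_costs(states, per_capita: pd.DataFrame, service: str) -> pd.DataFrame:
    """Total annual costs and diabetic share per projected year.

    Each state's 5-year groups aged 60+ are mapped to the cost strata; total
    cost = sum over groups of counts x per-capita cost, separately for the
    diabetic and non-diabetic populations. Utilization patterns (and hence
    per-capita costs) are held constant across years.
    """
    pc = per_capita[per_capita["service"] == service]

    def cost_of(diabetic: bool, stratum: str) -> float:
        row = pc[(pc["diabetic"] == diabetic) & (pc["stratum"] == stratum)]
        if len(row) == 0:
            raise KeyError(f"per-capita cost missing for ({diabetic}, {stratum})")
        return float(row["annual_cost"].iloc[0])

    rows = []
    for state in states:
        mask = state.grid.mask_from(60)
        starts = np.array(state.grid.starts)[mask]
        strata = coarse_stratum(starts)
        nd = state.n_diabetic[mask]
        nn = state.n_nondiabetic[mask]
        cost_d = float(sum(nd[i] * cost_of(True, strata[i]) for i in range(len(starts))))
        cost_n = float(sum(nn[i] * cost_of(False, strata[i]) for i in range(len(starts))))
        total = cost_d + cost_n
        rows.append(
            {
                "year": state.year,
                "service": service,
                "total_cost_diabetic": cost_d,
                "total_cost_nondiabetic": cost_n,
                "diabetic_share": cost_d / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
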