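import numpy as np
import pandas as pd
import pytest

from dm2burden.agegrid import ADULT_GRID, ELDERLY_GRID, AgeGrid
from dm2burden.synthetic import (
    CohortSpec,
    MortalitySurfaceSpec,
    default_surface_spec,
    generate_cohort,
    generate_mortality_surface,
    generate_population_counts,
    generate_utilization,
    read_cohort_csv,
    stable_population,
    write_cohort_csv,
)

FLAT_MORT = np.array([0.010, 0.016, 0.025, 0.042, 0.070, 0.115, 0.185, 0.30])


# ---------------------------------------------------------------------- cohort

def test_cohort_has_exactly_requested_size():
    spec = CohortSpec(n_subjects=2827, prevalence_by_age=np.full(8, 0.2), seed=0)
    assert len(generate_cohort(spec)) == 2827


def test_forced_prevalence_marks_everyone_diabetic_with_adult_onset():
    spec = CohortSpec(n_subjects=500, prevalence_by_age=np.ones(8), seed=1)
    c = generate_cohort(spec)
    assert c["diabetic_at_baseline"].all()
    assert (c["age_at_diagnosis"] >= 30.0).all()
    assert (c["age_at_diagnosis"] <= c["age_at_baseline"]).all()


def test_cohort_invariants_hold():
    spec = CohortSpec(n_subjects=4000, prevalence_by_age=np.full(8, 0.3),
                      incidence_by_age=np.full(8, 0.01),
                      baseline_mortality_by_age=FLAT_MORT, seed=2)
    c = generate_cohort(spec)
    assert (c["weight"] > 0).all()
    assert c["weight"].mean() == pytest.approx(1.0)
    died = c["died"]
    assert (c.loc[died, "age_at_death"] > c.loc[died, "age_at_baseline"]).all()
    assert c.loc[died, "cause_of_death"].isin(["diabetes", "other"]).all()
    assert c.loc[~died, "cause_of_death"].isna().all()
    # diabetes as a cause only ever strikes the diabetic
    dm2_deaths = died & (c["cause_of_death"] == "diabetes")
    assert (c.loc[dm2_deaths, "diabetic_at_baseline"]
            | np.isfinite(c.loc[dm2_deaths, "incident_diagnosis_age"])).all()


def test_fixed_seed_reproduces_cohort_and_surface_bit_identically():
    spec = lambda: CohortSpec(n_subjects=1000, prevalence_by_age=np.full(8, 0.25),
                              baseline_mortality_by_age=FLAT_MORT, seed=42)
    pd.testing.assert_frame_equal(generate_cohort(spec()), generate_cohort(spec()))
    a = generate_mortality_surface(default_surface_spec(seed=42))
    b = generate_mortality_surface(default_surface_spec(seed=42))
    np.testing.assert_array_equal(a.surface.m, b.surface.m)


def test_invalid_cohort_specs_rejected():
    with pytest.raises(ValueError):
        generate_cohort(CohortSpec(n_subjects=0))
    with pytest.raises(ValueError):
        generate_cohort(CohortSpec(n_subjects=10, hr_diabetes_mortality=0.0))
    with pytest.raises(ValueError):
        generate_cohort(CohortSpec(n_subjects=10, prevalence_by_age=np.full(8, 1.5)))


def test_equal_hazards_give_equal_death_proportions_across_strata():
    # hr = 1: diabetic and non-diabetic strata share one exponential model,
    # so their death proportions agree within binomial error
    spec = CohortSpec(n_subjects=30_000, prevalence_by_age=np.full(8, 0.5),
                      incidence_by_age=None,
                      baseline_mortality_by_age=FLAT_MORT,
                      hr_diabetes_mortality=1.0, weight_dispersion=0.0, seed=3)
    c = generate_cohort(spec)
    p = c.groupby("diabetic_at_baseline")["died"].mean()
    n = c.groupby("diabetic_at_baseline")["died"].size()
    se = np.sqrt(sum(p * (1 - p) / n))
    assert abs(p[True] - p[False]) < 3 * se


def test_empirical_prevalence_converges_to_schedule():
    target = np.array([0.23, 0.22, 0.21, 0.20, 0.18, 0.16, 0.14, 0.12])
    spec = CohortSpec(n_subjects=50_000, prevalence_by_age=target,
                      weight_dispersion=0.0, seed=4)
    c = generate_cohort(spec)
    gi = ELDERLY_GRID.index_of(c["age_at_baseline"].to_numpy())
    for k in range(8):
        sel = gi == k
        if sel.sum() < 200:
            continue
        phat = c.loc[sel, "diabetic_at_baseline"].mean()
        se = np.sqrt(target[k] * (1 - target[k]) / sel.sum())
        assert abs(phat - target[k]) < 3 * se


# --------------------------------------------------------------------- surface

def test_noiseless_driftless_surface_is_constant_at_exp_ax():
    spec = default_surface_spec(seed=0, true_drift=0.0, sigma_kt=0.0, obs_noise=0.0)
    res = generate_mortality_surface(spec)
    expected = np.exp(spec.true_ax)
    for j in range(res.surface.m.shape[1]):
        np.testing.assert_allclose(res.surface.m[:, j], expected, rtol=1e-12)


def test_pure_drift_surface_declines_linearly_with_slope_drift_times_bx():
    spec = default_surface_spec(seed=0, true_drift=-0.5, sigma_kt=0.0, obs_noise=0.0)
    res = generate_mortality_surface(spec)
    logm = np.log(res.surface.m)
    # closed form: log m(x,t) = ax + bx * (-0.5 t)
    t = np.arange(logm.shape[1])
    for i in (0, 7, 19):
        slopes = np.diff(logm[i])
        np.testing.assert_allclose(slopes, -0.5 * spec.true_bx[i], rtol=1e-9)
    assert logm.shape[1] == 31          # default window 1980-2010


def test_surface_rejects_unnormalized_bx_and_bad_fractions():
    spec = default_surface_spec(seed=0)
    spec.true_bx = spec.true_bx * 1.01
    with pytest.raises(ValueError):
        generate_mortality_surface(spec)
    spec2 = default_surface_spec(seed=0)
    frac = spec2.diabetes_fraction_by_age
    frac[0] = 0.5                        # nonzero below age 30
    with pytest.raises(ValueError):
        generate_mortality_surface(spec2)


def test_latent_index_extends_into_future_years():
    res = generate_mortality_surface(default_surface_spec(seed=9, future_years=25))
    assert len(res.truth["kt_future"]) == 25
    assert res.surface.m.shape[1] == 31  # observed window unchanged


# ----------------------------------------------------------- population counts

def test_population_counts_validation_and_identity():
    zero = generate_population_counts(ELDERLY_GRID, np.zeros(8), 2006)
    assert (zero["n_total"] == 0).all()
    one = generate_population_counts(ELDERLY_GRID, [1000, 0, 0, 0, 0, 0, 0, 0], 2006)
    assert one["n_total"].iloc[0] == 1000
    with pytest.raises(ValueError):
        generate_population_counts(ELDERLY_GRID, [-1] * 8, 2006)


def test_elderly_share_arithmetic():
    # 13% of a 5.1-million population aged 60+: totals built to that share
    share_profile = np.array([0.30, 0.24, 0.18, 0.12, 0.08, 0.05, 0.02, 0.01])
    totals = 0.13 * 5_100_000 * share_profile
    table = generate_population_counts(ELDERLY_GRID, totals, 2020)
    assert table["n_total"].sum() == pytest.approx(663_000)


def test_stable_population_declines_with_age():
    n = stable_population(ADULT_GRID, np.full(14, 0.02), entrant=1000.0, cohort_growth=0.1)
    assert (np.diff(n[:-1]) < 0).all()
    assert n[0] == 1000.0


# ------------------------------------------------------------------ utilization

def _cohort_for_utilization(n, seed=0):
    spec = CohortSpec(n_subjects=n, prevalence_by_age=np.full(8, 0.4),
                      weight_dispersion=0.0, seed=seed)
    return generate_cohort(spec)


def test_zero_participation_gives_all_zero_counts():
    c = _cohort_for_utilization(2000)
    out = generate_utilization(c, {"intercept": -50, "diabetic": 0, "age_70_79": 0, "age_80p": 0},
                               {"intercept": 0, "diabetic": 0, "age_70_79": 0, "age_80p": 0},
                               seed=1, column="hospitalizations")
    assert (out["hospitalizations"] == 0).all()


def test_full_participation_mean_matches_one_plus_intensity():
    c = _cohort_for_utilization(40_000)
    gamma0 = np.log(0.8)
    out = generate_utilization(c, {"intercept": 50, "diabetic": 0, "age_70_79": 0, "age_80p": 0},
                               {"intercept": gamma0, "diabetic": 0, "age_70_79": 0, "age_80p": 0},
                               seed=2, column="visits")
    mean, expect = out["visits"].mean(), 1.0 + 0.8
    se = out["visits"].std() / np.sqrt(len(out))
    assert abs(mean - expect) < 3 * se


def test_positive_diabetic_coefficient_raises_diabetic_utilization():
    c = _cohort_for_utilization(30_000)
    out = generate_utilization(c, {"intercept": -1.5, "diabetic": 0.7, "age_70_79": 0, "age_80p": 0},
                               {"intercept": -1.0, "diabetic": 0.3, "age_70_79": 0, "age_80p": 0},
                               seed=3, column="hosp")
    means = out.groupby("diabetic_at_baseline")["hosp"].mean()
    assert means[True] > means[False]


def test_malformed_coefficients_rejected():
    c = _cohort_for_utilization(50)
    with pytest.raises(ValueError):
        generate_utilization(c, {"intercept": 0.0}, {"intercept": 0.0, "diabetic": 0,
                             "age_70_79": 0, "age_80p": 0}, seed=0)


# -------------------------------------------------------------------------- I/O

def test_cohort_round_trips_through_csv(tmp_path):
    spec = CohortSpec(n_subjects=200, prevalence_by_age=np.full(8, 0.3),
                      baseline_mortality_by_age=FLAT_MORT, seed=6)
    c = generate_cohort(spec)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(c, path)
    back = read_cohort_csv(path)
    assert len(back) == len(c)
    np.testing.assert_array_equal(back["diabetic_at_baseline"], c["diabetic_at_baseline"])
    np.testing.assert_allclose(back["age_at_death"], c["age_at_death"])
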