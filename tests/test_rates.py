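import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dm2burden.agegrid import ELDERLY_GRID, AgeGrid
from dm2burden.rates import (
    cause_specific_hazards,
    estimate_diabetic_mortality,
    estimate_incidence,
    estimate_prevalence,
    grid_from_table,
    mx_to_qx,
    person_years,
    rate_table_from_csv,
    rate_table_to_csv,
)
from dm2burden.synthetic import CohortSpec, generate_cohort

from conftest import make_cohort


# --------------------------------------------------------------------- mx_to_qx

def test_mx_to_qx_closed_form_and_edges():
    assert mx_to_qx(0.0, 5.0, 2.5) == 0.0
    # q = n m / (1 + (n - nax) m) = 0.1 / 1.05
    assert mx_to_qx(0.02, 5.0, 2.5) == pytest.approx(0.1 / 1.05)
    assert mx_to_qx(50.0, 5.0, 2.5) == 1.0          # capped
    assert mx_to_qx(0.3, np.inf) == 1.0             # open interval convention
    with pytest.raises(ValueError):
        mx_to_qx(-0.1, 5.0, 2.5)
    with pytest.raises(ValueError):
        mx_to_qx(0.1, 5.0, 6.0)                     # nax outside (0, n]


@given(st.floats(min_value=0.0, max_value=2.0), st.floats(min_value=1e-6, max_value=2.0))
def test_mx_to_qx_monotone_in_m(m, dm):
    assert mx_to_qx(m + dm, 5.0, 2.5) >= mx_to_qx(m, 5.0, 2.5)


@given(st.floats(min_value=1e-6, max_value=0.0199))
def test_mx_to_qx_matches_exponential_for_small_nm(m):
    # n*m < 0.1: the separation-factor relation tracks 1 - exp(-n m) within 1%
    q = mx_to_qx(m, 5.0, 2.5)
    q_exp = 1.0 - np.exp(-5.0 * m)
    assert abs(q - q_exp) / q_exp < 0.01


# ----------------------------------------------------------------- person-years

def test_person_years_splits_exposure_across_groups():
    py = person_years([62.0], [73.5], ELDERLY_GRID)
    assert py[0, 0] == pytest.approx(3.0)   # 62 -> 65
    assert py[0, 1] == pytest.approx(5.0)   # 65 -> 70
    assert py[0, 2] == pytest.approx(3.5)   # 70 -> 73.5
    assert py[0, 3:].sum() == 0.0
    with pytest.raises(ValueError):
        person_years([70.0], [65.0], ELDERLY_GRID)


# ------------------------------------------------------------------- prevalence

def test_prevalence_all_diabetic_is_one_in_populated_groups():
    c = make_cohort({"age_at_baseline": np.array([61.0, 72.0, 88.0]),
                     "diabetic_at_baseline": np.array([True, True, True])})
    t = estimate_prevalence(c, ELDERLY_GRID)
    vals = t["prevalence"].to_numpy()
    assert np.allclose(vals[[0, 2, 5]], 1.0)
    assert np.isnan(vals[1])                 # empty group is missing, not zero


def test_prevalence_hand_count():
    c = make_cohort({"age_at_baseline": np.array([61.0, 62.0, 71.0, 72.0]),
                     "diabetic_at_baseline": np.array([True, False, True, True])})
    t = estimate_prevalence(c, ELDERLY_GRID)
    assert t["prevalence"].iloc[0] == pytest.approx(0.5)
    assert t["prevalence"].iloc[2] == pytest.approx(1.0)


def test_prevalence_respects_weights():
    c = make_cohort({"age_at_baseline": np.array([61.0, 62.0]),
                     "diabetic_at_baseline": np.array([True, False]),
                     "weight": np.array([3.0, 1.0])})
    t = estimate_prevalence(c, ELDERLY_GRID)
    assert t["prevalence"].iloc[0] == pytest.approx(0.75)
    assert estimate_prevalence(c, ELDERLY_GRID, weighted=False)["prevalence"].iloc[0] == pytest.approx(0.5)


def test_prevalence_rejects_empty_and_nonpositive_weights():
    with pytest.raises(ValueError):
        estimate_prevalence(make_cohort({"age_at_baseline": np.array([])}), ELDERLY_GRID)
    c = make_cohort({"age_at_baseline": np.array([61.0]), "weight": np.array([0.0])})
    with pytest.raises(ValueError):
        estimate_prevalence(c, ELDERLY_GRID)


# -------------------------------------------------------------------- incidence

def test_incidence_zero_without_diagnoses():
    c = make_cohort({"age_at_baseline": np.array([65.0, 70.0])})
    grid = AgeGrid.from_range(30, 95)
    t = estimate_incidence(c, grid)
    assert (t["incidence"].fillna(0.0) == 0.0).all()


def test_incidence_hand_enumerated_exposure():
    # diagnosed at 62 -> 2 diabetes-free years in 60-64; never-diagnosed peer
    # contributes the full 5 -> rate 1/7 in that group
    c = make_cohort({"age_at_baseline": np.array([65.0, 65.0]),
                     "diabetic_at_baseline": np.array([True, False]),
                     "age_at_diagnosis": np.array([62.0, np.nan])})
    grid = AgeGrid.from_range(30, 95)
    t = estimate_incidence(c, grid)
    i60 = grid.index_of(60)
    assert t["events"].iloc[i60] == 1.0
    assert t["exposure"].iloc[i60] == pytest.approx(7.0)
    assert t["incidence"].iloc[i60] == pytest.approx(1.0 / 7.0)


def test_incidence_rejects_type1_style_diagnoses():
    c = make_cohort({"age_at_baseline": np.array([65.0]),
                     "diabetic_at_baseline": np.array([True]),
                     "age_at_diagnosis": np.array([25.0])})
    with pytest.raises(ValueError):
        estimate_incidence(c, AgeGrid.from_range(30, 95))


def test_incidence_recovers_generator_schedule():
    # diagnosis histories simulated from the incidence process itself
    spec = CohortSpec(
        n_subjects=50_000,
        prevalence_by_age=None,
        incidence_by_age=np.array([0.015, 0.015, 0.012, 0.012, 0.010, 0.008, 0.006, 0.005]),
        baseline_mortality_by_age=None,
        weight_dispersion=0.0,
        seed=11,
    )
    cohort = generate_cohort(spec)
    grid = AgeGrid.from_range(30, 95)
    t = estimate_incidence(cohort, grid)
    start = grid.index_of(60)
    for k in range(ELDERLY_GRID.n_groups - 2):   # oldest cells too thin to test
        est = t["incidence"].iloc[start + k]
        events = t["events"].iloc[start + k]
        if events < 30:
            continue
        se = est / np.sqrt(events)               # Poisson/occurrence-exposure SE
        assert abs(est - spec.incidence_by_age[k]) < 3 * se


# ----------------------------------------------------------- diabetic mortality

def test_diabetic_mortality_zero_without_deaths():
    c = make_cohort({"age_at_baseline": np.array([70.0]),
                     "diabetic_at_baseline": np.array([True]),
                     "age_at_end_of_followup": np.array([75.0])})
    t = estimate_diabetic_mortality(c, ELDERLY_GRID)
    assert t["m_diabetic"].iloc[2] == 0.0


def test_diabetic_mortality_hand_enumeration():
    # two diabetics each contribute ~5 years in 70-74, one dies at the end
    c = make_cohort({"age_at_baseline": np.array([70.0, 70.0]),
                     "diabetic_at_baseline": np.array([True, True]),
                     "died": np.array([True, False]),
                     "age_at_death": np.array([74.999, np.nan]),
                     "age_at_end_of_followup": np.array([75.0, 75.0])})
    t = estimate_diabetic_mortality(c, ELDERLY_GRID)
    assert t["m_diabetic"].iloc[2] == pytest.approx(0.1, rel=1e-3)


def test_diabetic_mortality_rejects_death_before_baseline():
    c = make_cohort({"age_at_baseline": np.array([70.0]),
                     "diabetic_at_baseline": np.array([True]),
                     "died": np.array([True]),
                     "age_at_death": np.array([69.0])})
    with pytest.raises(ValueError):
        estimate_diabetic_mortality(c, ELDERLY_GRID)


def test_diabetic_mortality_tracks_hazard_ratio():
    base = np.array([0.010, 0.016, 0.025, 0.042, 0.070, 0.115, 0.185, 0.30])
    spec = CohortSpec(
        n_subjects=50_000,
        prevalence_by_age=np.full(8, 0.5),
        incidence_by_age=None,
        baseline_mortality_by_age=base,
        hr_diabetes_mortality=2.0,
        weight_dispersion=0.0,
        seed=13,
    )
    cohort = generate_cohort(spec)
    t = estimate_diabetic_mortality(cohort, ELDERLY_GRID)
    for k in range(5):
        est, events = t["m_diabetic"].iloc[k], t["events"].iloc[k]
        se = est / np.sqrt(events)
        assert abs(est - 2.0 * base[k]) < 3 * se


# --------------------------------------------------------- cause-specific rates

def test_cause_specific_rates_hand_arithmetic():
    # 10 person-years at 70-74, one death per cause -> 0.1 each, 0.2 all-cause
    c = make_cohort({"age_at_baseline": np.array([70.0, 70.0]),
                     "diabetic_at_baseline": np.array([True, True]),
                     "died": np.array([True, True]),
                     "age_at_death": np.array([74.999, 74.999]),
                     "cause_of_death": np.array(["diabetes", "other"], dtype=object),
                     "age_at_end_of_followup": np.array([75.0, 75.0])})
    dm2, other = cause_specific_hazards(c, ELDERLY_GRID)
    assert dm2["m"].iloc[2] == pytest.approx(0.1, rel=1e-3)
    assert other["m"].iloc[2] == pytest.approx(0.1, rel=1e-3)


def test_cause_specific_rates_sum_to_all_cause_exactly():
    spec = CohortSpec(n_subjects=3000,
                      prevalence_by_age=np.full(8, 0.3),
                      baseline_mortality_by_age=np.full(8, 0.05),
                      seed=5)
    cohort = generate_cohort(spec)
    dm2, other = cause_specific_hazards(cohort, ELDERLY_GRID)
    total_events = dm2["events"] + other["events"]
    np.testing.assert_array_equal(dm2["exposure"].to_numpy(), other["exposure"].to_numpy())
    # same-denominator additivity
    both = (dm2["m"].fillna(0) + other["m"].fillna(0)).to_numpy()
    allc = np.where(dm2["exposure"] > 0, total_events / dm2["exposure"], 0.0)
    np.testing.assert_allclose(both, allc, rtol=1e-12)


def test_cause_specific_rates_require_cause_flags():
    c = make_cohort({"age_at_baseline": np.array([70.0]),
                     "died": np.array([True]),
                     "age_at_death": np.array([73.0]),
                     "cause_of_death": np.array([None], dtype=object)})
    with pytest.raises(ValueError):
        cause_specific_hazards(c, ELDERLY_GRID)


# ------------------------------------------------------------------ CSV round trip

def test_rate_table_round_trips_through_csv(tmp_path):
    c = make_cohort({"age_at_baseline": np.array([61.0, 72.0]),
                     "diabetic_at_baseline": np.array([True, False])})
    t = estimate_prevalence(c, ELDERLY_GRID)
    path = tmp_path / "rates.csv"
    rate_table_to_csv(t, path)
    back = rate_table_from_csv(path)
    assert grid_from_table(back) == ELDERLY_GRID
    np.testing.assert_allclose(back["prevalence"].to_numpy(), t["prevalence"].to_numpy())
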