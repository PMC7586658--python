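import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dm2burden.agegrid import ELDERLY_GRID

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_cohort(rows: dict) -> pd.DataFrame:
    """Hand-built cohort frame with all columns the estimators expect."""
    n = len(rows["age_at_baseline"])
    base = {
        "id": np.arange(n),
        "weight": np.ones(n),
        "sex": ["female"] * n,
        "diabetic_at_baseline": np.zeros(n, dtype=bool),
        "age_at_diagnosis": np.full(n, np.nan),
        "incident_diagnosis_age": np.full(n, np.nan),
        "died": np.zeros(n, dtype=bool),
        "age_at_death": np.full(n, np.nan),
        "cause_of_death": np.array([None] * n, dtype=object),
    }
    base.update(rows)
    df = pd.DataFrame(base)
    if "age_at_end_of_followup" not in rows:
        df["age_at_end_of_followup"] = df["age_at_baseline"] + 12.0
    return df


@pytest.fixture(scope="session")
def elderly_grid():
    return ELDERLY_GRID


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default run shared by the pipeline and acceptance tests."""
    from dm2burden.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = RunConfig(seed=20240601, outdir=str(outdir), n_sims=500)
    return config, run_pipeline(config)
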