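import numpy as np
import pandas as pd
import pytest

from methewas import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded desk-scale cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_subjects=80,
        n_sites=1_500,
        n_genes=120,
        n_obesity_genes=30,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    from methewas import write_cohort

    directory = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, directory)
    return directory


@pytest.fixture()
def tiny_samples():
    """Hand-built 8-subject covariate table."""
    rng = np.random.default_rng(5)
    n = 8
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": rng.uniform(13, 20, n).round(2),
            "sex": ["male", "female"] * 4,
            "race": ["white"] * 6 + ["other"] * 2,
            "batch": [1, 1, 2, 2] * 2,
            "bmi_percentile": rng.uniform(5, 95, n).round(2),
        }
    )
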