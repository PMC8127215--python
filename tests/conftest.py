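import numpy as np
import pandas as pd
import pytest

from rarecareer import (
    DiseaseList,
    SimulationConfig,
    build_disease_list,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_list():
    return build_disease_list(seed=0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_clinicians=6,
        years=8,
        panel_size=400,
        min_job_changes=1,
        max_job_changes=4,
        attrition_rate=0.10,
        jitter_fraction=0.15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_list():
    """Short mixed list spanning common to rare, both acquisition classes."""
    df = pd.DataFrame(
        {
            "code": [1, 2, 3, 4, 5, 6],
            "prevalence": [0.3, 0.05, 0.01, 1e-3, 1e-4, 0.02],
            "acquisition_class": [
                "spontaneous",
                "congenital",
                "spontaneous",
                "congenital",
                "spontaneous",
                "congenital",
            ],
        }
    )
    return DiseaseList.from_frame(df)


@pytest.fixture(scope="session")
def small_cube(small_config, small_list):
    return simulate_cohort(small_config, small_list)


def single_condition_list(prevalence, acquisition_class="spontaneous"):
    df = pd.DataFrame(
        {
            "code": [1],
            "prevalence": [prevalence],
            "acquisition_class": [acquisition_class],
        }
    )
    return DiseaseList.from_frame(df)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
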