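import numpy as np
import pytest

from codrange import (
    SigmaComponents,
    SynthConfig,
    compute_csf_records,
    compute_occupancy,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """A reduced survey: 5 subregions, 3 ages, 10 years, ~80 sets/year."""
    return SynthConfig(
        n_subregions=5,
        ages=(1, 2, 3),
        sets_per_year=80,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_survey(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_occupancy(small_survey):
    return compute_occupancy(small_survey)


@pytest.fixture(scope="session")
def small_csf(small_survey):
    return compute_csf_records(small_survey)


@pytest.fixture(scope="session")
def interaction_only_config():
    """Truth whose random effects match the fitted age-by-subregion
    exchangeable structure exactly (no age/subregion main components)."""
    return SynthConfig(
        n_subregions=6,
        ages=(1, 2, 3),
        sets_per_year=150,
        sigma_a_co=SigmaComponents(0.0, 0.0, 0.8),
        sigma_b_co=SigmaComponents(0.0, 0.0, 0.12),
        sigma_a_csf=SigmaComponents(0.0, 0.0, 0.4),
        sigma_b_csf=SigmaComponents(0.0, 0.0, 0.05),
        seed=77,
    )
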