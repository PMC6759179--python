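import numpy as np
import pandas as pd
import pytest

from linkbench.synthetic import GeneratorConfig, generate_datasets, generate_population


@pytest.fixture(scope="session")
def small_config():
    """A small but fully-featured scenario used across the suite."""
    return GeneratorConfig(n_persons=500, seed=11)


@pytest.fixture(scope="session")
def small_datasets(small_config):
    return generate_datasets(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Full overlap, single admission, every error channel off."""
    return GeneratorConfig(
        n_persons=300,
        overlap_fraction=1.0,
        admission_rate=1.0,
        typo_rate_per_field=0.0,
        newborn_fraction=0.0,
        compound_surname_rate=0.0,
        missing_gender_rate=0.0,
        mrn_error_rate=0.0,
        opd_missing_mrn_rate=0.0,
        missing_zip_rate=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_datasets(clean_config):
    return generate_datasets(clean_config)


@pytest.fixture(scope="session")
def latent_population(small_config):
    return generate_population(small_config)
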