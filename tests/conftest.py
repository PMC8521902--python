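import numpy as np
import pytest

from intense.cohort_io import default_schema, normalize_cohort
from intense.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort_seed1(config):
    return generate_cohort(config, seed=1)


@pytest.fixture(scope="session")
def normalized_seed1(cohort_seed1):
    return normalize_cohort(cohort_seed1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
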