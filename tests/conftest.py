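import numpy as np
import pytest

from cohortcea import (
    ModelConfig,
    default_risk_equation,
    load_default_parameters,
    parameter_means,
)
from cohortcea.synthetic import make_life_table


@pytest.fixture(scope="session")
def specs():
    """The packaged study parameter table."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def means(specs):
    return parameter_means(specs)


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def risk_eq():
    return default_risk_equation()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240507)
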