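import numpy as np
import pytest

from ds3markov import (
    default_life_table,
    default_mortality_curve,
    default_transition_coefficients,
    default_utility_coefficients,
    all_matrices,
    utility_table,
)


@pytest.fixture(scope="session")
def trans_coefs():
    return default_transition_coefficients()


@pytest.fixture(scope="session")
def util_coefs():
    """Default (calibrated-age) utility coefficients."""
    return default_utility_coefficients()


@pytest.fixture(scope="session")
def util_coefs_printed():
    return default_utility_coefficients("printed")


@pytest.fixture(scope="session")
def general_table():
    return default_life_table()


@pytest.fixture(scope="session")
def mortality_curve(general_table):
    curve, _ = default_mortality_curve(general_table)
    return curve


@pytest.fixture(scope="session")
def matrices(trans_coefs):
    return all_matrices(trans_coefs)


@pytest.fixture(scope="session")
def utilities(util_coefs):
    return utility_table(util_coefs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
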