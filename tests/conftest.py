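import pytest
from hypothesis import HealthCheck, settings

from hbcube import datasets

# reproducible property tests in fresh environments (no example database)
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def alpha_table():
    return datasets.goose_alpha_table()


@pytest.fixture(scope="session")
def beta_table():
    return datasets.goose_beta_table()


@pytest.fixture(scope="session")
def combined_table():
    return datasets.goose_combined_table()


@pytest.fixture(scope="session")
def alpha_sites():
    return datasets.alpha_sites()


@pytest.fixture(scope="session")
def beta_sites():
    return datasets.beta_sites()


@pytest.fixture(scope="session")
def anserinae():
    return datasets.anserinae_tree(), datasets.anserinae_states()
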