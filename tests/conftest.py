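import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pahrisk import (
    default_constants,
    default_kinetics,
    paper_mixture,
    scenario,
    slope_set,
)


@pytest.fixture(scope="session")
def sediment_profile():
    """Packaged Superfund-sediment mixture (35 compounds)."""
    return paper_mixture()


@pytest.fixture(scope="session")
def oral_slopes():
    return slope_set("oral")


@pytest.fixture(scope="session")
def dermal_slopes():
    return slope_set("dermal")


@pytest.fixture
def adult_oral():
    return scenario("adult_trespasser", "oral")


@pytest.fixture
def adult_dermal():
    return scenario("adult_trespasser", "dermal")


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def constants():
    return default_constants()
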