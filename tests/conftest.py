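import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def endpoint_tables():
    """(RPFTable, HBGV map) per endpoint, derived from the shipped tables."""
    from cumrisk.workflow import endpoint_tables as build

    return build()


@pytest.fixture(scope="session")
def small_survey():
    """A small seeded synthetic survey shared across tests."""
    from cumrisk.synthetic import default_config, generate_survey

    return generate_survey(default_config(seed=7, n_individuals=250))
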