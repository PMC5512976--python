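import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def random_fixture_set():
    """A 50-record synthetic sequence set with uniform composition."""
    from protquant.fixtures import FixtureSpec, generate_fixture
    return generate_fixture(FixtureSpec(50, (5, 40), "uniform", seed=7,
                                        population_label="fix"))
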