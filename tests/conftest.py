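import pytest
from hypothesis import HealthCheck, settings

from nutrimpact.registry import load_bundled_exclusions, load_bundled_registry
from nutrimpact.synthetic import GeneratorParams, generate_country_profile

settings.register_profile(
    "suite",
    settings(
        max_examples=100,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def exclusions():
    return load_bundled_exclusions()


@pytest.fixture(scope="session")
def _base_profile():
    return generate_country_profile(GeneratorParams(seed=7))


@pytest.fixture
def profile(_base_profile):
    """A fresh, independently mutable copy per test."""
    from nutrimpact.affected_fractions import CountryProfile

    return CountryProfile.from_dict(_base_profile.to_dict())
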