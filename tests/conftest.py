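import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from contactfuse.synthetic import FixtureSpec, make_reference, make_structure


@pytest.fixture(scope="session")
def hairpin_spec():
    return FixtureSpec(seed=11, l=24, topology="hairpin", n_true=8, n_false=2)


@pytest.fixture(scope="session")
def hairpin_structure(hairpin_spec):
    return make_structure(hairpin_spec)


@pytest.fixture(scope="session")
def hairpin_reference(hairpin_spec):
    return make_reference(hairpin_spec)
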