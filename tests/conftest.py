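import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_dataset():
    """The deterministic packaged FBN1 case-control dataset."""
    from csburden import fbn1_fixture

    return fbn1_fixture()


@pytest.fixture(scope="session")
def domain_map():
    from csburden import fbn1_domain_map

    return fbn1_domain_map()
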