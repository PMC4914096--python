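import pytest
from hypothesis import HealthCheck, settings

from restaple import duplex_toy, make_helix_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def toy():
    return duplex_toy()


@pytest.fixture(scope="session")
def bundle6():
    # six-helix-bundle antenna analogue, ~1082-nt scaffold segment
    return make_helix_bundle(6, 1082, "honeycomb", 7)


@pytest.fixture(scope="session")
def bundle24():
    # 24-helix bundle with a 6-kb scaffold
    return make_helix_bundle(24, 6000, "honeycomb", 7)
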