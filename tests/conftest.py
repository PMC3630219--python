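import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hmec_net():
    from erbbsim.hmec import build_hmec_mini
    return build_hmec_mini()


@pytest.fixture(scope="session")
def library():
    from erbbsim.experiments import scenario_library
    return scenario_library()


@pytest.fixture(scope="session")
def subchain():
    from erbbsim.hmec import trafficking_subchain
    return trafficking_subchain()
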