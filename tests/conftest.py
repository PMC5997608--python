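import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fd_output():
    """One noise-free feed-on-demand cycle under the default calibration."""
    from feastfamine.pipeline import load_scenario, simulate_scenario

    return simulate_scenario(load_scenario("FD", seed=0))


@pytest.fixture(scope="session")
def sbr_output():
    """One noise-free single-pulse start-up cycle."""
    from feastfamine.pipeline import load_scenario, simulate_scenario

    return simulate_scenario(load_scenario("SBR1", seed=0))
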