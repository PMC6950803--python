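import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across the suite."""
    from anthoreg import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    from anthoreg import run_pipeline

    return run_pipeline(bundle)
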