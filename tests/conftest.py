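import pytest
from hypothesis import HealthCheck, settings

import grainsave as gs

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config() -> gs.AnalysisConfig:
    """The bundled Australian cancer inputs."""
    return gs.load_bundled_config()


@pytest.fixture(scope="session")
def bundle(config) -> gs.ResultsBundle:
    """Full model run on the bundled inputs."""
    return gs.run_pipeline(config)
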