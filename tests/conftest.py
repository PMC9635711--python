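import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Separable synthetic corpus shared by classifier tests (8x2x120 messages)."""
    from sentistack import SimulationConfig, generate_corpus

    cfg = SimulationConfig(
        messages_per_cell=120, class_separation=4.0, label_fraction=0.5, seed=7
    )
    return generate_corpus(cfg)
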