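import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def scenario():
    from phycofilm import ScenarioConfig
    return ScenarioConfig(seed=42)


@pytest.fixture
def haldane_truth():
    from phycofilm import HaldaneParams
    return HaldaneParams(mu_max=1.0, alpha=0.02, i_opt=150.0)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
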