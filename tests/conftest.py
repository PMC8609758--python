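import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from guidedev.synthetic_study import StudyConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (full reference-size, seed 0)."""
    return generate_study(StudyConfig(seed=0))


@pytest.fixture()
def small_config():
    """A reduced study for fast I/O-heavy tests."""
    return StudyConfig(
        group_sizes={"AT": 6, "P": 5, "M": 8},
        n_models=2,
        seed=0,
    )
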