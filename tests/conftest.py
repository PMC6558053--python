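import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diverse_induction import (
    GeneratorParams,
    SimulationConfig,
    build_toy_space,
    diversity_sweep,
    generate_ratings,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_space():
    return build_toy_space()


@pytest.fixture(scope="session")
def default_curve():
    """The default diversity sweep (m=101, 3 premises, 51 grid points)."""
    return diversity_sweep(SimulationConfig())


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic experiment (184 participants, seed 0)."""
    return generate_ratings(params=GeneratorParams(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
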