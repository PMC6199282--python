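import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heteropd.model_core import H_LEVELS, LatticeState, SimulationParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Fast parameters for smoke-level protocol tests."""
    return SimulationParams(
        L=16, b=1.1, u=0.5, alpha=2.0, total_mcs=120, avg_window=30,
        max_extensions=1, n_replicates=2, seed=9,
    )


def random_state(rng: np.random.Generator, L: int) -> LatticeState:
    """Random lattice with strategies and h drawn as in a real run."""
    strategies = rng.integers(0, 2, size=(L, L), dtype=np.int8)
    h = H_LEVELS[rng.integers(0, len(H_LEVELS), size=(L, L))]
    return LatticeState(strategies, h)
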