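import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import volentropy as ve

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def unit_complete(n: int, length: float = 1.0) -> ve.MetricGraph:
    """Complete graph on n nodes with equal edge lengths."""
    edges = {(i, j): length for i in range(n) for j in range(i + 1, n)}
    return ve.MetricGraph.from_edges([f"n{i}" for i in range(n)], edges)


def random_coherence(n: int, seed: int, low: float = 0.2, high: float = 0.8) -> np.ndarray:
    """Symmetric coherence matrix with iid off-diagonal entries."""
    rng = np.random.default_rng(seed)
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals[iu] = rng.uniform(low, high, len(iu[0]))
    vals = vals + vals.T
    return vals


@pytest.fixture
def k4():
    return unit_complete(4)


@pytest.fixture
def k4_hetero():
    """K4 with heterogeneous rational lengths drawn from {1, 1.5, 2}."""
    edges = {
        (0, 1): 1.0,
        (0, 2): 1.5,
        (0, 3): 2.0,
        (1, 2): 2.0,
        (1, 3): 1.5,
        (2, 3): 1.0,
    }
    return ve.MetricGraph.from_edges(["a", "b", "c", "d"], edges)
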