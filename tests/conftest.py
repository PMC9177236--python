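import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gango import DirectedConnectome, NetworkPartition, NoiseSpec, WeightedDAG, simulate_lingam


@pytest.fixture
def chain_data():
    """n=2000 samples of the chain x0 -> x1 -> x2 with b=0.8, exponential noise."""
    dag = WeightedDAG(3, {(0, 1): 0.8, (1, 2): 0.8}, (0, 1, 2))
    return dag, simulate_lingam(dag, 2000, NoiseSpec(), seed=42)


@pytest.fixture
def collider_data():
    """n=2000 samples of x0 -> x2 <- x1 with b=0.8, exponential noise."""
    dag = WeightedDAG(3, {(0, 2): 0.8, (1, 2): 0.8}, (0, 1, 2))
    return dag, simulate_lingam(dag, 2000, NoiseSpec(), seed=43)


@pytest.fixture
def star_graph():
    """Reciprocal star: center 0 with 0<->leaf for leaves 1..4."""
    edges = set()
    for leaf in range(1, 5):
        edges.add((0, leaf))
        edges.add((leaf, 0))
    return DirectedConnectome(5, frozenset(edges), strict=False)


@pytest.fixture
def path_graph():
    """Directed path a -> b -> c on 3 nodes."""
    return DirectedConnectome(3, frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def four_module_partition():
    labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
    return NetworkPartition(tuple(labels))
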