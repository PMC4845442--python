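import random

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from netcompare import Network, NetworkCollection

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NODE_LABELS = list("abcdefghijkl")


@pytest.fixture
def net_a() -> Network:
    return Network("A", edges=[("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def net_b() -> Network:
    return Network("B", edges=[("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def net_c() -> Network:
    return Network("C", edges=[("a", "b"), ("d", "e")])


@pytest.fixture
def collection_ab(net_a, net_b) -> NetworkCollection:
    return NetworkCollection([net_a, net_b])


@pytest.fixture
def collection_abc(net_a, net_b, net_c) -> NetworkCollection:
    return NetworkCollection([net_a, net_b, net_c])


@pytest.fixture
def path_graph() -> Network:
    return Network("path", edges=[("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle() -> Network:
    return Network("triangle", edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def two_triangles() -> Network:
    return Network(
        "two-triangles",
        edges=[("a", "b"), ("b", "c"), ("a", "c"),
               ("d", "e"), ("e", "f"), ("d", "f"),
               ("c", "d")],
    )


def random_network(rng: random.Random, name: str, max_nodes: int = 12,
                   p: float = 0.35) -> Network:
    """Seeded Erdős–Rényi-style network on a small label alphabet."""
    n = rng.randint(2, max_nodes)
    labels = NODE_LABELS[:n]
    edges = [
        (u, v)
        for i, u in enumerate(labels)
        for v in labels[i + 1:]
        if rng.random() < p
    ]
    return Network(name, nodes=labels, edges=edges)


# hypothesis strategy: small random simple networks
@st.composite
def networks(draw, min_nodes: int = 2, max_nodes: int = 8, name: str = "H"):
    n = draw(st.integers(min_nodes, max_nodes))
    labels = NODE_LABELS[:n]
    pairs = [
        (u, v) for i, u in enumerate(labels) for v in labels[i + 1:]
    ]
    chosen = draw(st.lists(st.sampled_from(pairs), unique=True,
                           max_size=len(pairs)))
    return Network(name, nodes=labels, edges=chosen)
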