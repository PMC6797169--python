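import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TOY_ATTRIBUTES = {
    "a": "positive",
    "b": "positive",
    "c": "negative",
    "d": "negative",
    "e": "neutral",
    "f": "positive",
    "g": "negative",
    "h": "neutral",
}

TOY_EDGES = [
    ("a", "b", 1),
    ("a", "c", 1),
    ("b", "e", 1),
    ("c", "d", 2),
    ("d", "g", 1),
    ("e", "f", 1),
    ("e", "g", 1),
    ("f", "h", 1),
]


@pytest.fixture
def toy_network() -> nx.Graph:
    """Hand-built 8-word network with hand-assigned valence attributes."""
    graph = nx.Graph()
    graph.graph["min_participants"] = 1
    for u, v, w in TOY_EDGES:
        graph.add_edge(u, v, weight=w)
    for node, attr in TOY_ATTRIBUTES.items():
        graph.nodes[node]["valence"] = attr
        graph.nodes[node]["unrated"] = False
    return graph
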