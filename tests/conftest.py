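import random

import pytest

from graphdwh import PropertyGraph

NODE_LABELS = ("Drug", "Gene", "Disease", "Variant")
EDGE_LABELS = ("TARGETS", "INDUCES", "ASSOCIATED_WITH")


def build_random_graph(
    rng: random.Random,
    max_nodes: int = 30,
    node_labels=NODE_LABELS,
    edge_labels=EDGE_LABELS,
    density: float = 2.0,
    with_properties: bool = True,
) -> PropertyGraph:
    """Random labeled graph with type-consistent properties (so it is
    GraphML-serializable)."""
    graph = PropertyGraph()
    n = rng.randint(0, max_nodes)
    for i in range(n):
        properties = {}
        if with_properties:
            properties = {"id": f"N{i}", "score": rng.random(), "flag": rng.random() < 0.5}
            if rng.random() < 0.3:
                properties["tags"] = [
                    rng.choice(["a|b", "c\\d", "plain"]) for _ in range(rng.randint(1, 3))
                ]
        graph.add_node(rng.choice(node_labels), properties)
    nodes = list(graph.nodes())
    for _ in range(int(density * n)):
        properties = {"weight": rng.random()} if with_properties and rng.random() < 0.5 else {}
        graph.add_edge(
            rng.choice(nodes), rng.choice(nodes), rng.choice(edge_labels), properties
        )
    return graph


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
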