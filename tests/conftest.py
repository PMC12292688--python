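import networkx as nx
import pytest

from netpharm import ppi, synthetic


def make_graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        a, b = e[:2]
        score = e[2] if len(e) > 2 else 900
        g.add_edge(a, b, combined_score=score)
    return g


@pytest.fixture
def triangle():
    return make_graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star3():
    """Star: center C with leaves X, Y, Z."""
    return make_graph([("C", "X"), ("C", "Y"), ("C", "Z")])


@pytest.fixture
def path3():
    return make_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def k4():
    return make_graph(
        [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    )


@pytest.fixture(scope="session")
def scenario1():
    return synthetic.generate_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario1_graph(scenario1):
    return ppi.build_graph(scenario1.edges, scenario1.analysis_list, 0.400)


def random_graph(seed, max_nodes=12, p=0.3):
    """Seeded G(n, p) with string labels; may be disconnected."""
    import random

    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    nodes = [f"N{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], combined_score=900)
    return g
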