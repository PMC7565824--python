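import networkx as nx
import pytest

from modnet.netcore import GeneNetwork


def make_network(edges, isolated=()) -> GeneNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(isolated)
    return GeneNetwork(g)


@pytest.fixture
def path3() -> GeneNetwork:
    """Path A - B - C."""
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> GeneNetwork:
    """Star with center HUB and three leaves."""
    return make_network([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])


@pytest.fixture
def complete4() -> GeneNetwork:
    return GeneNetwork(nx.relabel_nodes(nx.complete_graph(4), lambda i: f"N{i}"))
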