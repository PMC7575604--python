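import networkx as nx
import numpy as np
import pytest

from trnkit.network import Interaction, RegulatoryNetwork
from trnkit.synthetic import fixtures


@pytest.fixture(scope="session")
def tiny_nets():
    """The package's small fixed fixture networks."""
    return fixtures()


@pytest.fixture()
def three_row_net():
    """The canonical merged 2-interaction network: A->g1 doubly supported
    and positive, B->g2 expression-only negative."""
    from trnkit.network import Sign

    net = RegulatoryNetwork(label="three_row")
    net.add(Interaction(tf="A", target="G1", has_binding=True))
    net.add(
        Interaction(tf="A", target="G1", has_expression=True, sign=Sign.POSITIVE)
    )
    net.add(
        Interaction(tf="B", target="G2", has_expression=True, sign=Sign.NEGATIVE)
    )
    return net


def random_digraph(n: int, p: float, seed: int) -> nx.DiGraph:
    """Erdős–Rényi-style directed graph without self-loops."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


def structural_net(edges, label="net") -> RegulatoryNetwork:
    return RegulatoryNetwork.from_interactions(
        (Interaction(tf=u, target=v, has_binding=True) for u, v in edges),
        label=label,
    )
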