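import pytest

from ergged.cost_model import harper_defaults, uniform_costs
from ergged.graph_model import EdgeLabel, ErgGraph, NodeLabel


@pytest.fixture(scope="session")
def harper():
    return harper_defaults()


@pytest.fixture(scope="session")
def ones():
    return uniform_costs(1.0)


def make_graph(gid, nodes, edges=()):
    """Terse graph builder: nodes as {id: "[label]"}, edges as (u, v, sym)."""
    g = ErgGraph(id=gid)
    for nid, sym in nodes.items():
        g.add_node(nid, NodeLabel(sym))
    for u, v, sym in edges:
        g.add_edge(u, v, EdgeLabel(sym))
    return g
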