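import networkx as nx
import pytest

from rettnet.catalog import GeneCatalog, GeneClass, GeneRecord
from rettnet.io_formats import make_edge
from rettnet.netbuild import InteractionNetwork, build_first_order


def catalog_from(rtt=(), rttl=()):
    records = [GeneRecord(s, GeneClass.RTT_CLASSICAL) for s in rtt]
    records += [GeneRecord(s, GeneClass.RTTL_LITERATURE) for s in rttl]
    return GeneCatalog(records)


def network_from(edge_pairs, rtt=(), rttl=()):
    """Build a classified first-order network from raw symbol pairs."""
    catalog = catalog_from(rtt, rttl)
    edges = [make_edge(a, b) for a, b in edge_pairs]
    return build_first_order(catalog, edges), catalog


def plain_network(edge_pairs, isolated=()):
    """An InteractionNetwork with all nodes classified INTERACTOR."""
    graph = nx.Graph()
    graph.add_edges_from(edge_pairs)
    graph.add_nodes_from(isolated)
    for node in graph.nodes:
        graph.nodes[node]["gene_class"] = "INTERACTOR"
    return InteractionNetwork(graph)


@pytest.fixture
def star_network():
    """5-node star; center C, leaves L1..L4; C is an RTT seed."""
    net, _ = network_from(
        [("C", "L1"), ("C", "L2"), ("C", "L3"), ("C", "L4")], rtt=["C"]
    )
    return net


@pytest.fixture
def toy_catalog():
    return catalog_from(rtt=["MECP2", "CDKL5"], rttl=["HECW2", "TCF4"])
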