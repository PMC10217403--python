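"""First-order interaction network construction around seed genes.

The network keeps exactly the interactions with at least one seed endpoint
(passing the evidence filter), i.e. the seeds plus all their direct
interacting partners.  Nodes are classified RTT_SEED / RTTL_SEED /
INTERACTOR, with RTT taking precedence for symbols listed in both seed
groups.  Self-loops are excluded from the simple graph but counted, and
seeds that end up with no retained interaction are reported as isolated
rather than silently dropped (a seed can genuinely lose all its edges, as
happens to CDKL5 after tissue filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .catalog import GeneCatalog
from .io_formats import InteractionEdge

__all__ = [
    "NODE_CLASSES",
    "InteractionNetwork",
    "NetworkBuildError",
    "build_first_order",
    "classify_nodes",
    "connected_components",
]

NODE_CLASSES = ("RTT_SEED", "RTTL_SEED", "INTERACTOR")


class NetworkBuildError(ValueError):
    pass


@dataclass
class InteractionNetwork:
    """A simple undirected graph with node classes and edge metadata.

    ``graph`` is a :class:`networkx.Graph`; node attribute ``gene_class`` is
    one of :data:`NODE_CLASSES`; edge attributes carry evidence / sources /
    tissues from the input table.
    """

    graph: nx.Graph
    n_selfloops_dropped: int = 0
    isolated_seeds: set[str] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, node_class: str) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True)
            if d.get("gene_class") == node_class
        }

    @property
    def seed_nodes(self) -> set[str]:
        return self.nodes_of_class("RTT_SEED") | self.nodes_of_class("RTTL_SEED")

    @property
    def interactors(self) -> set[str]:
        return self.nodes_of_class("INTERACTOR")

    def counts(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_rtt_seed_nodes": len(self.nodes_of_class("RTT_SEED")),
            "n_rttl_seed_nodes": len(self.nodes_of_class("RTTL_SEED")),
            "n_seed_nodes": len(self.seed_nodes),
            "n_interactors": len(self.interactors),
            "n_selfloops_dropped": self.n_selfloops_dropped,
            "n_isolated_seeds": len(self.isolated_seeds),
            "isolated_seeds": sorted(self.isolated_seeds),
        }


def _node_class(symbol: str, catalog: GeneCatalog) -> str:
    # precedence: RTT seed > RTT-L seed > interactor
    if symbol in catalog.rtt_symbols:
        return "RTT_SEED"
    if symbol in catalog.rttl_symbols:
        return "RTTL_SEED"
    return "INTERACTOR"


def build_first_order(
    catalog: GeneCatalog,
    edges: list[InteractionEdge],
    evidence_filter: set[str] | None = frozenset({"experimental"}),
) -> InteractionNetwork:
    """Retain exactly the edges with >= 1 seed endpoint and allowed evidence.

    ``evidence_filter=None`` admits every evidence class.  Seeds from the
    catalog whose every interaction was filtered away (or was a self-loop)
    are recorded in ``isolated_seeds`` and do not appear as graph nodes.
    """
    if not catalog.records:
        raise NetworkBuildError("empty seed catalog")
    seeds = catalog.rtt_symbols | catalog.rttl_symbols
    graph = nx.Graph()
    n_selfloops = 0
    for edge in edges:
        if evidence_filter is not None and edge.evidence not in evidence_filter:
            continue
        if edge.symbol_a not in seeds and edge.symbol_b not in seeds:
            continue
        if edge.is_self_loop:
            n_selfloops += 1
            continue
        graph.add_edge(
            edge.symbol_a,
            edge.symbol_b,
            evidence=edge.evidence,
            sources=edge.sources,
            tissues=edge.tissues,
        )
    for node in graph.nodes:
        graph.nodes[node]["gene_class"] = _node_class(node, catalog)
    isolated = {s for s in seeds if s not in graph}
    return InteractionNetwork(graph, n_selfloops, isolated)


def classify_nodes(network: InteractionNetwork, catalog: GeneCatalog) -> dict[str, str]:
    """Node -> class mapping; classes partition the node set."""
    mapping = {}
    for node in network.graph.nodes:
        mapping[node] = _node_class(node, catalog)
        network.graph.nodes[node]["gene_class"] = mapping[node]
    return mapping


def connected_components(network: InteractionNetwork) -> list[set[str]]:
    """Components ordered by decreasing size, ties by smallest symbol."""
    comps = list(nx.connected_components(network.graph))
    return sorted(comps, key=lambda c: (-len(c), min(c)))
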