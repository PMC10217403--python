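"""Seed-mediated sub-networks and seed-seed adjacency.

A sub-network anchored on a set of seeds is, by default, the induced
subgraph on the anchors plus their first-order neighbors (neighbor-neighbor
edges kept); both choices are flags.  Seed-seed adjacency reports the edges
whose two endpoints are both seeds, labelled by seed-class pair — the direct
contacts (e.g. a classical seed touching a Rett-like seed) that hold the
seed neighborhoods together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .catalog import GeneCatalog
from .netbuild import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["SubnetworkSpec", "SubnetworkError", "extract_subnetwork", "seed_adjacency_report"]


class SubnetworkError(ValueError):
    pass


@dataclass
class SubnetworkSpec:
    anchor_seeds: set[str]
    include_neighbors: bool = True
    induced: bool = True


def extract_subnetwork(network: InteractionNetwork, spec: SubnetworkSpec) -> InteractionNetwork:
    """Extract the sub-network mediated by the anchor seeds.

    Anchors absent from the network are reported and skipped; it is an error
    only if none remain.
    """
    graph = network.graph
    present = {a for a in spec.anchor_seeds if a in graph}
    missing = set(spec.anchor_seeds) - present
    if missing:
        logger.warning("anchors missing from network: %s", sorted(missing))
    if not present:
        raise SubnetworkError("all anchor seeds missing from network")
    nodes = set(present)
    if spec.include_neighbors:
        for anchor in present:
            nodes.update(graph.neighbors(anchor))
    sub = nx.Graph()
    sub.add_nodes_from((n, dict(graph.nodes[n])) for n in nodes)
    if spec.induced:
        sub.add_edges_from(
            (a, b, dict(d)) for a, b, d in graph.edges(data=True)
            if a in nodes and b in nodes
        )
    else:
        sub.add_edges_from(
            (a, b, dict(d)) for a, b, d in graph.edges(data=True)
            if (a in present or b in present) and a in nodes and b in nodes
        )
    return InteractionNetwork(sub)


def seed_adjacency_report(network: InteractionNetwork, catalog: GeneCatalog):
    """All seed-seed edges with their class pair, sorted for determinism.

    Returns a list of ``(symbol_a, symbol_b, class_a, class_b)`` where the
    classes are the node classes (RTT_SEED / RTTL_SEED).
    """
    graph = network.graph
    seeds = network.seed_nodes
    report = []
    for a, b in graph.edges():
        if a in seeds and b in seeds:
            a, b = sorted((a, b))
            report.append(
                (a, b, graph.nodes[a]["gene_class"], graph.nodes[b]["gene_class"])
            )
    return sorted(report)
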