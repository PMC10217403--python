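"""Tissue-restricted networks and seed-class partner sets.

A protein counts as expressed in a tissue when it has an expression call at
any level other than ``not_detected``; a protein with no call at all for the
tissue is treated as not expressed and removed (this is what strips CDKL5
from a brain-restricted network when the atlas lacks protein-level data for
it).  Filtering keeps a node iff expressed and an edge iff both endpoints
survive, yielding a subgraph of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import ExpressionTable
from .netbuild import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["PartnerReport", "expressed", "filter_network", "common_interactors"]


@dataclass
class PartnerReport:
    """Seed-class partner sets and their intersection (Venn summary).

    Partners are INTERACTOR nodes only — seeds never count as partners of
    each other here, so the common set is a set of third-party proteins
    bridging the two seed classes.
    """

    rtt_partners: set[str] = field(default_factory=set)
    rttl_partners: set[str] = field(default_factory=set)
    common: set[str] = field(default_factory=set)
    dropped_seeds: set[str] = field(default_factory=set)

    def counts(self) -> dict:
        return {
            "n_rtt_partners": len(self.rtt_partners),
            "n_rttl_partners": len(self.rttl_partners),
            "n_common": len(self.common),
            "dropped_seeds": sorted(self.dropped_seeds),
        }


def expressed(symbol: str, tissue: str, table: ExpressionTable) -> bool:
    """True iff the symbol has a call other than ``not_detected`` for the
    tissue; symbols without any call are not expressed."""
    level = table.level(symbol, tissue)
    return level is not None and level != "not_detected"


def filter_network(
    network: InteractionNetwork,
    table: ExpressionTable,
    tissue: str,
    keep_uncovered: bool = False,
):
    """Restrict the network to proteins expressed in a tissue.

    ``keep_uncovered=True`` retains symbols that simply lack expression data
    instead of dropping them.  Returns ``(filtered_network, PartnerReport)``;
    the report's ``dropped_seeds`` lists seeds removed by the filter and its
    partner sets describe the filtered network.
    """
    if len(table) == 0 and not keep_uncovered:
        logger.warning("empty expression table: filtered network is empty")
    graph = network.graph

    def keep(node):
        if expressed(node, tissue, table):
            return True
        return keep_uncovered and table.level(node, tissue) is None

    kept = [n for n in graph.nodes if keep(n)]
    sub = nx.Graph()
    sub.add_nodes_from((n, dict(graph.nodes[n])) for n in kept)
    kept_set = set(kept)
    sub.add_edges_from(
        (a, b, dict(d)) for a, b, d in graph.edges(data=True)
        if a in kept_set and b in kept_set
    )
    dropped_seeds = network.seed_nodes - kept_set
    filtered = InteractionNetwork(
        sub,
        n_selfloops_dropped=network.n_selfloops_dropped,
        isolated_seeds=set(network.isolated_seeds) | dropped_seeds,
    )
    report = common_interactors(filtered)
    report.dropped_seeds = dropped_seeds
    return filtered, report


def common_interactors(network: InteractionNetwork) -> PartnerReport:
    """Interactors adjacent to each seed class, and their intersection."""
    graph = network.graph
    rtt_seeds = network.nodes_of_class("RTT_SEED")
    rttl_seeds = network.nodes_of_class("RTTL_SEED")
    interactors = network.interactors
    rtt_partners = {
        n for seed in rtt_seeds for n in graph.neighbors(seed) if n in interactors
    }
    rttl_partners = {
        n for seed in rttl_seeds for n in graph.neighbors(seed) if n in interactors
    }
    return PartnerReport(
        rtt_partners=rtt_partners,
        rttl_partners=rttl_partners,
        common=rtt_partners & rttl_partners,
    )
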