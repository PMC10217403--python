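"""Synthetic interactomes, expression tables and gene-set collections.

The generator emulates the statistical structure the analysis assumes about
its real inputs: a heavy-tailed (preferential-attachment) interactome with
designated seed genes of two classes, incomplete ordinal expression
coverage in a target tissue (some proteins lacking any record, as happens
to real seeds), and annotation sources with one planted over-represented
term.  Everything is deterministic under ``rng_seed``.

The planted number of common interactors is exact by construction: any
non-seed node that happens to touch both seed classes in the backbone is
first unwired from the first class (its edges to those seeds are removed),
and exactly ``planted_common_k`` nodes are then wired to at least one seed
of each class.  Planting adds edges rather than rewiring, so backbone
degrees can rise slightly on planted nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .catalog import GeneCatalog, GeneClass, GeneRecord
from .io_formats import ExpressionRecord, ExpressionTable, InteractionEdge, TermSet, make_edge

__all__ = [
    "SyntheticError",
    "SyntheticConfig",
    "generate_interactome",
    "generate_expression",
    "generate_gmt",
]


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 4 + 58 seeds on a ~2250-node heavy-tailed
    backbone, 63 planted cross-class partners, and a planted term with a
    15/20 overlap against a 20-gene query."""

    n_nodes: int = 2250
    attachment_m: int = 2
    backbone: str = "ba"  # "ba" preferential attachment, or "er" Erdos-Renyi
    n_rtt_seeds: int = 4
    n_rttl_seeds: int = 58
    tissue: str = "brain"
    p_not_detected: float = 0.15
    p_uncovered: float = 0.05
    planted_common_k: int = 63
    planted_term: tuple[int, int] = (20, 15)  # (term size K, overlap k)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 10:
            raise SyntheticError("n_nodes must be >= 10")
        if self.attachment_m < 1:
            raise SyntheticError("attachment_m must be >= 1")
        if self.n_rtt_seeds + self.n_rttl_seeds >= self.n_nodes:
            raise SyntheticError("seed counts must be < n_nodes")
        for p in (self.p_not_detected, self.p_uncovered):
            if not 0 <= p <= 1:
                raise SyntheticError(f"probability out of [0,1]: {p}")
        n_free = self.n_nodes - self.n_rtt_seeds - self.n_rttl_seeds
        if self.planted_common_k > n_free:
            raise SyntheticError(
                f"cannot plant {self.planted_common_k} common interactors with "
                f"only {n_free} non-seed nodes"
            )
        if self.planted_common_k > 0 and (self.n_rtt_seeds < 1 or self.n_rttl_seeds < 1):
            raise SyntheticError("planting common interactors needs seeds of both classes")


def _symbol(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(config: SyntheticConfig):
    """Backbone graph + seed assignment + exact common-interactor planting.

    Returns ``(edges, catalog)`` where edges are canonical
    :class:`InteractionEdge` objects (all evidence ``experimental``, all
    flagged for ``config.tissue``) and the catalog labels the sampled RTT
    and RTT-L seed symbols.
    """
    rng = np.random.default_rng(config.rng_seed)
    if config.backbone == "ba":
        graph = nx.barabasi_albert_graph(
            config.n_nodes, config.attachment_m, seed=config.rng_seed
        )
    elif config.backbone == "er":
        p = 2.0 * config.attachment_m / (config.n_nodes - 1)
        graph = nx.gnp_random_graph(config.n_nodes, p, seed=config.rng_seed)
    else:
        raise SyntheticError(f"unknown backbone {config.backbone!r}")

    n_seeds = config.n_rtt_seeds + config.n_rttl_seeds
    seed_ids = rng.choice(config.n_nodes, size=n_seeds, replace=False)
    rtt_ids = sorted(int(i) for i in seed_ids[: config.n_rtt_seeds])
    rttl_ids = sorted(int(i) for i in seed_ids[config.n_rtt_seeds:])
    rtt_set, rttl_set = set(rtt_ids), set(rttl_ids)
    seed_set = rtt_set | rttl_set

    def common_now():
        out = []
        for node in graph.nodes:
            if node in seed_set:
                continue
            nbrs = set(graph.neighbors(node))
            if nbrs & rtt_set and nbrs & rttl_set:
                out.append(node)
        return out

    # unwire accidental cross-class partners from the RTT side
    for node in common_now():
        for seed in sorted(set(graph.neighbors(node)) & rtt_set):
            graph.remove_edge(node, seed)

    # plant exactly k cross-class partners
    if config.planted_common_k > 0:
        candidates = sorted(set(graph.nodes) - seed_set)
        planted = rng.choice(len(candidates), size=config.planted_common_k, replace=False)
        for idx in planted:
            node = candidates[int(idx)]
            nbrs = set(graph.neighbors(node))
            if not nbrs & rtt_set:
                graph.add_edge(node, rtt_ids[int(rng.integers(len(rtt_ids)))])
            if not nbrs & rttl_set:
                graph.add_edge(node, rttl_ids[int(rng.integers(len(rttl_ids)))])

    edges = [
        make_edge(
            _symbol(a), _symbol(b),
            evidence="experimental",
            sources=("synthetic",),
            tissues=(config.tissue,),
        )
        for a, b in graph.edges()
    ]
    edges.sort(key=lambda e: e.key)

    records = [
        GeneRecord(_symbol(i), GeneClass.RTT_CLASSICAL, "synthetic") for i in rtt_ids
    ] + [
        GeneRecord(_symbol(i), GeneClass.RTTL_LITERATURE, "synthetic") for i in rttl_ids
    ]
    return edges, GeneCatalog(records)


def generate_expression(
    config: SyntheticConfig,
    symbols,
    forced_uncovered=(),
) -> ExpressionTable:
    """Per-symbol ordinal calls for the target tissue.

    Each symbol is independently uncovered (no record at all) with
    ``p_uncovered``, otherwise ``not_detected`` with ``p_not_detected``,
    otherwise low/medium/high uniformly.  ``forced_uncovered`` names symbols
    (e.g. one seed) guaranteed to lack a record, reproducing the scenario of
    a seed dropping out of the tissue network for want of data.
    """
    symbols = sorted(set(symbols))
    if not symbols:
        raise SyntheticError("no symbols supplied")
    forced = set(forced_uncovered)
    rng = np.random.default_rng([config.rng_seed, 1])
    records = []
    for symbol in symbols:
        u = rng.random()
        v = rng.random()
        w = rng.integers(3)
        if symbol in forced or u < config.p_uncovered:
            continue
        if v < config.p_not_detected:
            level = "not_detected"
        else:
            level = ("low", "medium", "high")[int(w)]
        records.append(ExpressionRecord(symbol, config.tissue, level))
    return ExpressionTable(records)


def generate_gmt(config: SyntheticConfig, universe, query, source: str = "GO_BP"):
    """Random term collection with one planted over-represented term.

    The planted term (id ``T_PLANTED``) has exactly ``K`` members of which
    exactly ``k`` come from ``query``; the remaining ``n_terms - 1`` terms
    draw members uniformly from the universe with sizes uniform in
    ``term_size_range``.
    """
    universe = sorted(set(universe))
    query = sorted(set(query))
    K, k = config.planted_term
    non_query = sorted(set(universe) - set(query))
    if k > len(query) or k > K or (K - k) > len(non_query) or K > len(universe):
        raise SyntheticError(
            f"infeasible planted term (K={K}, k={k}) for universe {len(universe)}, "
            f"query {len(query)}"
        )
    rng = np.random.default_rng([config.rng_seed, 2])
    members = [query[int(i)] for i in rng.choice(len(query), size=k, replace=False)]
    members += [
        non_query[int(i)] for i in rng.choice(len(non_query), size=K - k, replace=False)
    ]
    terms = []
    if K > 0:
        terms.append(TermSet("T_PLANTED", "planted over-represented term", source, frozenset(members)))
    lo, hi = config.term_size_range
    for t in range(config.n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        picks = rng.choice(len(universe), size=size, replace=False)
        terms.append(
            TermSet(f"T{t:04d}", f"random term {t}", source,
                    frozenset(universe[int(i)] for i in picks))
        )
    return terms
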