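"""Network topology: degree, betweenness and closeness centralities,
per-class summaries, and hub ranking.

Conventions follow the NetworkAnalyzer defaults for simple undirected
graphs: betweenness counts each unordered pair of distinct endpoints once
and excludes the endpoints themselves (Brandes' algorithm); the normalized
variant divides the raw pair count by (N-1)(N-2)/2.  Closeness uses the
Wasserman-Faust component-scaled form, which is well defined on the
disconnected graphs this pipeline produces (an isolated seed scores 0):

    CC(v) = (n_c - 1) / sum_u d(v, u)  *  (n_c - 1) / (N - 1)

with n_c the size of v's component and N the graph order.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "centrality_table",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "group_summary",
    "rank_hubs",
    "write_centrality_table",
]

METRICS = ("degree", "betweenness_raw", "betweenness_norm", "closeness")


def degree_centrality(network: InteractionNetwork) -> dict[str, int]:
    return dict(network.graph.degree())


def betweenness_centrality(network: InteractionNetwork, normalized: bool = False) -> dict[str, float]:
    """Raw (pair-count) or normalized betweenness, endpoints excluded.

    Disconnected graphs need no special handling: pairs in different
    components have no connecting path and contribute nothing.
    """
    return nx.betweenness_centrality(network.graph, normalized=normalized)


def closeness_centrality(network: InteractionNetwork) -> dict[str, float]:
    """Component-scaled (Wasserman-Faust) closeness in [0, 1]."""
    return nx.closeness_centrality(network.graph, wf_improved=True)


def centrality_table(network: InteractionNetwork) -> pd.DataFrame:
    """One row per node: symbol, class, degree, raw/normalized betweenness,
    closeness.  Sorted by symbol for determinism."""
    graph = network.graph
    n = graph.number_of_nodes()
    bc_raw = betweenness_centrality(network, normalized=False)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    cc = closeness_centrality(network)
    rows = [
        {
            "symbol": node,
            "node_class": graph.nodes[node].get("gene_class", "INTERACTOR"),
            "degree": graph.degree(node),
            "betweenness_raw": bc_raw[node],
            "betweenness_norm": bc_raw[node] * scale,
            "closeness": cc[node],
        }
        for node in sorted(graph.nodes)
    ]
    columns = ["symbol", "node_class"] + list(METRICS)
    return pd.DataFrame(rows, columns=columns)


def group_summary(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Five-number summary of a metric per node class (linear-interpolation
    quartiles).  Classes absent from the table are absent from the output."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    rows = []
    for node_class, sub in table.groupby("node_class", sort=True):
        values = sub[metric].to_numpy(dtype=float)
        q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
        rows.append(
            {
                "node_class": node_class,
                "n": len(values),
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


def rank_hubs(
    table: pd.DataFrame,
    metric: str,
    k: int,
    class_filter: str | None = None,
) -> list[str]:
    """Top-k symbols by a metric, descending; ties broken by symbol.

    If k exceeds the number of available rows, all rows are returned.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = table if class_filter is None else table[table["node_class"] == class_filter]
    ordered = sub.sort_values(
        by=[metric, "symbol"], ascending=[False, True], kind="mergesort"
    )
    if k > len(ordered):
        logger.info("rank_hubs: k=%d exceeds %d rows, returning all", k, len(ordered))
    return ordered["symbol"].head(k).tolist()


def write_centrality_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)
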