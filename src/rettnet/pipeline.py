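"""End-to-end pipeline: catalog -> network -> topology -> tissue filter ->
sub-networks -> common interactors -> enrichment -> report.

Every intermediate is written to the output directory in the exchange
formats of :mod:`rettnet.io_formats`; the final :class:`RunReport` collects
the headline counts of each stage and is fully deterministic given the
inputs (re-running on identical files reproduces byte-identical reports).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import GeneCatalog, GeneClass, load_packaged_catalog, parse_catalog
from .enrich import EnrichmentQuery, run_enrichment
from .io_formats import (
    InteractionDialect,
    read_expression,
    read_gmt,
    read_interactions,
    write_graph,
)
from .netbuild import build_first_order, connected_components
from .subnet import SubnetworkSpec, extract_subnetwork, seed_adjacency_report
from .tissue import filter_network
from .topology import centrality_table, group_summary, rank_hubs, write_centrality_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    interactions: str = ""
    expression: str = ""
    gmt_sources: dict[str, str] = field(default_factory=dict)  # source name -> path
    catalog: str | None = None  # None -> packaged seed lists
    tissue: str = "brain"
    evidence: list[str] = field(default_factory=lambda: ["experimental"])
    rttl_choice: str = "union"  # "union" (cohort + literature) or "literature"
    alpha: float = 0.05
    sidedness: str = "upper"
    universe: str = "source_union"  # "source_union" or "network"
    correction_scope: str = "per_source"
    top_k_hubs: int = 10
    outdir: str = "rettnet_out"
    rng_seed: int = 0
    tissue_columns: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}


@dataclass
class RunReport:
    config: dict
    version: str
    catalog_counts: dict
    network_counts: dict
    n_components: int
    largest_component: int
    filtered_counts: dict
    partner_counts: dict
    seed_seed_edges: int
    top_hubs: dict
    enrichment_summary: dict

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "catalog": self.catalog_counts,
            "network": self.network_counts,
            "n_components": self.n_components,
            "largest_component": self.largest_component,
            "filtered_network": self.filtered_counts,
            "partners": self.partner_counts,
            "seed_seed_edges": self.seed_seed_edges,
            "top_hubs": self.top_hubs,
            "enrichment": self.enrichment_summary,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _load_catalog(config: PipelineConfig) -> GeneCatalog:
    if config.catalog:
        cat = parse_catalog(Path(config.catalog).read_text())
    else:
        cat = load_packaged_catalog()
    if config.rttl_choice == "literature":
        cat = GeneCatalog([r for r in cat.records if r.gene_class != GeneClass.RTTL_COHORT])
    elif config.rttl_choice != "union":
        raise ValueError(f"unknown rttl_choice {config.rttl_choice!r}")
    return cat


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    stage = "catalog"
    t0 = time.monotonic()
    try:
        catalog = _load_catalog(config)
        catalog_counts = {"n_rtt": catalog.n_rtt, "n_rttl": catalog.n_rttl}
        logger.info("catalog: %d RTT, %d RTT-L seeds", catalog.n_rtt, catalog.n_rttl)

        stage = "build"
        dialect = InteractionDialect(tissue_columns=list(config.tissue_columns))
        edges, n_skipped = read_interactions(config.interactions, dialect)
        network = build_first_order(catalog, edges, set(config.evidence))
        write_graph(network.graph, outdir / "network.tsv", "TSV_EDGELIST")
        network_counts = network.counts()
        network_counts["n_input_rows_skipped"] = n_skipped
        logger.info("network: %d nodes, %d edges", network.n_nodes, network.n_edges)

        stage = "topology"
        table = centrality_table(network)
        write_centrality_table(table, outdir / "centrality_full.tsv")
        comps = connected_components(network)

        stage = "tissue_filter"
        expr = read_expression(config.expression)
        filtered, partner_report = filter_network(network, expr, config.tissue)
        write_graph(filtered.graph, outdir / "network_filtered.tsv", "TSV_EDGELIST")
        for name, symbols in (
            ("rtt_partners", partner_report.rtt_partners),
            ("rttl_partners", partner_report.rttl_partners),
            ("common_interactors", partner_report.common),
        ):
            (outdir / f"{name}.txt").write_text("\n".join(sorted(symbols)) + "\n")

        stage = "topology_filtered"
        table_f = centrality_table(filtered)
        write_centrality_table(table_f, outdir / "centrality_filtered.tsv")
        for metric in ("degree", "betweenness_raw"):
            group_summary(table_f, metric).to_csv(
                outdir / f"summary_{metric}.tsv", sep="\t", index=False
            )

        stage = "subnetworks"
        rtt_present = catalog.rtt_symbols & set(network.graph.nodes)
        if rtt_present:
            sub = extract_subnetwork(network, SubnetworkSpec(anchor_seeds=rtt_present))
            write_graph(sub.graph, outdir / "subnetwork_rtt.tsv", "TSV_EDGELIST")
        seed_edges = seed_adjacency_report(network, catalog)
        (outdir / "seed_seed_edges.tsv").write_text(
            "symbol_a\tsymbol_b\tclass_a\tclass_b\n"
            + "".join(f"{a}\t{b}\t{ca}\t{cb}\n" for a, b, ca, cb in seed_edges)
        )

        stage = "hubs"
        top_hubs = {}
        for node_class in ("RTT_SEED", "RTTL_SEED", "INTERACTOR"):
            top_hubs[node_class] = rank_hubs(
                table, "degree", config.top_k_hubs, class_filter=node_class
            ) if (table["node_class"] == node_class).any() else []

        stage = "enrichment"
        enrichment_summary = {}
        if config.gmt_sources:
            sources = [
                read_gmt(path, source=name)
                for name, path in sorted(config.gmt_sources.items())
            ]
            background = (
                set(network.graph.nodes) if config.universe == "network" else None
            )
            query = EnrichmentQuery(
                query_genes=catalog.rtt_symbols | catalog.rttl_symbols,
                background=background,
                sources=sources,
                alpha=config.alpha,
                sidedness=config.sidedness,
                correction_scope=config.correction_scope,
            )
            results = run_enrichment(query)
            with open(outdir / "enrichment.tsv", "w") as fh:
                fh.write("term_id\tsource\tK\tn\tk\tp_raw\tp_adj\tsignificant\toverlap\n")
                for r in results:
                    fh.write(
                        f"{r.term_id}\t{r.source}\t{r.K}\t{r.n}\t{r.k}\t"
                        f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{int(r.significant)}\t"
                        f"{','.join(sorted(r.overlap_symbols))}\n"
                    )
            for name in sorted(config.gmt_sources):
                enrichment_summary[name] = sum(
                    1 for r in results if r.source == name and r.significant
                )

        stage = "report"
        report = RunReport(
            config=config.to_dict(),
            version=__version__,
            catalog_counts=catalog_counts,
            network_counts=network_counts,
            n_components=len(comps),
            largest_component=len(comps[0]) if comps else 0,
            filtered_counts=filtered.counts(),
            partner_counts=partner_report.counts(),
            seed_seed_edges=len(seed_edges),
            top_hubs=top_hubs,
            enrichment_summary=enrichment_summary,
        )
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(render_report(report))
        if marker.exists():
            marker.unlink()
        logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
        return report
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc


def render_report(report: RunReport) -> str:
    d = report.to_dict()
    lines = [
        f"rettnet v{d['version']} run report",
        "",
        f"Seed catalog: {d['catalog']['n_rtt']} RTT, {d['catalog']['n_rttl']} RTT-L genes",
        (
            f"First-order network: {d['network']['n_nodes']} nodes, "
            f"{d['network']['n_edges']} edges "
            f"({d['network']['n_interactors']} interactors, "
            f"{d['network']['n_isolated_seeds']} isolated seeds, "
            f"{d['network']['n_selfloops_dropped']} self-loops dropped)"
        ),
        f"Components: {d['n_components']} (largest {d['largest_component']} nodes)",
        (
            f"Tissue-filtered network: {d['filtered_network']['n_nodes']} nodes, "
            f"{d['filtered_network']['n_edges']} edges"
        ),
        (
            f"Partners: {d['partners']['n_rtt_partners']} RTT, "
            f"{d['partners']['n_rttl_partners']} RTT-L, "
            f"{d['partners']['n_common']} common interactors"
        ),
        f"Seeds dropped by the filter: {', '.join(d['partners']['dropped_seeds']) or 'none'}",
        f"Seed-seed direct edges: {d['seed_seed_edges']}",
    ]
    for node_class, hubs in d["top_hubs"].items():
        if hubs:
            lines.append(f"Top hubs ({node_class}): {', '.join(hubs)}")
    if d["enrichment"]:
        parts = ", ".join(f"{k}: {v}" for k, v in sorted(d["enrichment"].items()))
        lines.append(f"Significant terms per source: {parts}")
    return "\n".join(lines) + "\n"
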