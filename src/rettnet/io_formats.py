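"""Readers and writers for interaction tables, expression tables, GMT gene
sets, and Cytoscape-friendly graph exchange formats.

Interaction tables follow an IID-style tab-separated dialect (two symbol
columns, an evidence class, optional source and per-tissue columns); the
column layout is configuration, not code, since database releases move
columns around.  Expression tables use the four-level ordinal protein-atlas
scale.  Gene sets use the Broad GMT dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .catalog import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "EVIDENCE_CLASSES",
    "EXPRESSION_LEVELS",
    "InteractionEdge",
    "ExpressionRecord",
    "ExpressionTable",
    "TermSet",
    "InteractionDialect",
    "read_interactions",
    "write_interactions",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "write_graph",
    "read_graph_tsv",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


EVIDENCE_CLASSES = ("experimental", "predicted", "orthologous")

#: HPA-style ordinal scale, ascending.
EXPRESSION_LEVELS = ("not_detected", "low", "medium", "high")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(EXPRESSION_LEVELS)}


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected interaction, canonically ordered (symbol_a <= symbol_b)."""

    symbol_a: str
    symbol_b: str
    evidence: str = "experimental"
    sources: frozenset[str] = frozenset()
    tissues: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.symbol_a > self.symbol_b:
            raise FormatError(
                f"edge not canonical: {self.symbol_a!r} > {self.symbol_b!r}"
            )
        if self.evidence not in EVIDENCE_CLASSES:
            raise FormatError(f"unknown evidence class {self.evidence!r}")

    @property
    def is_self_loop(self) -> bool:
        return self.symbol_a == self.symbol_b

    @property
    def key(self) -> tuple[str, str]:
        return (self.symbol_a, self.symbol_b)


def make_edge(a: str, b: str, evidence="experimental", sources=(), tissues=()):
    """Build a canonical edge from raw symbols."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    if a > b:
        a, b = b, a
    return InteractionEdge(a, b, evidence, frozenset(sources), frozenset(tissues))


@dataclass
class InteractionDialect:
    """Column names of an IID-style interaction table."""

    symbol_a: str = "symbol1"
    symbol_b: str = "symbol2"
    evidence: str | None = "evidence_type"
    sources: str | None = "sources"
    tissue_columns: list[str] = field(default_factory=list)
    comment_prefix: str = "#"


def read_interactions(path, dialect: InteractionDialect | None = None):
    """Read an interaction table into canonical, deduplicated edges.

    Duplicate rows for the same unordered symbol pair are merged by taking
    the union of their source and tissue sets (keeping the first evidence
    class seen).  Rows with an empty symbol are skipped with a warning.
    Returns ``(edges, n_skipped)``.
    """
    dialect = dialect or InteractionDialect()
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(dialect.comment_prefix)
    ]
    if not lines:
        return [], 0
    header = lines[0].rstrip("\n").split("\t")
    col = {name: i for i, name in enumerate(header)}
    for required in (dialect.symbol_a, dialect.symbol_b):
        if required not in col:
            raise FormatError(f"missing configured column {required!r} in {path}")
    if dialect.evidence is not None and dialect.evidence not in col:
        raise FormatError(f"missing configured column {dialect.evidence!r} in {path}")

    merged: dict[tuple[str, str], InteractionEdge] = {}
    n_skipped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")

        def get(name):
            i = col[name]
            return fields[i].strip() if i < len(fields) else ""

        raw_a, raw_b = get(dialect.symbol_a), get(dialect.symbol_b)
        if not raw_a or not raw_b:
            logger.warning("%s line %d: empty symbol, row skipped", path, lineno)
            n_skipped += 1
            continue
        evidence = get(dialect.evidence).lower() if dialect.evidence else "experimental"
        if evidence not in EVIDENCE_CLASSES:
            raise FormatError(f"line {lineno}: unknown evidence class {evidence!r}")
        sources = set()
        if dialect.sources and dialect.sources in col:
            sources = {s.strip() for s in get(dialect.sources).split(";") if s.strip()}
        tissues = {
            t for t in dialect.tissue_columns
            if t in col and get(t) not in ("", "0", "-", "N", "n")
        }
        edge = make_edge(raw_a, raw_b, evidence, sources, tissues)
        if edge.key in merged:
            old = merged[edge.key]
            merged[edge.key] = replace(
                old,
                sources=old.sources | edge.sources,
                tissues=old.tissues | edge.tissues,
            )
        else:
            merged[edge.key] = edge
    return [merged[k] for k in sorted(merged)], n_skipped


def write_interactions(edges, path, tissue_columns=(), header_comment: str | None = None):
    """Write edges in the IID-style dialect that :func:`read_interactions`
    reads back (default column names, one flag column per listed tissue)."""
    tissue_columns = list(tissue_columns)
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("\t".join(["symbol1", "symbol2", "evidence_type", "sources"] + tissue_columns))
    for e in sorted(edges, key=lambda e: e.key):
        row = [e.symbol_a, e.symbol_b, e.evidence, ";".join(sorted(e.sources))]
        row += ["1" if t in e.tissues else "0" for t in tissue_columns]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _normalize_level(text: str) -> str:
    level = text.strip().lower().replace(" ", "_")
    if level not in _LEVEL_RANK:
        raise FormatError(f"unknown expression level {text!r}")
    return level


@dataclass(frozen=True)
class ExpressionRecord:
    symbol: str
    tissue: str
    level: str

    def __post_init__(self):
        if self.level not in _LEVEL_RANK:
            raise FormatError(f"unknown expression level {self.level!r}")


@dataclass
class ExpressionTable:
    """Protein x tissue ordinal expression calls, unique per (symbol, tissue).

    Tissue names are matched case-insensitively.  Duplicate calls for the
    same (symbol, tissue) are aggregated by the maximum ordinal level.
    """

    records: list[ExpressionRecord] = field(default_factory=list)

    def __post_init__(self):
        self._levels: dict[tuple[str, str], str] = {}
        for rec in self.records:
            key = (rec.symbol, rec.tissue.lower())
            old = self._levels.get(key)
            if old is None or _LEVEL_RANK[rec.level] > _LEVEL_RANK[old]:
                self._levels[key] = rec.level
        # re-materialize the aggregated records
        self.records = [
            ExpressionRecord(sym, tissue, lvl)
            for (sym, tissue), lvl in sorted(self._levels.items())
        ]

    def level(self, symbol: str, tissue: str) -> str | None:
        return self._levels.get((normalize_symbol(symbol), tissue.lower()))

    def covered_symbols(self, tissue: str) -> set[str]:
        t = tissue.lower()
        return {sym for (sym, tis) in self._levels if tis == t}

    def __len__(self):
        return len(self.records)


def read_expression(path) -> ExpressionTable:
    """Read a tab-separated symbol/tissue/level table (header optional)."""
    records = []
    first_data_line = True
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path} line {lineno}: expected symbol/tissue/level")
        if first_data_line:
            first_data_line = False
            if fields[0].strip().lower() in ("symbol", "gene"):
                continue
        try:
            level = _normalize_level(fields[2])
        except FormatError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
        records.append(
            ExpressionRecord(normalize_symbol(fields[0]), fields[1].strip().lower(), level)
        )
    return ExpressionTable(records)


def write_expression(table: ExpressionTable, path, header_comment: str | None = None):
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("symbol\ttissue\tlevel")
    for rec in table.records:
        lines.append(f"{rec.symbol}\t{rec.tissue}\t{rec.level}")
    Path(path).write_text("\n".join(lines) + "\n")


TERM_SOURCES = ("GO_BP", "KEGG", "REACTOME", "WIKIPATHWAYS", "TF", "MIRNA")


@dataclass(frozen=True)
class TermSet:
    """One annotation term (gene set) from a named source."""

    term_id: str
    term_name: str
    source: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"term {self.term_id!r} has no members")


def read_gmt(path, source: str = "GO_BP") -> list[TermSet]:
    """Read a Broad-dialect GMT file: ``term_id TAB description TAB genes...``."""
    terms = []
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path} line {lineno}: GMT line needs >= 3 fields")
        term_id = fields[0].strip()
        if term_id in seen:
            raise FormatError(f"{path} line {lineno}: duplicate term_id {term_id!r}")
        seen.add(term_id)
        members = frozenset(
            normalize_symbol(g) for g in fields[2:] if g.strip()
        )
        if not members:
            raise FormatError(f"{path} line {lineno}: term {term_id!r} has no members")
        terms.append(TermSet(term_id, fields[1].strip(), source, members))
    return terms


def write_gmt(terms, path, header_comment: str | None = None):
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    for term in terms:
        lines.append("\t".join([term.term_id, term.term_name] + sorted(term.members)))
    Path(path).write_text("\n".join(lines) + "\n")


GRAPH_FORMATS = ("TSV_EDGELIST", "SIF", "GRAPHML")


def write_graph(graph: nx.Graph, path, fmt: str = "TSV_EDGELIST"):
    """Export a network deterministically (edges sorted by symbol pair).

    ``GRAPHML`` carries the ``gene_class`` node attribute inline; ``SIF`` and
    ``TSV_EDGELIST`` get a ``<path>.nodes.tsv`` sidecar with the classes.
    SIF uses interaction type ``pp``.
    """
    fmt = fmt.upper()
    if fmt not in GRAPH_FORMATS:
        raise FormatError(f"unknown graph format {fmt!r}")
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    if fmt == "GRAPHML":
        out = nx.Graph()
        for node in sorted(graph.nodes()):
            out.add_node(node, gene_class=str(graph.nodes[node].get("gene_class", "")))
        out.add_edges_from(edges)
        nx.write_graphml(out, path)
        return
    if fmt == "SIF":
        lines = [f"{a} pp {b}" for a, b in edges]
        isolated = sorted(n for n in graph.nodes() if graph.degree(n) == 0)
        lines += isolated
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:  # TSV_EDGELIST
        lines = ["symbol_a\tsymbol_b"] + [f"{a}\t{b}" for a, b in edges]
        path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
    node_lines = ["symbol\tgene_class"] + [
        f"{n}\t{graph.nodes[n].get('gene_class', '')}" for n in sorted(graph.nodes())
    ]
    sidecar.write_text("\n".join(node_lines) + "\n")


def read_graph_tsv(path) -> nx.Graph:
    """Read back a TSV edge list written by :func:`write_graph`, restoring
    node classes from the sidecar if present."""
    path = Path(path)
    graph = nx.Graph()
    lines = path.read_text().splitlines()
    for line in lines[1:]:
        if line.strip():
            a, b = line.split("\t")[:2]
            graph.add_edge(a, b)
    sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines()[1:]:
            if line.strip():
                parts = line.split("\t")
                symbol = parts[0]
                gene_class = parts[1] if len(parts) > 1 else ""
                graph.add_node(symbol, gene_class=gene_class)
    return graph
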