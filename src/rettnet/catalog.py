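"""Curated seed-gene catalogs and cohort phenotype tables.

The analysis anchors a protein-protein interaction network on two groups of
seed genes: the classical/atypical Rett syndrome (RTT) genes and the larger
Rett-syndrome-like (RTT-L) set, the latter combining a sequenced patient
cohort with genes curated from the literature.  This module parses, validates
and combines those lists, parses the cohort phenotype/variant table, and
tabulates how many main diagnostic criteria each patient meets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "GeneClass",
    "GeneRecord",
    "GeneCatalog",
    "PatientRecord",
    "CriteriaProfile",
    "CatalogError",
    "normalize_symbol",
    "parse_catalog",
    "serialize_catalog",
    "combine_rttl",
    "parse_patients",
    "tabulate_criteria",
    "load_packaged_catalog",
    "load_packaged_patients",
    "PHENOTYPE_COLUMNS",
    "DEFAULT_CRITERIA_MAP",
]


class CatalogError(ValueError):
    """Raised for malformed seed lists or patient tables."""


class GeneClass:
    """Closed vocabulary of seed-gene classes."""

    RTT_CLASSICAL = "RTT_CLASSICAL"
    RTT_ATYPICAL = "RTT_ATYPICAL"
    RTTL_COHORT = "RTTL_COHORT"
    RTTL_LITERATURE = "RTTL_LITERATURE"

    ALL = (RTT_CLASSICAL, RTT_ATYPICAL, RTTL_COHORT, RTTL_LITERATURE)
    RTT = (RTT_CLASSICAL, RTT_ATYPICAL)
    RTTL = (RTTL_COHORT, RTTL_LITERATURE)


# accepted spellings for class labels in input files
_CLASS_ALIASES = {
    "RTT_CLASSICAL": GeneClass.RTT_CLASSICAL,
    "RTT": GeneClass.RTT_CLASSICAL,
    "RTT_ATYPICAL": GeneClass.RTT_ATYPICAL,
    "RTTL_COHORT": GeneClass.RTTL_COHORT,
    "RTT-L_COHORT": GeneClass.RTTL_COHORT,
    "RTTL_LITERATURE": GeneClass.RTTL_LITERATURE,
    "RTT-L_LITERATURE": GeneClass.RTTL_LITERATURE,
    "RTT-L": GeneClass.RTTL_LITERATURE,
    "RTTL": GeneClass.RTTL_LITERATURE,
}

#: The twelve phenotype columns of the cohort table, in file order.
PHENOTYPE_COLUMNS = (
    "Developmental Regression",
    "Developmental Delay",
    "Intellectual Disability",
    "Microcephaly",
    "Loss of Hand Use",
    "Stereotyped Hand Movements",
    "Involuntary Tongue Movements",
    "Hyperventilation",
    "Choreoathetosis",
    "Early Epileptic Encephalopathy",
    "Hypotonia",
    "Scoliosis",
)

#: Main diagnostic criteria that have a matching phenotype column.  The
#: criteria "gait abnormalities" and "loss of spoken language" have no
#: column in the cohort table and are deliberately not mapped.
DEFAULT_CRITERIA_MAP = {
    "regression": "Developmental Regression",
    "loss_of_hand_skills": "Loss of Hand Use",
    "hand_stereotypies": "Stereotyped Hand Movements",
}


def normalize_symbol(symbol: str) -> str:
    """Uppercase, trim, and strip all internal whitespace from a gene symbol.

    No alias/HGNC resolution is attempted: the pipeline works at the symbol
    level exactly as curated.
    """
    return re.sub(r"\s+", "", symbol).upper()


@dataclass(frozen=True, order=True)
class GeneRecord:
    symbol: str
    gene_class: str
    provenance: str = ""

    def __post_init__(self):
        if not self.symbol:
            raise CatalogError("empty gene symbol")
        if re.search(r"\s", self.symbol):
            raise CatalogError(f"gene symbol contains whitespace: {self.symbol!r}")
        if self.gene_class not in GeneClass.ALL:
            raise CatalogError(f"unknown gene class: {self.gene_class!r}")


@dataclass
class GeneCatalog:
    """A collection of seed-gene records with per-group distinct counts.

    A symbol may legitimately appear under more than one class (MECP2 is both
    classical and atypical; TCF4 is both cohort and literature RTT-L); the
    distinct-symbol counts ``n_rtt`` and ``n_rttl`` deduplicate across the
    classes of each group.
    """

    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = (rec.symbol, rec.gene_class)
            if key in seen:
                raise CatalogError(f"duplicate record {key}")
            seen.add(key)

    def symbols(self, *classes: str) -> set[str]:
        wanted = set(classes) if classes else set(GeneClass.ALL)
        return {r.symbol for r in self.records if r.gene_class in wanted}

    @property
    def rtt_symbols(self) -> set[str]:
        return self.symbols(*GeneClass.RTT)

    @property
    def rttl_symbols(self) -> set[str]:
        return self.symbols(*GeneClass.RTTL)

    @property
    def n_rtt(self) -> int:
        return len(self.rtt_symbols)

    @property
    def n_rttl(self) -> int:
        return len(self.rttl_symbols)

    def seed_class(self, symbol: str) -> str | None:
        """Seed group for a symbol: RTT takes precedence over RTT-L."""
        if symbol in self.rtt_symbols:
            return "RTT"
        if symbol in self.rttl_symbols:
            return "RTTL"
        return None


def _resolve_class(label: str, lineno: int) -> str:
    key = label.strip().upper().replace(" ", "_")
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise CatalogError(f"line {lineno}: unknown class label {label!r}") from None


def parse_catalog(table_text: str, provenance: str = "") -> GeneCatalog:
    """Parse a two-column seed list: ``class_label <TAB or :> symbols``.

    Symbols are comma-separated, normalized, and deduplicated per class.
    Lines starting with ``#`` and blank lines are ignored.
    """
    records: list[GeneRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            label, _, rest = line.partition("\t")
        elif ":" in line:
            label, _, rest = line.partition(":")
        else:
            raise CatalogError(f"line {lineno}: expected 'class<TAB>symbols'")
        gene_class = _resolve_class(label, lineno)
        for token in rest.split(","):
            if not token.strip():
                raise CatalogError(f"line {lineno}: empty symbol in row {label!r}")
            symbol = normalize_symbol(token)
            key = (symbol, gene_class)
            if key in seen:
                continue
            seen.add(key)
            records.append(GeneRecord(symbol, gene_class, provenance))
    return GeneCatalog(records)


def serialize_catalog(catalog: GeneCatalog) -> str:
    """Write a catalog back to the seed-list dialect (round-trips with
    :func:`parse_catalog`)."""
    lines = []
    for gene_class in GeneClass.ALL:
        symbols = sorted(catalog.symbols(gene_class))
        if symbols:
            lines.append(f"{gene_class}\t{', '.join(symbols)}")
    return "\n".join(lines) + "\n"


def combine_rttl(cohort: GeneCatalog, literature: GeneCatalog):
    """Union the two RTT-L sources into one catalog.

    Dual membership is preserved as two records (one per class).  Returns
    ``(combined_catalog, overlap_symbols)`` where the overlap is the set of
    symbols present in both sources.
    """
    records = list(cohort.records) + [
        r for r in literature.records
        if (r.symbol, r.gene_class) not in {(c.symbol, c.gene_class) for c in cohort.records}
    ]
    overlap = cohort.rttl_symbols & literature.rttl_symbols
    return GeneCatalog(records), overlap


@dataclass
class PatientRecord:
    patient_id: int
    phenotype_flags: dict[str, bool]
    gene: str
    genomic_coordinates: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    cadd_phred: float = 0.0

    def __post_init__(self):
        if self.patient_id <= 0:
            raise CatalogError(f"patient_id must be positive: {self.patient_id}")
        missing = set(PHENOTYPE_COLUMNS) - set(self.phenotype_flags)
        if missing:
            raise CatalogError(f"patient {self.patient_id}: missing flags {sorted(missing)}")
        if self.cadd_phred < 0:
            raise CatalogError(f"patient {self.patient_id}: negative CADD score")


def parse_patients(table_text: str) -> list[PatientRecord]:
    """Parse the tab-separated cohort table (Y/N phenotype flags).

    The header must contain the twelve phenotype columns plus ``Patient`` and
    ``Gene``; variant and CADD columns are carried through as data.
    """
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    col = {name: i for i, name in enumerate(header)}
    required = ("Patient", "Gene") + PHENOTYPE_COLUMNS
    missing = [c for c in required if c not in col]
    if missing:
        raise CatalogError(f"patient table missing columns: {missing}")

    def get(fields, name, default=""):
        i = col.get(name)
        return fields[i] if i is not None and i < len(fields) else default

    patients = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        flags = {}
        for pheno in PHENOTYPE_COLUMNS:
            value = get(fields, pheno).strip().upper()
            if value not in ("Y", "N"):
                raise CatalogError(
                    f"line {lineno}, column {pheno!r}: flag must be Y or N, got {value!r}"
                )
            flags[pheno] = value == "Y"
        cadd_text = get(fields, "CADD PHRED Score", "0").strip()
        patients.append(
            PatientRecord(
                patient_id=int(get(fields, "Patient")),
                phenotype_flags=flags,
                gene=normalize_symbol(get(fields, "Gene")),
                genomic_coordinates=get(fields, "Variant: Genomic Coordinates").strip(),
                cdna_change=get(fields, "cDNA Change").strip(),
                protein_change=get(fields, "Protein Change").strip(),
                cadd_phred=float(cadd_text) if cadd_text else 0.0,
            )
        )
    return patients


@dataclass
class CriteriaProfile:
    patient_id: int
    n_main_criteria_met: int
    criteria_used: list[str]

    def __post_init__(self):
        if not 0 <= self.n_main_criteria_met <= len(self.criteria_used):
            raise CatalogError("criteria count out of bounds")


def tabulate_criteria(
    patients: list[PatientRecord],
    criteria_map: dict[str, str] | None = None,
):
    """Count, per patient, how many mapped main criteria are flagged present.

    Returns ``(profiles, per_criterion_frequency)``; the frequency counts how
    many patients are positive for each mapped criterion.
    """
    if criteria_map is None:
        criteria_map = DEFAULT_CRITERIA_MAP
    for criterion, column in criteria_map.items():
        if column not in PHENOTYPE_COLUMNS:
            raise CatalogError(f"criterion {criterion!r} maps to unknown column {column!r}")
    criteria = sorted(criteria_map)
    profiles = []
    frequency = {c: 0 for c in criteria}
    for patient in patients:
        met = 0
        for criterion in criteria:
            if patient.phenotype_flags[criteria_map[criterion]]:
                met += 1
                frequency[criterion] += 1
        profiles.append(CriteriaProfile(patient.patient_id, met, criteria))
    return profiles, frequency


def _read_packaged(name: str) -> str:
    return (resources.files("rettnet") / "data" / name).read_text()


def load_packaged_catalog() -> GeneCatalog:
    """The curated seed-gene lists shipped with the package."""
    return parse_catalog(_read_packaged("seed_genes.tsv"), provenance="packaged")


def load_packaged_patients() -> list[PatientRecord]:
    """The packaged cohort phenotype/variant table (8 patients)."""
    return parse_patients(_read_packaged("cohort_patients.tsv"))
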