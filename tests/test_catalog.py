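"""Seed-list and cohort-table parsing against the packaged curated data."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rettnet.catalog import (
    CatalogError,
    DEFAULT_CRITERIA_MAP,
    GeneCatalog,
    GeneClass,
    GeneRecord,
    combine_rttl,
    load_packaged_catalog,
    load_packaged_patients,
    normalize_symbol,
    parse_catalog,
    parse_patients,
    serialize_catalog,
    tabulate_criteria,
)


class TestParseCatalog:
    def test_packaged_counts(self):
        """The curated lists carry 4 distinct RTT genes, 58 literature RTT-L
        genes, and 60 RTT-L genes overall (cohort brings 2 new symbols)."""
        cat = load_packaged_catalog()
        assert cat.n_rtt == 4
        assert len(cat.symbols(GeneClass.RTTL_LITERATURE)) == 58
        assert cat.n_rttl == 60
        assert cat.rtt_symbols == {"MECP2", "CDKL5", "FOXG1", "NTNG1"}

    def test_normalization_dedups(self):
        cat = parse_catalog("RTT-L: tcf4, TCF4 ")
        assert [r.symbol for r in cat.records] == ["TCF4"]

    def test_mecp2_counted_once_across_rtt_classes(self):
        cat = load_packaged_catalog()
        classes = {r.gene_class for r in cat.records if r.symbol == "MECP2"}
        assert classes == {GeneClass.RTT_CLASSICAL, GeneClass.RTT_ATYPICAL}
        assert cat.n_rtt == len(cat.rtt_symbols)  # distinct-symbol count

    @pytest.mark.parametrize(
        "text,match",
        [
            ("RTT_CLASSICAL\tMECP2,,FOXG1", "empty symbol"),
            ("NOT_A_CLASS\tGENE1", "unknown class"),
        ],
    )
    def test_errors_name_the_row(self, text, match):
        with pytest.raises(CatalogError, match=match):
            parse_catalog(text)

    def test_round_trip(self):
        cat = load_packaged_catalog()
        again = parse_catalog(serialize_catalog(cat))
        assert {(r.symbol, r.gene_class) for r in again.records} == {
            (r.symbol, r.gene_class) for r in cat.records
        }

    @given(st.permutations(["RTT_CLASSICAL\tMECP2", "RTT_ATYPICAL\tCDKL5, FOXG1",
                            "RTTL_COHORT\tTCF4, GRIN1", "RTTL_LITERATURE\tTCF4, HTT"]))
    @settings(derandomize=True, max_examples=24)
    def test_counts_permutation_invariant(self, rows):
        cat = parse_catalog("\n".join(rows))
        assert cat.n_rtt == 3
        assert cat.n_rttl == 3


class TestCombineRttl:
    def test_cohort_plus_literature_union(self):
        """8 cohort genes overlap the 58 literature genes in 6 symbols,
        leaving a union of 60 distinct RTT-L genes."""
        cat = load_packaged_catalog()
        cohort = GeneCatalog([r for r in cat.records if r.gene_class == GeneClass.RTTL_COHORT])
        literature = GeneCatalog(
            [r for r in cat.records if r.gene_class == GeneClass.RTTL_LITERATURE]
        )
        combined, overlap = combine_rttl(cohort, literature)
        assert combined.n_rttl == 60
        assert overlap == {"GABRG2", "GRIN1", "GRIN2A", "KCNB1", "KCNQ2", "TCF4"}
        # dual membership preserved as two records
        assert sum(1 for r in combined.records if r.symbol == "TCF4") == 2

    def test_empty_cohort_is_identity(self):
        lit = parse_catalog("RTTL_LITERATURE\tA, B, C")
        combined, overlap = combine_rttl(GeneCatalog([]), lit)
        assert combined.rttl_symbols == {"A", "B", "C"}
        assert overlap == set()

    @given(
        st.sets(st.sampled_from("ABCDEFGH"), max_size=6),
        st.sets(st.sampled_from("EFGHIJKL"), max_size=6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_union_count_is_set_union(self, cohort_syms, lit_syms):
        cohort = GeneCatalog([GeneRecord(s, GeneClass.RTTL_COHORT) for s in cohort_syms])
        lit = GeneCatalog([GeneRecord(s, GeneClass.RTTL_LITERATURE) for s in lit_syms])
        combined, overlap = combine_rttl(cohort, lit)
        assert combined.n_rttl == len(cohort_syms | lit_syms)
        assert overlap == cohort_syms & lit_syms


class TestPatients:
    def test_packaged_cohort(self):
        patients = load_packaged_patients()
        assert len(patients) == 8
        assert patients[0].gene == "GABRG2"
        assert patients[0].cadd_phred == 22.2

    def test_empty_body(self):
        header = "\t".join(
            ["Patient"] + list(DEFAULT_CRITERIA_MAP.values())
            + ["Developmental Delay", "Intellectual Disability", "Microcephaly",
               "Involuntary Tongue Movements", "Hyperventilation", "Choreoathetosis",
               "Early Epileptic Encephalopathy", "Hypotonia", "Scoliosis", "Gene"]
        )
        assert parse_patients(header) == []

    def test_bad_flag_names_row_and_column(self):
        from rettnet.catalog import _read_packaged

        table = _read_packaged("cohort_patients.tsv").replace("\n1\tY", "\n1\tX", 1)
        with pytest.raises(CatalogError, match="Developmental Regression"):
            parse_patients(table)


class TestCriteria:
    def test_patient3_meets_all_mapped_main_criteria(self):
        """Patient 3 is positive for regression, loss of hand use and hand
        stereotypies — all three mapped main criteria."""
        patients = load_packaged_patients()
        profiles, _ = tabulate_criteria(patients)
        by_id = {p.patient_id: p for p in profiles}
        assert by_id[3].n_main_criteria_met == 3

    def test_empty_map_gives_zero_counts(self):
        patients = load_packaged_patients()
        profiles, freq = tabulate_criteria(patients, criteria_map={})
        assert all(p.n_main_criteria_met == 0 for p in profiles)
        assert freq == {}

    def test_frequencies_equal_column_recounts(self):
        patients = load_packaged_patients()
        _, freq = tabulate_criteria(patients)
        for criterion, column in DEFAULT_CRITERIA_MAP.items():
            recount = sum(1 for p in patients if p.phenotype_flags[column])
            assert freq[criterion] == recount

    def test_unmapped_criterion_errors(self):
        with pytest.raises(CatalogError, match="unknown column"):
            tabulate_criteria(load_packaged_patients(), {"gait": "Gait Abnormalities"})


def test_normalize_symbol_idempotent():
    for raw in ("  tcf4 ", "T CF4", "MeCp2"):
        once = normalize_symbol(raw)
        assert normalize_symbol(once) == once
        assert " " not in once and once == once.upper()
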