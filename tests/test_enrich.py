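"""Hypergeometric tails against exact rational enumeration; ORA wiring."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rettnet.enrich import (
    EnrichmentError,
    EnrichmentQuery,
    PathwayMap,
    hypergeom_two_sided,
    hypergeom_upper,
    map_pathway,
    run_enrichment,
)
from rettnet.io_formats import TermSet

from conftest import network_from
from oracles import hyper_pmf, hyper_two_sided, hyper_upper


def all_cases(n_max):
    for N in range(1, n_max + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, n + K - N), min(K, n) + 1):
                    yield N, K, n, k


class TestHypergeomUpper:
    def test_known_value(self):
        # drawing 4 of the 5 marked items in 4 draws from 10: 5 / C(10,4)
        assert hypergeom_upper(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_k0_is_certain(self):
        assert hypergeom_upper(30, 10, 5, 0) == 1.0

    def test_term_equals_universe(self):
        assert hypergeom_upper(7, 7, 3, 3) == 1.0

    def test_bounds_checked(self):
        with pytest.raises(EnrichmentError):
            hypergeom_upper(10, 5, 4, 5)
        with pytest.raises(EnrichmentError):
            hypergeom_upper(10, 11, 4, 2)

    def test_exhaustive_small_universes(self):
        """Log-space upper tail agrees with exact rational enumeration for
        every admissible (N <= 12, K, n, k)."""
        for N, K, n, k in all_cases(12):
            exact = float(hyper_upper(N, K, n, k))
            got = hypergeom_upper(N, K, n, k)
            assert abs(got - exact) <= 1e-12 * max(exact, 1e-300), (N, K, n, k)

    def test_monotone_in_k(self):
        for N, K, n in [(40, 12, 9), (25, 25, 10), (18, 5, 18)]:
            values = [hypergeom_upper(N, K, n, k)
                      for k in range(max(0, n + K - N), min(K, n) + 1)]
            assert values == sorted(values, reverse=True)


class TestHypergeomTwoSided:
    def test_symmetric_case(self):
        # N=8, K=4, n=4: P(X=4) = P(X=0), so the two-sided p at k=4 is both tails
        exact = float(hyper_pmf(8, 4, 4, 4) + hyper_pmf(8, 4, 4, 0))
        assert hypergeom_two_sided(8, 4, 4, 4) == pytest.approx(exact, rel=1e-12)

    def test_mode_gives_one(self):
        # at the most likely outcome every other outcome is included
        assert hypergeom_two_sided(10, 5, 4, 2) == pytest.approx(1.0, rel=1e-9)

    def test_exhaustive_small_universes(self):
        for N, K, n, k in all_cases(12):
            exact = float(hyper_two_sided(N, K, n, k))
            got = hypergeom_two_sided(N, K, n, k)
            assert abs(got - exact) <= 1e-12 * max(exact, 1e-300), (N, K, n, k)

    @given(st.integers(2, 60), st.data())
    @settings(derandomize=True, max_examples=60)
    def test_at_least_min_tail(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        lo, hi = max(0, n + K - N), min(K, n)
        k = data.draw(st.integers(lo, hi))
        upper = hypergeom_upper(N, K, n, k)
        lower = float(sum(hyper_pmf(N, K, n, i) for i in range(lo, k + 1)))
        assert hypergeom_two_sided(N, K, n, k) >= min(upper, lower) - 1e-12


UNIVERSE = {chr(ord("A") + i) for i in range(10)}  # A..J


def term(term_id, members, source="GO_BP"):
    return TermSet(term_id, term_id, source, frozenset(members))


class TestRunEnrichment:
    def test_single_term_worked_example(self):
        results = run_enrichment(
            EnrichmentQuery(
                query_genes={"A", "B", "C", "D"},
                background=UNIVERSE,
                sources=[[term("T1", {"A", "B", "C", "D", "E"})]],
            )
        )
        (r,) = results
        assert (r.K, r.n, r.k) == (5, 4, 4)
        assert r.p_raw == pytest.approx(5 / 210, rel=1e-9)
        assert r.p_adj == pytest.approx(5 / 210, rel=1e-9)  # m = 1
        assert r.significant

    def test_bonferroni_scope(self):
        terms = [term("T1", {"A", "B", "C", "D", "E"}), term("T2", set(UNIVERSE))]
        results = run_enrichment(
            EnrichmentQuery({"A", "B", "C", "D"}, UNIVERSE, [terms])
        )
        by_id = {r.term_id: r for r in results}
        assert by_id["T1"].p_adj == pytest.approx(2 * by_id["T1"].p_raw)

    def test_k0_terms_counted_in_m_not_reported(self):
        terms = [term("HIT", {"A", "B"}), term("MISS", {"I", "J"})]
        results = run_enrichment(EnrichmentQuery({"A", "B"}, UNIVERSE, [terms]))
        assert [r.term_id for r in results] == ["HIT"]
        assert results[0].p_adj == pytest.approx(min(1.0, 2 * results[0].p_raw))

    def test_default_background_is_source_union(self):
        terms = [term("T1", {"A", "B", "C"}), term("T2", {"C", "D"})]
        (r,) = run_enrichment(EnrichmentQuery({"A", "B"}, None, [terms]))[:1]
        assert r.n == 2 and r.K == 3  # universe {A,B,C,D}

    def test_empty_query_after_restriction_errors(self):
        terms = [term("T1", {"A", "B"})]
        with pytest.raises(EnrichmentError, match="empty"):
            run_enrichment(EnrichmentQuery({"Z9"}, None, [terms]))

    def test_order_invariance(self):
        t1 = term("T1", {"A", "B", "C"})
        t2 = term("T2", {"B", "C", "D", "E"})
        q = {"A", "B", "C"}
        r12 = run_enrichment(EnrichmentQuery(q, UNIVERSE, [[t1, t2]]))
        r21 = run_enrichment(EnrichmentQuery(q, UNIVERSE, [[t2, t1]]))
        assert [(r.term_id, r.p_raw, r.p_adj) for r in r12] == [
            (r.term_id, r.p_raw, r.p_adj) for r in r21
        ]

    def test_two_sided_mode(self):
        results = run_enrichment(
            EnrichmentQuery(
                {"A", "B", "C", "D"}, UNIVERSE,
                [[term("T1", {"A", "B", "C", "D", "E"})]],
                sidedness="two_sided",
            )
        )
        assert results[0].p_raw == pytest.approx(
            float(hyper_two_sided(10, 5, 4, 4)), rel=1e-9
        )


class TestMapPathway:
    def test_seed_and_shared_interactor(self):
        net, catalog = network_from(
            [("S1", "X"), ("T1", "X"), ("S1", "T1")], rtt=["S1"], rttl=["T1"]
        )
        pm = map_pathway(net, catalog, term("WP", {"S1", "X"}))
        assert pm.member_seeds_by_class["RTT"] == {"S1"}
        assert pm.shared_interactors_in_pathway == {"X"}

    def test_disjoint_pathway_empty_map(self):
        net, catalog = network_from([("S1", "X")], rtt=["S1"])
        pm = map_pathway(net, catalog, term("WP", {"Q1", "Q2"}))
        assert pm.counts()["n_rtt_members"] == 0
        assert pm.shared_interactors_in_pathway == set()

    def test_planted_class_membership_counts(self):
        rtt = [f"R{i}" for i in range(4)]
        rttl = [f"L{i}" for i in range(30)]
        edges = [(s, "HUB") for s in rtt + rttl]
        net, catalog = network_from(edges, rtt=rtt, rttl=rttl)
        pathway = term("WP", set(rtt[:3]) | set(rttl[:22]) | {"HUB"})
        pm = map_pathway(net, catalog, pathway)
        assert len(pm.member_seeds_by_class["RTT"]) == 3
        assert len(pm.member_seeds_by_class["RTTL"]) == 22
        assert pm.shared_interactors_in_pathway == {"HUB"}
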