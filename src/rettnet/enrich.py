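"""Multi-source over-representation analysis (ORA).

For a query gene set of size n drawn from a background universe of size N,
the overlap k with an annotation term of size K follows a hypergeometric
distribution under the null of no association.  Enrichment is the upper
tail P(X >= k); a two-sided minimum-likelihood variant (the sum of all
outcome probabilities no larger than that of the observed overlap) is also
provided.  Raw p-values are Bonferroni-corrected within each annotation
source by default (p_adj = min(1, m * p_raw) with m the number of terms in
the correction scope), with an option for a global correction.

Tail sums are accumulated in log space from the hypergeometric log-pmf, so
deep tails (p far below float underflow of individual products of binomial
coefficients) stay accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .catalog import GeneCatalog
from .io_formats import TermSet
from .netbuild import InteractionNetwork
from .tissue import common_interactors

__all__ = [
    "EnrichmentError",
    "EnrichmentQuery",
    "EnrichmentResult",
    "PathwayMap",
    "hypergeom_upper",
    "hypergeom_two_sided",
    "run_enrichment",
    "map_pathway",
]


class EnrichmentError(ValueError):
    pass


def _check_bounds(N: int, K: int, n: int, k: int):
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"invalid hypergeometric bounds N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise EnrichmentError(
            f"overlap k={k} outside support [{max(0, n + K - N)}, {min(K, n)}] "
            f"for N={N}, K={K}, n={n}"
        )


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact via log-space summation."""
    _check_bounds(N, K, n, k)
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(hypergeom.logpmf(support, N, K, n)))))


def hypergeom_two_sided(N: int, K: int, n: int, k: int) -> float:
    """Minimum-likelihood two-sided p: sum of P(X = i) over all outcomes i
    at most as probable as the observed k (within a small relative slack to
    absorb floating-point ties), capped at 1."""
    _check_bounds(N, K, n, k)
    lo, hi = max(0, n + K - N), min(K, n)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    log_obs = hypergeom.logpmf(k, N, K, n)
    include = logp <= log_obs + 1e-9
    return float(min(1.0, np.exp(logsumexp(logp[include]))))


@dataclass
class EnrichmentQuery:
    query_genes: set[str]
    background: set[str] | None = None
    sources: list[list[TermSet]] = field(default_factory=list)
    alpha: float = 0.05
    sidedness: str = "upper"  # or "two_sided"
    correction_scope: str = "per_source"  # or "global"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise EnrichmentError(f"alpha must be in (0,1), got {self.alpha}")
        if self.sidedness not in ("upper", "two_sided"):
            raise EnrichmentError(f"unknown sidedness {self.sidedness!r}")
        if self.correction_scope not in ("per_source", "global"):
            raise EnrichmentError(f"unknown correction scope {self.correction_scope!r}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    source: str
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float
    overlap_symbols: frozenset[str]
    significant: bool = False


def run_enrichment(query: EnrichmentQuery) -> list[EnrichmentResult]:
    """One result per term with non-empty overlap, sorted by (p_adj, term_id).

    The background universe defaults, per source, to the union of that
    source's member symbols; the query is restricted to the background
    before testing.  Terms with k = 0 still count toward the Bonferroni m
    but are not reported.
    """
    if not query.sources:
        return []
    per_source: list[tuple[list[TermSet], set[str], set[str]]] = []
    any_query = False
    for terms in query.sources:
        background = (
            set(query.background)
            if query.background is not None
            else set().union(*(t.members for t in terms)) if terms else set()
        )
        q = query.query_genes & background
        any_query = any_query or bool(q)
        per_source.append((terms, background, q))
    if not any_query:
        raise EnrichmentError("query is empty after restriction to the background")

    test = hypergeom_upper if query.sidedness == "upper" else hypergeom_two_sided
    m_global = sum(len(terms) for terms, _, _ in per_source)
    results = []
    for terms, background, q in per_source:
        m = m_global if query.correction_scope == "global" else len(terms)
        for term in terms:
            members = term.members & background
            overlap = q & members
            if not overlap:
                continue  # counted in m, not reported
            p_raw = test(len(background), len(members), len(q), len(overlap))
            p_adj = min(1.0, m * p_raw)
            results.append(
                EnrichmentResult(
                    term_id=term.term_id,
                    term_name=term.term_name,
                    source=term.source,
                    K=len(members),
                    n=len(q),
                    k=len(overlap),
                    p_raw=p_raw,
                    p_adj=p_adj,
                    overlap_symbols=frozenset(overlap),
                    significant=p_adj < query.alpha,
                )
            )
    return sorted(results, key=lambda r: (r.p_adj, r.term_id))


@dataclass
class PathwayMap:
    """Seed membership of one pathway plus its shared interactors."""

    term_id: str
    member_seeds_by_class: dict[str, set[str]]
    shared_interactors_in_pathway: set[str]

    def counts(self) -> dict:
        return {
            "term_id": self.term_id,
            "n_rtt_members": len(self.member_seeds_by_class.get("RTT", set())),
            "n_rttl_members": len(self.member_seeds_by_class.get("RTTL", set())),
            "n_shared_interactors": len(self.shared_interactors_in_pathway),
        }


def map_pathway(network: InteractionNetwork, catalog: GeneCatalog, pathway: TermSet) -> PathwayMap:
    """Which seeds belong to the pathway, and which pathway members are also
    common interactors of both seed classes in the network."""
    if not pathway.members:
        raise EnrichmentError(f"pathway {pathway.term_id!r} is empty")
    rtt = catalog.rtt_symbols & pathway.members
    # RTT takes precedence for dual-listed symbols, mirroring node classes
    rttl = (catalog.rttl_symbols - catalog.rtt_symbols) & pathway.members
    shared = common_interactors(network).common & pathway.members
    return PathwayMap(
        term_id=pathway.term_id,
        member_seeds_by_class={"RTT": rtt, "RTTL": rttl},
        shared_interactors_in_pathway=shared,
    )
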