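"""Independent brute-force oracles used to verify the pipeline's numerics.

These deliberately avoid the code paths (and, where feasible, the libraries)
they check: centralities come from the direct combinatorial definitions over
BFS distances and path counts, and hypergeometric tail probabilities from
exact rational enumeration with integer binomial coefficients.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def _bfs(adj, source):
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def brute_betweenness(adj):
    """Raw betweenness by the definition: for every unordered pair (s, t),
    the fraction of shortest s-t paths through v, using the identity that a
    shortest path passes v iff d(s,v) + d(v,t) = d(s,t), with path count
    sigma_s(v) * sigma_t(v)."""
    nodes = list(adj)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs(adj, s)
    bc = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        total = sigma[s][t]
        for v in nodes:
            if v is s or v is t or v == s or v == t:
                continue
            if v in dist[s] and v in dist[t] and dist[s][v] + dist[t][v] == d_st:
                bc[v] += Fraction(sigma[s][v] * sigma[t][v], total)
    return bc


def brute_closeness(adj):
    """Component-scaled closeness straight from BFS distance sums."""
    nodes = list(adj)
    n_total = len(nodes)
    cc = {}
    for v in nodes:
        dist, _ = _bfs(adj, v)
        n_comp = len(dist)
        total = sum(dist.values())
        if total == 0 or n_total < 2:
            cc[v] = Fraction(0)
        else:
            cc[v] = Fraction(n_comp - 1, total) * Fraction(n_comp - 1, n_total - 1)
    return cc


def hyper_pmf(N, K, n, k) -> Fraction:
    if not (max(0, n + K - N) <= k <= min(K, n)):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hyper_upper(N, K, n, k) -> Fraction:
    return sum((hyper_pmf(N, K, n, i) for i in range(k, min(K, n) + 1)), Fraction(0))


def hyper_two_sided(N, K, n, k) -> Fraction:
    """Minimum-likelihood two-sided p by exact rational comparison."""
    p_obs = hyper_pmf(N, K, n, k)
    total = Fraction(0)
    for i in range(max(0, n + K - N), min(K, n) + 1):
        p_i = hyper_pmf(N, K, n, i)
        if p_i <= p_obs:
            total += p_i
    return min(total, Fraction(1))


def adjacency(graph):
    """Plain dict-of-sets adjacency from a networkx graph (nodes with no
    edges included)."""
    adj = {v: set() for v in graph.nodes}
    for a, b in graph.edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj
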