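"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, arbitrary-precision arithmetic) and shares no code with the
package implementation it checks.
"""

from fractions import Fraction
from itertools import combinations, permutations
from math import comb

import networkx as nx
import numpy as np


def rank_products_bruteforce(treated, control, descending=True):
    """Rank products by explicit loops over all treated x control pairs."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    n = t.shape[0]
    ratios = []
    for i in range(t.shape[1]):
        for j in range(c.shape[1]):
            ratios.append(t[:, i] - c[:, j])
    rp = np.ones(n)
    for col in ratios:
        order = -col if descending else col
        # average ranks on ties, by explicit counting
        ranks = np.empty(n)
        for g in range(n):
            less = sum(1 for h in range(n) if order[h] < order[g])
            equal = sum(1 for h in range(n) if order[h] == order[g])
            ranks[g] = less + (equal + 1) / 2.0
        rp *= ranks
    return rp ** (1.0 / len(ratios))


def exhaustive_evalues(rp_observed, n_genes, n_comparisons):
    """Exact E(g) under the independent-uniform-rank null, by enumerating all
    rank-column combinations (feasible only for tiny n_genes/K)."""
    perms = list(permutations(range(1, n_genes + 1)))
    null_rps = []

    def rec(k, acc):
        if k == n_comparisons:
            for g_ranks in zip(*acc):
                prod = 1.0
                for r in g_ranks:
                    prod *= r
                null_rps.append(prod ** (1.0 / n_comparisons))
            return
        for p in perms:
            rec(k + 1, acc + [p])

    rec(0, [])
    null_rps = np.sort(np.array(null_rps))
    n_draws = len(perms) ** n_comparisons
    # tolerance for float representation of equal rank products
    query = np.asarray(rp_observed) * (1 + 1e-9)
    return np.searchsorted(null_rps, query, side="right") / n_draws


def best_connected_query_coverage(graph, query, k):
    """Exhaustive optimum of the K-exception connected subnetwork problem.

    Enumerates every subset of at most k non-query nodes, induces the graph
    on query plus that subset, and takes the best query count over connected
    components.
    """
    query = set(query)
    non_query = sorted(set(graph.nodes) - query)
    best = 0
    for size in range(0, k + 1):
        for extra in combinations(non_query, size):
            sub = graph.subgraph(query | set(extra))
            for comp in nx.connected_components(sub):
                best = max(best, len(comp & query))
    return best


def maximal_cliques_bruteforce(graph, min_size):
    """All maximal cliques >= min_size by subset enumeration (tiny graphs)."""
    nodes = sorted(graph.nodes)
    cliques = []
    for size in range(min_size, len(nodes) + 1):
        for cand in combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in combinations(cand, 2)):
                cliques.append(set(cand))
    maximal = []
    for c in cliques:
        if not any(c < other for other in cliques):
            maximal.append(tuple(sorted(c)))
    return sorted(maximal, key=lambda c: (-len(c), c))


def hypergeom_upper_tail_exact(x, big_n, big_k, n):
    """P(X >= x) by exact summation of point masses with Fractions."""
    total = Fraction(0)
    for i in range(x, min(n, big_k) + 1):
        total += Fraction(comb(big_k, i) * comb(big_n - big_k, n - i),
                          comb(big_n, n))
    return float(total)


def extended_modularity_loops(graph, modules):
    """EQ by plain double loops over module node pairs."""
    nodes = sorted(graph.nodes)
    deg = {v: graph.degree(v) for v in nodes}
    two_m = sum(deg.values())
    o = {}
    for mem in modules.values():
        for v in mem:
            o[v] = o.get(v, 0) + 1
    total = 0.0
    for mem in modules.values():
        for v in mem:
            for w in mem:
                a = 1.0 if graph.has_edge(v, w) else 0.0
                total += (a - deg[v] * deg[w] / two_m) / (o[v] * o[w])
    return total / two_m


def activation_double_loop(z_frame, genes, conditions):
    """Mean Z by an explicit double loop."""
    total, count = 0.0, 0
    for g in genes:
        if g not in z_frame.index:
            continue
        for c in conditions:
            total += float(z_frame.at[g, c])
            count += 1
    return total / count
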