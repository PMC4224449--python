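"""Overlapping module detection by clique agglomeration, module activation,
hypergeometric enrichment and module prioritization.

Module detection follows the maximal-clique agglomeration scheme: initial
communities are the maximal cliques of at least ``min_clique`` nodes (cliques
that are *subordinate* — every member also occurs in a larger retained clique
— are discarded) plus singletons for uncovered nodes.  Communities are merged
pairwise by maximal modularity-style similarity

    S(C1, C2) = (1/2m) * sum_{v in C1, w in C2} [A_vw - k_v k_w / (2m)]

until one community remains, and the dendrogram level maximizing the extended
modularity

    EQ = (1/2m) * sum_modules sum_{v,w in module} (1 / (O_v O_w)) [A_vw - k_v k_w / (2m)]

is returned, where O_v is the number of modules covering node v.  Because
modules may overlap, a node can belong to several modules.

Enrichment of modules against curated node sets is the one-sided upper-tail
hypergeometric test (the enrichment-directional reading of Fisher's exact
test), with Benjamini-Hochberg correction within each collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError
from .coexpress import ActivationResult, activation_score

__all__ = [
    "ModuleSet",
    "maximal_cliques",
    "eagle_modules",
    "module_activation",
    "hypergeom_enrichment",
    "ora_collection",
    "prioritize_modules",
]


@dataclass
class ModuleSet:
    """Possibly-overlapping node modules plus the agglomeration trace."""

    modules: dict                      # module-id -> frozenset of nodes
    eq: float                          # extended modularity of the returned level
    trace: list = field(default_factory=list)   # (level, n_communities, EQ)

    def membership_counts(self) -> dict:
        o: dict = {}
        for nodes in self.modules.values():
            for v in nodes:
                o[v] = o.get(v, 0) + 1
        return o

    def sorted_ids(self) -> list:
        return sorted(self.modules, key=lambda k: (-len(self.modules[k]), k))


def maximal_cliques(graph: nx.Graph, min_size: int = 3) -> list[tuple]:
    """All maximal cliques with at least ``min_size`` nodes, sorted members,
    deterministic order (size descending, then lexicographic)."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)
               if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def _initial_communities(graph: nx.Graph, min_clique: int) -> list[frozenset]:
    cliques = maximal_cliques(graph, min_clique)
    retained: list[frozenset] = []
    covered: set = set()
    for c in cliques:          # size-descending: a clique is subordinate when
        members = set(c)       # all its members are already covered by larger ones
        if members <= covered:
            continue
        retained.append(frozenset(members))
        covered |= members
    for v in sorted(set(graph.nodes) - covered):
        retained.append(frozenset([v]))
    retained.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return retained


def eagle_modules(graph: nx.Graph, min_clique: int = 3) -> ModuleSet:
    """Overlapping modules by agglomerative maximal-clique merging.

    Deterministic: similarity ties break to the lexicographically smallest
    community pair.  Works per connected component implicitly (merging two
    disconnected communities has non-positive similarity, so they merge last).
    """
    if graph.number_of_nodes() == 0:
        raise ComputationError("empty graph")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        # edgeless graph: every node is its own module
        mods = {f"M{i+1}": frozenset([v]) for i, v in enumerate(nodes)}
        return ModuleSet(mods, 0.0, [(0, n, 0.0)])
    b = a - np.outer(k, k) / two_m

    comms = _initial_communities(graph, min_clique)
    x = np.zeros((len(comms), n))
    for ci, c in enumerate(comms):
        for v in c:
            x[ci, idx[v]] = 1.0
    alive = list(range(len(comms)))
    members = {ci: set(c) for ci, c in enumerate(comms)}
    bx = x @ b                       # community x node
    sim = bx @ x.T                   # community x community

    def community_eq(active_ids) -> float:
        o = np.zeros(n)
        for ci in active_ids:
            o += x[ci]
        o[o == 0] = 1.0
        y = x[active_ids] / o[None, :]
        return float(np.einsum("ij,jk,ik->", y, b, y) / two_m)

    trace = []
    best_eq = community_eq(alive)
    best_partition = [frozenset(members[ci]) for ci in alive]
    trace.append((0, len(alive), best_eq))
    level = 0
    while len(alive) > 1:
        # pick the max-similarity pair, deterministic tie-break
        best_pair, best_val = None, None
        for ii, ci in enumerate(alive):
            for cj in alive[ii + 1:]:
                v = sim[ci, cj]
                if best_val is None or v > best_val + 1e-12:
                    best_val, best_pair = v, (ci, cj)
                elif abs(v - best_val) <= 1e-12:
                    cand = tuple(sorted((tuple(sorted(members[ci])),
                                         tuple(sorted(members[cj])))))
                    cur = tuple(sorted((tuple(sorted(members[best_pair[0]])),
                                        tuple(sorted(members[best_pair[1]])))))
                    if cand < cur:
                        best_pair = (ci, cj)
        ci, cj = best_pair
        members[ci] = members[ci] | members[cj]
        x[ci] = np.maximum(x[ci], x[cj])
        alive.remove(cj)
        bx[ci] = x[ci] @ b
        sim[ci, :] = bx[ci] @ x.T
        sim[:, ci] = sim[ci, :]
        level += 1
        eq = community_eq(alive)
        trace.append((level, len(alive), eq))
        if eq > best_eq + 1e-12:
            best_eq = eq
            best_partition = [frozenset(members[c]) for c in alive]

    best_partition.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    mods = {f"M{i+1}": c for i, c in enumerate(best_partition)}
    return ModuleSet(mods, best_eq, trace)


def extended_modularity(graph: nx.Graph, modules: dict) -> float:
    """Independent recomputation of EQ from a module dictionary."""
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    o = np.zeros(len(nodes))
    for mem in modules.values():
        for v in mem:
            o[idx[v]] += 1
    total = 0.0
    for mem in modules.values():
        ids = [idx[v] for v in mem]
        for vi in ids:
            for wi in ids:
                total += (a[vi, wi] - k[vi] * k[wi] / two_m) / (o[vi] * o[wi])
    return total / two_m


def module_activation(modules: ModuleSet, z: pd.DataFrame, conditions,
                      orthologs: pd.DataFrame) -> pd.DataFrame:
    """Activation score per module after back-mapping nodes to expression genes.

    Nodes without an unambiguous back-mapping or without expression rows are
    excluded and counted; a module with no mapped node gets a missing score.
    """
    clean = orthologs[~orthologs["ambiguous"].astype(bool)]
    node2gene = dict(zip(clean["target_id"], clean["source_id"]))
    rows = []
    for mid in modules.sorted_ids():
        nodes = modules.modules[mid]
        genes = sorted({node2gene[v] for v in nodes if v in node2gene})
        try:
            res = activation_score(genes, z, conditions, set_id=mid)
            rows.append((mid, len(nodes), res.score, res.n_genes,
                         len(nodes) - res.n_genes))
        except ComputationError:
            rows.append((mid, len(nodes), np.nan, 0, len(nodes)))
    return pd.DataFrame(rows, columns=["module", "n_nodes", "activation",
                                       "n_expressed", "n_unmapped"]
                        ).set_index("module")


def hypergeom_enrichment(module, reference, background_n: int) -> dict:
    """One-sided upper-tail hypergeometric enrichment P(X >= x).

    Draws n = |module| from a population of ``background_n`` containing
    K = |reference| successes; x = |module & reference|.
    """
    module, reference = set(module), set(reference)
    n, big_k = len(module), len(reference)
    if n > background_n or big_k > background_n:
        raise ComputationError("module or reference larger than the background")
    x = len(module & reference)
    if x > min(n, big_k):
        raise ComputationError("inconsistent overlap count")
    p = float(hypergeom.sf(x - 1, background_n, big_k, n))
    return {"n": n, "x": x, "K": big_k, "N": background_n, "p": min(p, 1.0)}


def ora_collection(genes, collection: dict, background_n: int,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation analysis of one gene set against a GMT collection.

    BH correction is applied across the collection; ``significant`` flags
    bh_fdr < alpha.
    """
    if not collection:
        raise ComputationError("empty gene-set collection")
    rows = []
    for name in sorted(collection):
        members = collection[name]["members"] if isinstance(collection[name], dict) \
            else set(collection[name])
        r = hypergeom_enrichment(genes, members, background_n)
        rows.append((name, r["n"], r["x"], r["K"], r["N"], r["p"]))
    table = pd.DataFrame(rows, columns=["set", "n", "x", "K", "N", "p"]
                         ).set_index("set")
    _, fdr, _, _ = multipletests(table["p"].values, method="fdr_bh")
    table["bh_fdr"] = fdr
    table["significant"] = table["bh_fdr"] < alpha
    return table


def prioritize_modules(activations: pd.DataFrame,
                       enrichments: dict[str, pd.DataFrame],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Rank modules by (number of significantly enriched collections desc,
    activation desc); ties break by module size desc then id.

    ``enrichments`` maps collection name -> per-module enrichment table
    (index module, columns including bh_fdr).
    """
    counts = pd.Series(0, index=activations.index, dtype=int)
    for table in enrichments.values():
        flat = table.reset_index()
        sig = flat.loc[flat["bh_fdr"] < alpha, "module"].unique()
        counts = counts.add(pd.Series(1, index=pd.Index(sig, name="module"))
                            .reindex(activations.index, fill_value=0),
                            fill_value=0)
    out = activations.copy()
    out["n_enriched_collections"] = counts.astype(int)
    out = (out.reset_index()
              .sort_values(by=["n_enriched_collections", "activation",
                               "n_nodes", "module"],
                           ascending=[False, False, False, True],
                           na_position="last")
              .set_index("module"))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def module_collection_enrichment(modules: ModuleSet, collection: dict,
                                 background_n: int) -> pd.DataFrame:
    """Per-module enrichment against every set of one collection, BH within
    the collection (across all module x set tests)."""
    rows = []
    for mid in modules.sorted_ids():
        for name in sorted(collection):
            members = collection[name]["members"] if isinstance(collection[name], dict) \
                else set(collection[name])
            r = hypergeom_enrichment(modules.modules[mid], members, background_n)
            rows.append((mid, name, r["n"], r["x"], r["K"], r["N"], r["p"]))
    table = pd.DataFrame(rows, columns=["module", "set", "n", "x", "K", "N", "p"])
    _, fdr, _, _ = multipletests(table["p"].values, method="fdr_bh")
    table["bh_fdr"] = fdr
    return table
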