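"""Significance, robustness and specificity evaluation of a prioritized module.

Two independent permutation nulls assess whether the prioritized module's
connectivity could arise by chance:

* ``random_module_null`` — draw the same number of nodes uniformly from the
  network and record the largest connected component's node and edge counts;
* ``degree_preserving_null`` — rewire the network by double-edge swaps
  (preserving every node's degree exactly), re-induce the module's node ids
  and record the same statistics.

Empirical p follows the plain counting convention p = #(null >= observed)/reps;
a (count+1)/(reps+1) small-sample correction is available behind a flag.

The robustness harness re-runs the whole discovery pipeline with one quarter
of the samples left out (stratified so every condition keeps treated and
control replicates) and reports the overlap of each fold's top module with the
full-data top module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_score

from .errors import ComputationError

__all__ = [
    "NullDistribution",
    "random_module_null",
    "degree_preserving_null",
    "subsample_stability",
    "condition_specificity",
    "cluster_conditions",
    "timepoint_profile",
    "external_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    statistic: str                 # "lcc_nodes" or "lcc_edges"
    observed: int
    null_values: np.ndarray
    empirical_p: float

    @property
    def reps(self) -> int:
        return len(self.null_values)


def _lcc_stats(graph: nx.Graph, nodes) -> tuple[int, int]:
    sub = graph.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        return 0, 0
    # deterministic choice among equally large components
    comp = max(nx.connected_components(sub),
               key=lambda c: (len(c), tuple(sorted(c))))
    lcc = sub.subgraph(comp)
    return lcc.number_of_nodes(), lcc.number_of_edges()


def _empirical_p(null: np.ndarray, observed: int, corrected: bool) -> float:
    count = int((null >= observed).sum())
    if corrected:
        return (count + 1) / (len(null) + 1)
    return count / len(null)


def random_module_null(network: nx.Graph, module, reps: int = 1000,
                       seed: int = 0, corrected: bool = False
                       ) -> tuple[NullDistribution, NullDistribution]:
    """Uniform node-sampling null for LCC node and edge counts."""
    if reps < 1:
        raise ComputationError("reps must be >= 1")
    module = set(module)
    if len(module) > network.number_of_nodes():
        raise ComputationError("module larger than the network")
    obs_nodes, obs_edges = _lcc_stats(network, module)
    rng = np.random.default_rng(seed)
    all_nodes = sorted(network.nodes)
    nn = np.empty(reps, dtype=int)
    ne = np.empty(reps, dtype=int)
    for r in range(reps):
        sample = rng.choice(len(all_nodes), size=len(module), replace=False)
        nodes = [all_nodes[i] for i in sample]
        nn[r], ne[r] = _lcc_stats(network, nodes)
    return (NullDistribution("lcc_nodes", obs_nodes, nn,
                             _empirical_p(nn, obs_nodes, corrected)),
            NullDistribution("lcc_edges", obs_edges, ne,
                             _empirical_p(ne, obs_edges, corrected)))


def _double_edge_swaps(edges: list, adj: dict, n_attempts: int,
                       rng: np.random.Generator) -> int:
    """In-place double-edge swaps on an edge list + adjacency-set dict.

    Picks two edges (a,b),(c,d) and proposes (a,d),(c,b); rejects swaps that
    would create self-loops or multi-edges.  Returns the accepted count.
    """
    m = len(edges)
    accepted = 0
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        i, j = pairs[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[t]:
            c, d = d, c
        if a == d or c == b:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    return accepted


def degree_preserving_null(network: nx.Graph, module, reps: int = 1000,
                           swaps_per_edge: int = 10, seed: int = 0,
                           corrected: bool = False
                           ) -> tuple[NullDistribution, NullDistribution]:
    """Degree-sequence-preserving rewiring null for LCC node and edge counts.

    A single swap chain is used: a burn-in of ``swaps_per_edge * |E|``
    attempted swaps, then ``|E|`` attempted swaps between successive samples.
    Every sampled graph has exactly the original degree sequence.
    """
    if network.number_of_edges() < 2:
        raise ComputationError("degree-preserving rewiring needs >= 2 edges")
    if reps < 1:
        raise ComputationError("reps must be >= 1")
    module = set(module)
    obs_nodes, obs_edges = _lcc_stats(network, module)
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in network.edges]
    adj = {v: set(network.neighbors(v)) for v in network.nodes}
    m = len(edges)
    burn = _double_edge_swaps(edges, adj, swaps_per_edge * m, rng)
    if burn == 0:
        log.warning("no swap was acceptable (rigid graph); null equals observed graph")
    nn = np.empty(reps, dtype=int)
    ne = np.empty(reps, dtype=int)
    module_list = [v for v in module if v in adj]
    for r in range(reps):
        _double_edge_swaps(edges, adj, m, rng)
        # LCC of the module-induced subgraph in the rewired graph
        g = nx.Graph()
        g.add_nodes_from(module_list)
        mod = set(module_list)
        for v in module_list:
            for w in adj[v]:
                if w in mod:
                    g.add_edge(v, w)
        if g.number_of_nodes() == 0:
            nn[r], ne[r] = 0, 0
        else:
            comp = max(nx.connected_components(g),
                       key=lambda c: (len(c), tuple(sorted(c))))
            sub = g.subgraph(comp)
            nn[r], ne[r] = sub.number_of_nodes(), sub.number_of_edges()
    return (NullDistribution("lcc_nodes", obs_nodes, nn,
                             _empirical_p(nn, obs_nodes, corrected)),
            NullDistribution("lcc_edges", obs_edges, ne,
                             _empirical_p(ne, obs_edges, corrected)))


def assign_folds(samples: pd.DataFrame, n_folds: int, seed: int) -> pd.Series:
    """Stratified fold assignment of samples.

    Within each condition (treated and control separately) replicates are
    dealt to folds round-robin after a seeded shuffle, so leaving out any one
    fold keeps at least one treated and one control replicate per condition
    whenever replicates >= 2.
    """
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=samples.index, dtype=int)
    for (_, _), grp in samples.groupby(["condition_id", "group"], sort=True):
        ids = sorted(grp.index)
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            fold[sid] = i % n_folds
    return fold


def subsample_stability(run_pipeline, intensity: pd.DataFrame,
                        samples: pd.DataFrame, full_top_genes: set,
                        n_folds: int = 4, seed: int = 0) -> dict:
    """Leave-one-fold-out robustness of the top module.

    ``run_pipeline(intensity, samples)`` must re-run the discovery pipeline on
    the reduced tables and return the top module's gene set.  The overlap
    fraction of fold f is |top_f & top_full| / |top_full|.
    """
    if not full_top_genes:
        raise ComputationError("full-data top module is empty")
    folds = assign_folds(samples, n_folds, seed)
    fractions = []
    for f in range(n_folds):
        keep = folds.index[folds != f]
        sub_samples = samples.loc[keep]
        # every condition must keep both of its arms
        before = set(map(tuple, samples[["condition_id", "group"]].values))
        after = set(map(tuple, sub_samples[["condition_id", "group"]].values))
        lost = before - after
        if lost:
            cid, grp = sorted(lost)[0]
            raise ComputationError(
                f"fold {f} removes all {grp} samples of condition {cid!r}")
        sub_int = intensity[keep]
        top = set(run_pipeline(sub_int, sub_samples))
        frac = len(top & full_top_genes) / len(full_top_genes)
        fractions.append(frac)
    return {"fold_overlap": fractions, "mean_overlap": float(np.mean(fractions))}


def condition_specificity(module_genes, z: pd.DataFrame,
                          disease_conditions) -> pd.DataFrame:
    """Per-condition mean Z over the module genes, with ranks.

    Rank 1 is the most activated condition.  The disease flag marks the
    designated conditions.
    """
    genes = [g for g in set(module_genes) if g in z.index]
    if not genes:
        raise ComputationError("no module gene has expression data")
    profile = z.loc[sorted(genes)].mean(axis=0)
    out = pd.DataFrame({"mean_z": profile})
    out["rank"] = out["mean_z"].rank(ascending=False, method="min").astype(int)
    out["disease"] = out.index.isin(set(disease_conditions))
    return out.sort_values("rank")


def cluster_conditions(matrix: pd.DataFrame, max_k: int = 20
                       ) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of condition columns with a silhouette cut.

    Distance is 1 - Pearson r between condition profiles; linkage is average.
    Flat clusters are taken at the k in [2, max_k] maximizing the silhouette
    score.  Returns (linkage matrix, condition -> cluster Series).
    """
    if matrix.shape[1] < 2:
        raise ComputationError("need >= 2 conditions to cluster")
    x = matrix.values.T
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = average(squareform(dist, checks=False))
    best = None
    upper = min(max_k, matrix.shape[1] - 1)
    for k in range(2, upper + 1):
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dist, labels, metric="precomputed")
        if best is None or s > best[0]:
            best = (s, labels)
    if best is None:
        labels = fcluster(link, t=2, criterion="maxclust")
    else:
        labels = best[1]
    return link, pd.Series(labels, index=matrix.columns, name="cluster")


def timepoint_profile(module_genes, matrix: pd.DataFrame, groups: dict,
                      threshold: float = 0.6) -> tuple[pd.DataFrame, pd.Series]:
    """Per-timepoint mean log2 ratio of module genes and activated-gene counts.

    ``groups`` maps condition id -> timepoint label.  A gene counts as
    activated at a timepoint when its mean log2 ratio there is strictly above
    ``threshold`` (0.6 log2 units is roughly a 1.5-fold change).
    """
    unknown = [c for c in groups if c not in matrix.columns]
    if unknown:
        raise ComputationError(f"unknown condition id {unknown[0]!r} in timepoint groups")
    genes = [g for g in sorted(set(module_genes)) if g in matrix.index]
    if not genes:
        raise ComputationError("no module gene has expression data")
    labels = sorted(set(groups.values()), key=lambda v: (isinstance(v, str), v))
    per_gene = {}
    counts = {}
    for lab in labels:
        cols = [c for c, l in groups.items() if l == lab]
        means = matrix.loc[genes, cols].mean(axis=1)
        per_gene[lab] = means
        counts[lab] = int((means > threshold).sum())
    return pd.DataFrame(per_gene), pd.Series(counts, name="activated_genes")


def external_correlation(module_genes, internal: pd.Series,
                         external: pd.Series) -> tuple[float, int]:
    """Pearson correlation of matched internal vs external log2 ratios.

    Matching is over the module genes present in both vectors; fewer than 3
    matches is an error.
    """
    genes = sorted(set(module_genes) & set(internal.index) & set(external.index))
    if len(genes) < 3:
        raise ComputationError(f"only {len(genes)} matched genes; need >= 3")
    r, _ = pearsonr(internal[genes].values.astype(float),
                    external[genes].values.astype(float))
    return float(r), len(genes)
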