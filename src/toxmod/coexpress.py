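"""Co-expression clustering and the activation-score statistic.

Genes are clustered on 1 - Pearson correlation of their log-ratio profiles
across *all* conditions (average linkage) and the dendrogram is cut with a
dynamic tree cut: branches are split recursively while both children can
sustain clusters of at least ``min_size`` genes; genes that end up in
sub-minimum branches are left unassigned (cluster 0).

The activation score links a gene set to a designated condition subset:
log-ratios are standardized per gene across all conditions into Z-scores
(Z_ij = (x_ij - mu_i) / sigma_i), and the activation of a set over the subset
is the plain arithmetic mean of the included Z_ij.  Because each row is
centered, the activation over the complete condition set is identically zero —
a useful hard identity for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .errors import ComputationError
from .diffexpr import DEGSet

__all__ = [
    "ActivationResult",
    "zscore_standardize",
    "coexpression_clusters",
    "activation_score",
    "select_active_clusters",
    "combine_gene_sets",
]

log = logging.getLogger(__name__)


@dataclass
class ActivationResult:
    """Activation of one gene set over a condition subset."""

    set_id: str
    score: float
    n_genes: int          # genes with expression rows (N_c)
    n_conditions: int     # conditions averaged over (N_f)
    n_missing: int        # genes lacking expression data, excluded


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-scores across all conditions (sd with denominator n-1).

    Rows with zero standard deviation are dropped (their count is logged).
    """
    if matrix.shape[1] < 2:
        raise ComputationError("Z-score standardization needs >= 2 conditions")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("zscore_standardize: dropped %d constant rows", dropped)
    m = matrix.loc[keep]
    return m.sub(mu[keep], axis=0).div(sd[keep], axis=0)


def _dynamic_cut(node, heights_median: float, min_size: int, deep_split: bool,
                 out: list) -> None:
    """Recursive branch splitting; appends leaf-index lists of final clusters."""
    if node.is_leaf() or node.get_count() < 2 * min_size:
        out.append(node.pre_order())
        return
    left, right = node.get_left(), node.get_right()
    lc, rc = left.get_count(), right.get_count()
    supported = deep_split or node.dist >= heights_median
    if lc >= min_size and rc >= min_size and supported:
        _dynamic_cut(left, heights_median, min_size, deep_split, out)
        _dynamic_cut(right, heights_median, min_size, deep_split, out)
    elif lc < min_size <= rc:
        out.append(left.pre_order())        # shed the small branch -> unassigned
        _dynamic_cut(right, heights_median, min_size, deep_split, out)
    elif rc < min_size <= lc:
        out.append(right.pre_order())
        _dynamic_cut(left, heights_median, min_size, deep_split, out)
    else:
        out.append(node.pre_order())


def coexpression_clusters(matrix: pd.DataFrame,
                          min_size: int = 16,
                          deep_split: bool = True) -> pd.Series:
    """Hard gene partition from average-linkage clustering + dynamic tree cut.

    Returns a gene -> cluster-id Series; cluster 0 holds unassigned genes
    (members of branches too small to form a cluster).  Deterministic:
    rows are ordered by gene id before the dendrogram is built, so the result
    is invariant to the input row order.

    ``deep_split=False`` additionally requires a branch's merge height to
    reach the median merge height before it is split, yielding fewer, coarser
    clusters.
    """
    if min_size < 2:
        raise ComputationError("min_size must be >= 2")
    matrix = matrix.sort_index()
    genes = matrix.index
    if len(genes) < min_size:
        return pd.Series(0, index=genes, name="cluster")
    x = matrix.values
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ComputationError("constant gene rows cannot be correlated; drop them first")
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = average(squareform(dist, checks=False))
    root = to_tree(z)
    heights_median = float(np.median(z[:, 2]))
    pieces: list[list[int]] = []
    _dynamic_cut(root, heights_median, min_size, deep_split, pieces)

    labels = np.zeros(len(genes), dtype=int)
    # stable cluster numbering: by decreasing size, ties by smallest member id
    sized = sorted((p for p in pieces if len(p) >= min_size),
                   key=lambda p: (-len(p), genes[min(p)]))
    for k, piece in enumerate(sized, start=1):
        labels[piece] = k
    return pd.Series(labels, index=genes, name="cluster")


def activation_score(genes, z: pd.DataFrame, conditions,
                     set_id: str = "set") -> ActivationResult:
    """Mean Z-score of a gene set over a condition subset.

    Genes absent from the Z-score matrix are excluded and counted (mirrors
    back-mapping of network nodes to expression data).
    """
    genes = sorted(set(genes))
    conditions = [c for c in z.columns if c in set(conditions)]
    present = [g for g in genes if g in z.index]
    if not present:
        raise ComputationError(f"no gene of set {set_id!r} has expression data")
    if not conditions:
        raise ComputationError("no valid condition supplied")
    block = z.loc[present, conditions]
    return ActivationResult(set_id, float(block.values.mean()),
                            len(present), len(conditions),
                            len(genes) - len(present))


def select_active_clusters(clusters: pd.Series,
                           z: pd.DataFrame,
                           conditions,
                           cutoff: float = 2.0) -> tuple[set, pd.DataFrame]:
    """Union of genes in clusters with |activation| strictly above ``cutoff``.

    Cluster 0 (unassigned) is never scored or selected.  Returns the gene
    union and the full per-cluster score table.
    """
    if clusters.empty:
        raise ComputationError("empty cluster set")
    rows = []
    selected: set = set()
    for cid in sorted(c for c in clusters.unique() if c != 0):
        members = clusters.index[clusters == cid]
        res = activation_score(members, z, conditions, set_id=str(cid))
        chosen = abs(res.score) > cutoff
        rows.append((cid, res.score, res.n_genes, res.n_conditions,
                     res.n_missing, chosen))
        if chosen:
            selected |= set(members)
    table = pd.DataFrame(rows, columns=["cluster", "activation", "n_genes",
                                        "n_conditions", "n_missing",
                                        "selected"]).set_index("cluster")
    return selected, table


def combine_gene_sets(deg: DEGSet, coexpr_genes: set) -> tuple[set, dict]:
    """Union of DEG (up + down) and activated co-expression genes.

    Returns the union and a size report (|DEG|, |coexpr|, overlap, union).
    """
    deg_genes = set(deg.up) | set(deg.down)
    coexpr_genes = set(coexpr_genes)
    union = deg_genes | coexpr_genes
    report = {
        "n_deg": len(deg_genes),
        "n_coexpr": len(coexpr_genes),
        "n_overlap": len(deg_genes & coexpr_genes),
        "n_union": len(union),
    }
    return union, report
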