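"""Rank-product differential expression with permutation-based FDR.

The two-class (unpaired) rank product: for a condition with T treated and C
control replicates, all K = T*C pairwise log-ratios are formed; per comparison
genes are ranked by fold change (descending for the "up" statistic, ascending
for "down", ties get average ranks) and the rank product of gene g is the
geometric mean of its K ranks.  Small RP = consistently extreme gene.

Significance follows the permutation convention of the rank-only null: null
rank columns are drawn as independent uniform permutations per comparison.
With E(g) the expected number of null rank products at least as extreme as
RP_g and p the position of g in the RP-sorted list, pfp(g) = E(g)/p is the
estimated proportion of false positives (an FDR estimate); a step-up pass
makes pfp monotone non-decreasing along the sorted list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ComputationError

__all__ = ["RankProductResult", "DEGSet", "rank_product_test", "aggregate_deg"]


@dataclass
class RankProductResult:
    """Per-gene rank products and pfp values, one frame per direction."""

    up: pd.DataFrame      # columns: rank_product, pfp
    down: pd.DataFrame
    n_comparisons: int
    n_perm: int

    def significant(self, direction: str, fdr_cutoff: float = 0.05) -> set:
        frame = getattr(self, direction)
        return set(frame.index[frame["pfp"] < fdr_cutoff])


@dataclass
class DEGSet:
    """Aggregated up/down DEG sets with per-condition provenance."""

    up: set
    down: set
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    # provenance columns: gene, direction, conditions (comma-joined), n_conditions


def _rank_products(log_ratios: np.ndarray, descending: bool) -> np.ndarray:
    """Geometric mean of per-comparison ranks (rows = genes)."""
    x = -log_ratios if descending else log_ratios
    ranks = rankdata(x, axis=0)                     # average ranks on ties
    return np.exp(np.mean(np.log(ranks), axis=1))


def _null_rank_products(treated: np.ndarray, control: np.ndarray,
                        n_perm: int, rng: np.random.Generator,
                        method: str) -> dict[str, np.ndarray]:
    """Null rank-product values per direction, ``n_perm * n_genes`` each.

    ``method="permute"`` shuffles gene labels independently within each
    replicate array and recomputes all pairwise ratios — this preserves the
    correlation between comparisons that share replicates, giving a
    calibrated pfp.  ``method="uniform"`` draws independent uniform rank
    columns per comparison (the rank-only null).
    """
    n = treated.shape[0]
    n_comp = treated.shape[1] * control.shape[1]
    null_up = np.empty(n_perm * n)
    null_down = np.empty(n_perm * n)
    for b in range(n_perm):
        if method == "permute":
            t = np.empty_like(treated)
            c = np.empty_like(control)
            for j in range(treated.shape[1]):
                t[:, j] = treated[rng.permutation(n), j]
            for j in range(control.shape[1]):
                c[:, j] = control[rng.permutation(n), j]
            lr = (t[:, :, None] - c[:, None, :]).reshape(n, -1)
            ranks = rankdata(-lr, axis=0)
            null_up[b * n:(b + 1) * n] = np.exp(np.mean(np.log(ranks), axis=1))
            # descending and ascending ranks are complementary
            null_down[b * n:(b + 1) * n] = \
                np.exp(np.mean(np.log(n + 1.0 - ranks), axis=1))
        elif method == "uniform":
            for dest in (null_up, null_down):
                cols = np.argsort(rng.random((n_comp, n)), axis=1) + 1.0
                dest[b * n:(b + 1) * n] = np.exp(np.mean(np.log(cols), axis=0))
        else:
            raise ComputationError(f"unknown null method {method!r}")
    return {"up": null_up, "down": null_down}


def _pfp(rp: np.ndarray, null: np.ndarray, n_perm: int
         ) -> tuple[np.ndarray, np.ndarray]:
    """Permutation (pfp, E) for observed rank products against a null sample.

    E(g) is the expected number of null rank products at or below RP_g per
    permutation; pfp(g) = E(g)/position(g) with a step-up monotonization.
    """
    n_genes = len(rp)
    null = np.sort(null)
    e = np.searchsorted(null, rp, side="right") / n_perm
    order = np.argsort(rp, kind="stable")
    pos = np.empty(n_genes)
    # position p = number of observed RPs <= RP_g (ties share the larger position)
    sorted_rp = rp[order]
    pos[order] = np.searchsorted(sorted_rp, sorted_rp, side="right")
    pfp = e / pos
    # step-up: pfp(g) := min over genes with RP >= RP_g
    sorted_pfp = pfp[order]
    sorted_pfp = np.minimum.accumulate(sorted_pfp[::-1])[::-1]
    out = np.empty(n_genes)
    out[order] = sorted_pfp
    return out, e


def rank_product_test(treated: pd.DataFrame,
                      control: pd.DataFrame,
                      n_perm: int = 100,
                      seed: int = 0,
                      null_method: str = "uniform") -> RankProductResult:
    """Two-class rank product over all treated x control pairings.

    Parameters
    ----------
    treated, control
        genes x replicates log2 intensity tables over the same gene index.
    n_perm
        number of null permutations for the pfp estimate.
    seed
        seed of the permutation generator.
    null_method
        "uniform" (default, the classic rank-product convention) draws
        independent uniform rank columns per comparison; "permute" shuffles
        gene labels within each replicate array and recomputes the pairwise
        ratios, preserving the correlation between comparisons that share
        replicates.  The uniform null is mildly anticonservative for pairwise
        treated x control ratios (they share replicates) but is the
        convention this statistic is known for; the permutation null is
        calibrated and correspondingly less sensitive.
    """
    if n_perm < 1:
        raise ComputationError("n_perm must be >= 1")
    if treated.shape[1] < 1 or control.shape[1] < 1:
        raise ComputationError("need at least one replicate per class")
    if not treated.index.equals(control.index):
        control = control.reindex(treated.index)
        if control.isna().any().any():
            raise ComputationError("treated and control gene universes differ")
    genes = treated.index
    n = len(genes)
    # all pairwise log-ratios, shape genes x (T*C)
    lr = (treated.values[:, :, None] - control.values[:, None, :]).reshape(n, -1)
    k = lr.shape[1]
    rng = np.random.default_rng(seed)

    frames = {}
    nulls = _null_rank_products(treated.values, control.values, n_perm, rng,
                                null_method)
    for direction, descending in (("up", True), ("down", False)):
        rp = _rank_products(lr, descending)
        pfp, e = _pfp(rp, nulls[direction], n_perm)
        frames[direction] = pd.DataFrame(
            {"rank_product": rp, "e_value": e, "pfp": pfp}, index=genes)
    return RankProductResult(frames["up"], frames["down"], k, n_perm)


def aggregate_deg(results: dict[str, RankProductResult],
                  fdr_cutoff: float = 0.05,
                  min_conditions: int = 2) -> DEGSet:
    """Genes significant in at least ``min_conditions`` conditions, per direction.

    ``results`` maps condition id -> RankProductResult.  A gene may appear in
    both lists when it passes in opposite directions in different conditions.
    """
    if min_conditions > len(results):
        raise ComputationError(
            f"min_conditions={min_conditions} exceeds the {len(results)} supplied results")
    hits: dict[str, dict[str, list[str]]] = {"up": {}, "down": {}}
    for cid in sorted(results):
        res = results[cid]
        for direction in ("up", "down"):
            for g in res.significant(direction, fdr_cutoff):
                hits[direction].setdefault(g, []).append(cid)
    rows = []
    sets = {}
    for direction in ("up", "down"):
        passed = {g for g, cids in hits[direction].items()
                  if len(cids) >= min_conditions}
        sets[direction] = passed
        for g in sorted(passed):
            cids = hits[direction][g]
            rows.append((g, direction, ",".join(cids), len(cids)))
    prov = pd.DataFrame(rows, columns=["gene", "direction", "conditions",
                                       "n_conditions"])
    return DEGSet(sets["up"], sets["down"], prov)
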