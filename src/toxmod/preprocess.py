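"""From probe-level intensities to the filtered gene x condition log-ratio matrix.

The pipeline contract starts at a normalized log2 intensity table (array
normalization and outlier-array removal are upstream concerns).  This module
applies non-specific probe filtering, collapses probes to genes, forms the
per-condition log-ratios (mean over treated replicates minus mean over matched
control replicates), selects the disease-condition subset by histopathology
severity, and runs the replicate-clustering QC that excludes conditions whose
treated replicates co-cluster with controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import ComputationError

__all__ = [
    "FilterReport",
    "filter_probes",
    "condition_log_ratios",
    "collapse_probes",
    "collapse_winners",
    "select_disease_conditions",
    "qc_replicate_clustering",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_removed_unannotated: int
    n_removed_low_iqr: int
    n_removed_absent: int
    n_kept: int


def _condition_means(intensity: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per probe per condition (treated and control conditions alike)."""
    cond_of = samples["condition_id"]
    cols = intensity.columns
    groups = cond_of.reindex(cols)
    return intensity.T.groupby(groups).mean().T


def _probe_iqr(intensity: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    means = _condition_means(intensity, samples)
    q75 = means.quantile(0.75, axis=1)
    q25 = means.quantile(0.25, axis=1)
    return q75 - q25


def filter_probes(intensity: pd.DataFrame,
                  presence: pd.DataFrame,
                  samples: pd.DataFrame,
                  annotation: pd.Series,
                  iqr_quantile: float = 0.5,
                  present_frac: float = 0.25) -> tuple[pd.DataFrame, FilterReport]:
    """Non-specific filtering of probes.

    Removes, in order: probes without a gene annotation; probes whose IQR
    across condition-mean intensities falls below the ``iqr_quantile``
    quantile of all probe IQRs; probes "present" (all replicates of a
    condition flagged 1) in fewer than ``present_frac`` of conditions.
    """
    n_input = len(intensity)
    ann = annotation.reindex(intensity.index).fillna("")
    annotated = intensity.index[ann != ""]
    n_unann = n_input - len(annotated)
    kept = intensity.loc[annotated]

    iqr = _probe_iqr(kept, samples)
    thr = iqr.quantile(iqr_quantile)
    pass_iqr = iqr.index[iqr >= thr]
    n_low = len(kept) - len(pass_iqr)
    kept = kept.loc[pass_iqr]

    # a condition counts as "present" when all of its replicates are flagged 1
    pres = presence.reindex(index=kept.index, columns=kept.columns)
    cond_of = samples["condition_id"].reindex(kept.columns)
    cond_present = pres.T.groupby(cond_of).min().T          # probes x conditions
    frac_present = cond_present.mean(axis=1)
    pass_pres = frac_present.index[frac_present >= present_frac]
    n_absent = len(kept) - len(pass_pres)
    kept = kept.loc[pass_pres]

    if kept.empty:
        raise ComputationError("probe filtering removed all probes")
    report = FilterReport(n_input, n_unann, n_low, n_absent, len(kept))
    log.info("filter_probes: %s", report)
    return kept, report


def condition_log_ratios(intensity: pd.DataFrame,
                         samples: pd.DataFrame) -> pd.DataFrame:
    """Log-ratio matrix: one column per treated condition.

    For each treated condition the value is the mean over its treated
    replicates minus the mean over the matched control condition's replicates
    (both already on log2 scale).
    """
    treated = samples[samples["group"] == "treated"]
    means = _condition_means(intensity, samples)
    cols = {}
    for cid, grp in treated.groupby("condition_id", sort=True):
        ctrl = set(grp["control_condition_id"])
        ctrl.discard("")
        if len(ctrl) != 1 or next(iter(ctrl)) not in means.columns:
            raise ComputationError(
                f"condition {cid!r} has no resolvable control condition")
        cols[cid] = means[cid] - means[next(iter(ctrl))]
    if not cols:
        raise ComputationError("no treated conditions found")
    return pd.DataFrame(cols)


def collapse_winners(matrix: pd.DataFrame, probe2gene: pd.Series) -> pd.Series:
    """gene -> winning probe id (highest IQR across columns, ties to the
    lexicographically smallest probe id)."""
    p2g = probe2gene.reindex(matrix.index)
    if p2g.isna().any() or (p2g == "").any():
        raise ComputationError("probe-to-gene mapping does not cover all retained probes")
    q75 = matrix.quantile(0.75, axis=1)
    q25 = matrix.quantile(0.25, axis=1)
    iqr = q75 - q25
    order = pd.DataFrame({"gene": p2g, "iqr": iqr}) \
        .reset_index(names="probe") \
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    winners = order.drop_duplicates("gene", keep="first")
    return pd.Series(winners["probe"].values,
                     index=pd.Index(winners["gene"].values, name="gene_id")
                     ).sort_index()


def collapse_probes(matrix: pd.DataFrame, probe2gene: pd.Series) -> pd.DataFrame:
    """One row per gene: keep the probe with the highest IQR across columns.

    Ties break to the lexicographically smallest probe id.
    """
    winners = collapse_winners(matrix, probe2gene)
    out = matrix.loc[winners.values]
    out.index = winners.index
    return out


def select_disease_conditions(samples: pd.DataFrame,
                              score_threshold: int = 1) -> list[str]:
    """Treated conditions with histopathology severity strictly above threshold."""
    treated = samples[samples["group"] == "treated"]
    scores = treated.groupby("condition_id")["histopath_score"].max()
    sel = sorted(scores.index[scores > score_threshold])
    if not sel:
        log.warning("no condition exceeds histopathology score %d", score_threshold)
    return sel


def qc_replicate_clustering(intensity: pd.DataFrame,
                            samples: pd.DataFrame,
                            candidate_conditions: list[str]) -> pd.DataFrame:
    """Replicate-clustering QC of candidate disease conditions.

    All treated replicates of the candidate conditions and their matched
    control replicates are clustered hierarchically (1 - Pearson r distance,
    average linkage) and the dendrogram is cut into two groups.  A condition
    fails when all of its treated replicates land in the group dominated by
    control samples — the signature of a treatment indistinguishable from its
    controls.
    """
    if len(candidate_conditions) < 2:
        raise ComputationError("replicate-clustering QC needs >= 2 candidate conditions")
    treated = samples[(samples["group"] == "treated")
                      & samples["condition_id"].isin(candidate_conditions)]
    ctrl_ids = set(treated["control_condition_id"]) - {""}
    controls = samples[samples["condition_id"].isin(ctrl_ids)]
    cols = list(treated.index) + list(controls.index)
    if len(cols) < 2:
        raise ComputationError("fewer than 2 samples available for QC clustering")
    sub = intensity[cols]
    corr = np.corrcoef(sub.values.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = average(squareform(dist, checks=False))
    groups = fcluster(z, t=2, criterion="maxclust")
    is_control = np.array([c in set(controls.index) for c in cols])
    # the control-dominated group is the one holding the majority of controls
    g_ctrl = 1 if (groups[is_control] == 1).sum() >= (groups[is_control] == 2).sum() else 2
    rows = []
    for cid in sorted(candidate_conditions):
        own = set(treated.index[treated["condition_id"] == cid])
        idx = [i for i, c in enumerate(cols) if c in own]
        in_ctrl_group = all(groups[i] == g_ctrl for i in idx) if idx else False
        rows.append((cid, not in_ctrl_group))
    return pd.DataFrame(rows, columns=["condition_id", "qc_pass"]).set_index("condition_id")
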