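"""Synthetic DrugMatrix-like study generator with recorded ground truth.

Emulates the input side of a toxicogenomics module-discovery run: a probe-level
log2 intensity table over many chemical-exposure conditions (each condition =
one chemical at one dose and duration, with treated and matched control
replicates), a present/absent flag table, sample metadata with histopathology
severity scores, an undirected protein-interaction network with a planted dense
disease module, curated gene-set collections, and an imperfect ortholog map.

Everything is driven by a single integer seed and fully reproducible.

Signal structure
----------------
* Planted differentially expressed genes receive a mean log2 shift (up or down)
  in the treated replicates of the designated disease conditions only.
* Co-expression blocks share a latent per-condition factor, giving a tunable
  within-block Pearson correlation of the condition-level log-ratios.
* Two of the blocks are "disease blocks": their latent factor has an elevated
  (resp. depressed) mean in disease conditions, so the whole block is
  coherently activated there.  Those genes are therefore differentially
  expressed by construction and are counted in the planted DEG ground truth.
* The planted network module is wired over the ortholog images of a subset of
  the disease-relevant genes, on top of a preferential-attachment background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "StudyTables",
    "NetworkBundle",
    "generate_study",
    "generate_network",
    "recovery_metrics",
]


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study; defaults are the package's reference scale.

    The reference scale (2,000 genes x 100 conditions, 4 disease conditions,
    3 replicates per arm, shift 1.0 log2 units, noise 0.4 log2 units) is a
    down-scaled analogue of a liver toxicogenomics compendium of several
    thousand genes and several hundred exposure conditions.
    """

    n_genes: int = 2000
    n_conditions: int = 100
    n_disease_conditions: int = 4
    replicates_per_condition: int = 3
    n_planted_deg: int = 100
    deg_log2_shift: float = 1.0
    n_coexpr_blocks: int = 8
    block_size: int = 40
    block_correlation: float = 0.7
    noise_sd: float = 0.4
    network_nodes: int = 1500
    network_attach_degree: int = 3
    planted_module_size: int = 60
    planted_module_edge_prob: float = 0.3
    curated_set_sizes: Sequence[int] = (30, 50)
    curated_set_overlap_frac: float = 0.5
    seed: int = 1
    # Shift (log2 units) of the disease blocks' latent factor mean in disease
    # conditions; sized so the planted cluster activation clears |A| > 2.
    disease_block_log2_shift: float = 2.5
    # Condition-level response variability (log2 sd) of the shift-planted DEG
    # genes across all treated conditions: disease genes are broadly
    # chemical-responsive, which is what lets them pass a non-specific
    # variance filter on real compendium data.
    deg_condition_sd: float = 0.3
    # Imperfections exercising the preprocessing filters and mapping loss.
    n_unannotated_probes: int = 20
    n_duplicate_probes: int = 30
    n_absent_genes: int = 50
    ortholog_mapped_frac: float = 0.92
    ortholog_ambiguous_frac: float = 0.04
    # When true, one extra condition is labelled diseased (histopathology 2)
    # but receives no expression shift — the replicate-clustering QC target.
    include_null_disease_condition: bool = False

    def validate(self) -> None:
        c = self
        checks = [
            ("n_genes", c.n_genes >= 1),
            ("n_conditions", c.n_conditions >= 2),
            ("n_disease_conditions",
             0 < c.n_disease_conditions < c.n_conditions),
            ("replicates_per_condition", c.replicates_per_condition >= 1),
            ("n_planted_deg", 0 <= c.n_planted_deg <= c.n_genes),
            ("n_coexpr_blocks", c.n_coexpr_blocks >= 0),
            ("block_size", c.block_size >= 2),
            ("block_correlation", 0.0 < c.block_correlation < 1.0),
            ("noise_sd", c.noise_sd >= 0.0),
            ("network_nodes", c.network_nodes >= 2),
            ("network_attach_degree",
             1 <= c.network_attach_degree < c.network_nodes),
            ("planted_module_size",
             0 <= c.planted_module_size <= c.network_nodes),
            ("planted_module_edge_prob",
             0.0 < c.planted_module_edge_prob <= 1.0),
            ("curated_set_sizes", all(s >= 1 for s in c.curated_set_sizes)),
            ("curated_set_overlap_frac",
             0.0 <= c.curated_set_overlap_frac <= 1.0),
            ("ortholog_mapped_frac", 0.0 <= c.ortholog_mapped_frac <= 1.0),
            ("ortholog_ambiguous_frac",
             0.0 <= c.ortholog_ambiguous_frac <= 1.0 - c.ortholog_mapped_frac),
            ("n_absent_genes", 0 <= c.n_absent_genes < c.n_genes),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(
                    f"invalid configuration field {name!r} (value {getattr(c, name)!r})"
                )
        if c.n_coexpr_blocks * c.block_size > c.n_genes:
            raise ConfigurationError(
                "invalid configuration field 'n_coexpr_blocks': "
                "blocks do not fit into n_genes")


@dataclass
class GroundTruth:
    """Planted signal of one synthetic study.

    ``planted_deg_up``/``planted_deg_down`` hold every gene constructed to be
    differentially expressed in the disease conditions: the explicitly
    shift-planted genes (``shift_deg_up``/``shift_deg_down``) plus the genes
    of the up-/down-activated disease co-expression blocks.
    """

    planted_deg_up: set = field(default_factory=set)
    planted_deg_down: set = field(default_factory=set)
    block_membership: dict = field(default_factory=dict)
    planted_module: set = field(default_factory=set)
    disease_condition_ids: set = field(default_factory=set)
    shift_deg_up: set = field(default_factory=set)
    shift_deg_down: set = field(default_factory=set)
    disease_block_up: int | None = None
    disease_block_down: int | None = None
    null_disease_condition: str | None = None
    planted_module_genes: set = field(default_factory=set)

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, set):
                d[k] = sorted(v)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class StudyTables:
    """Expression side of a synthetic study."""

    intensity: pd.DataFrame        # probes x samples, log2 scale
    presence: pd.DataFrame         # probes x samples, 0/1 present flags
    samples: pd.DataFrame          # one row per sample (ConditionTable)
    probe_annotation: pd.Series    # probe_id -> gene_id ('' = unannotated)
    truth: GroundTruth


@dataclass
class NetworkBundle:
    """Network side of a synthetic study."""

    network: nx.Graph
    gene_sets: dict                # set name -> {"description": str, "members": set}
    orthologs: pd.DataFrame        # columns source_id, target_id, ambiguous
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_study(config: SyntheticConfig) -> StudyTables:
    """Generate intensities, presence flags and sample metadata with ground truth.

    Layout of the gene universe (indices into ``G00000..``):

    * genes ``0 .. n_coexpr_blocks*block_size-1`` form the co-expression
      blocks (block 1 = up-disease block, block 2 = down-disease block when
      at least two blocks are requested);
    * the next ``n_planted_deg`` genes are the explicitly shift-planted DEGs
      (first half up, second half down);
    * ``n_absent_genes`` genes at the top of the range are "absent"
      (presence flags mostly 0) and carry no signal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    genes = _gene_ids(c.n_genes)
    n_block_genes = c.n_coexpr_blocks * c.block_size
    block_membership = {}
    for b in range(c.n_coexpr_blocks):
        for i in range(b * c.block_size, (b + 1) * c.block_size):
            block_membership[genes[i]] = b + 1

    deg_start = n_block_genes
    if deg_start + c.n_planted_deg > c.n_genes:
        raise ConfigurationError(
            "invalid configuration field 'n_planted_deg': "
            "planted DEGs do not fit after the co-expression blocks")
    n_up = c.n_planted_deg // 2
    shift_up = set(genes[deg_start:deg_start + n_up])
    shift_down = set(genes[deg_start + n_up:deg_start + c.n_planted_deg])

    disease_block_up = 1 if c.n_coexpr_blocks >= 1 else None
    disease_block_down = 2 if c.n_coexpr_blocks >= 2 else None
    block_up_genes = {g for g, b in block_membership.items() if b == disease_block_up}
    block_down_genes = {g for g, b in block_membership.items() if b == disease_block_down}

    absent = set(genes[c.n_genes - c.n_absent_genes:]) if c.n_absent_genes else set()

    # --- conditions and samples -------------------------------------------
    n_cond = c.n_conditions
    cond_ids = [f"cond{j:04d}" for j in range(n_cond)]
    disease_ids = set(cond_ids[:c.n_disease_conditions])
    null_cond = None
    if c.include_null_disease_condition:
        null_cond = cond_ids[c.n_disease_conditions]

    chemicals = [f"chem{j // 2:03d}" for j in range(n_cond)]
    doses = rng.choice([10.0, 30.0, 100.0, 300.0], size=n_cond)
    durations = rng.choice([0.25, 1.0, 3.0, 5.0, 7.0], size=n_cond)

    rows = []
    treated_cols: list[str] = []
    control_cols: list[str] = []
    for j, cid in enumerate(cond_ids):
        score = 2 if (cid in disease_ids or cid == null_cond) else int(rng.integers(0, 2))
        ctrl_id = f"ctrl_{cid}"
        for r in range(c.replicates_per_condition):
            sid = f"{cid}_t{r}"
            treated_cols.append(sid)
            rows.append((sid, cid, chemicals[j], doses[j], durations[j],
                         "treated", ctrl_id, score))
        for r in range(c.replicates_per_condition):
            sid = f"{cid}_c{r}"
            control_cols.append(sid)
            rows.append((sid, ctrl_id, chemicals[j], 0.0, durations[j],
                         "control", "", score))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "condition_id", "chemical", "dose",
                       "duration", "group", "control_condition_id",
                       "histopath_score"]).set_index("sample_id")

    # --- expression signal -------------------------------------------------
    reps = c.replicates_per_condition
    base = rng.normal(8.0, 1.5, size=c.n_genes)

    # Latent per-block condition factors.  Loading calibrated so that the
    # condition-level log-ratios (means over `reps` replicates, treated minus
    # control) of two block members correlate at ~ block_correlation.
    var_eps = c.noise_sd ** 2 * 2.0 / reps
    loading = float(np.sqrt(c.block_correlation / (1.0 - c.block_correlation) * var_eps)) \
        if var_eps > 0 else 1.0
    factors = rng.standard_normal((c.n_coexpr_blocks, n_cond))
    disease_mask = np.array([cid in disease_ids for cid in cond_ids])
    if disease_block_up is not None and loading > 0:
        factors[disease_block_up - 1, disease_mask] += c.disease_block_log2_shift / loading
    if disease_block_down is not None and loading > 0:
        factors[disease_block_down - 1, disease_mask] -= c.disease_block_log2_shift / loading

    # Per-gene, per-condition treatment effect (applied to treated replicates).
    effect = np.zeros((c.n_genes, n_cond))
    for gi, g in enumerate(genes):
        b = block_membership.get(g)
        if b is not None:
            effect[gi] += loading * factors[b - 1]
    up_idx = [genes.index(g) for g in sorted(shift_up)]
    down_idx = [genes.index(g) for g in sorted(shift_down)]
    effect[np.ix_(up_idx, disease_mask)] += c.deg_log2_shift
    effect[np.ix_(down_idx, disease_mask)] -= c.deg_log2_shift
    # broad chemical responsiveness of the planted DEG genes
    resp_idx = up_idx + down_idx
    if resp_idx and c.deg_condition_sd > 0:
        effect[resp_idx, :] += rng.normal(0.0, c.deg_condition_sd,
                                          size=(len(resp_idx), n_cond))

    n_samples = 2 * reps * n_cond
    intensity = np.empty((c.n_genes, n_samples))
    col_order = []
    pos = 0
    for j, cid in enumerate(cond_ids):
        t = (base[:, None] + effect[:, [j]]
             + rng.normal(0.0, c.noise_sd, size=(c.n_genes, reps)))
        ctl = base[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_genes, reps))
        intensity[:, pos:pos + reps] = t
        intensity[:, pos + reps:pos + 2 * reps] = ctl
        col_order += [f"{cid}_t{r}" for r in range(reps)]
        col_order += [f"{cid}_c{r}" for r in range(reps)]
        pos += 2 * reps

    # --- probe layer -------------------------------------------------------
    probe_ids = [f"p_{g}" for g in genes]
    annotation = {p: g for p, g in zip(probe_ids, genes)}
    values = [intensity]
    dup_targets = genes[:c.n_duplicate_probes]
    if dup_targets:
        dup_rows = []
        for g in dup_targets:
            gi = genes.index(g)
            # low-variance duplicate: shrunk toward the gene's own mean
            row = intensity[gi].mean() + 0.3 * (intensity[gi] - intensity[gi].mean())
            dup_rows.append(row)
            pid = f"q_{g}"
            probe_ids.append(pid)
            annotation[pid] = g
        values.append(np.vstack(dup_rows))
    if c.n_unannotated_probes:
        un = rng.normal(8.0, 1.5, size=(c.n_unannotated_probes, 1)) \
            + rng.normal(0.0, c.noise_sd + 0.5, size=(c.n_unannotated_probes, n_samples))
        for i in range(c.n_unannotated_probes):
            pid = f"x_{i:04d}"
            probe_ids.append(pid)
            annotation[pid] = ""
        values.append(un)
    full = np.vstack(values)
    intensity_df = pd.DataFrame(full, index=pd.Index(probe_ids, name="probe_id"),
                                columns=col_order)

    # presence flags: Bernoulli(0.9) for expressed genes, Bernoulli(0.1) for
    # the absent subset (and unannotated probes treated as expressed)
    p_present = np.full(len(probe_ids), 0.9)
    for i, pid in enumerate(probe_ids):
        if annotation[pid] in absent:
            p_present[i] = 0.1
    presence = (rng.random((len(probe_ids), n_samples)) < p_present[:, None]).astype(int)
    presence_df = pd.DataFrame(presence, index=intensity_df.index, columns=col_order)

    truth = GroundTruth(
        planted_deg_up=shift_up | block_up_genes,
        planted_deg_down=shift_down | block_down_genes,
        block_membership=block_membership,
        disease_condition_ids=set(disease_ids),
        shift_deg_up=shift_up,
        shift_deg_down=shift_down,
        disease_block_up=disease_block_up,
        disease_block_down=disease_block_down,
        null_disease_condition=null_cond,
    )
    ann = pd.Series(annotation, name="gene_id").reindex(intensity_df.index)
    return StudyTables(intensity_df, presence_df, samples, ann, truth)


def generate_network(config: SyntheticConfig,
                     truth: GroundTruth | None = None) -> NetworkBundle:
    """Generate the interaction network, curated gene sets and ortholog map.

    The background is a Barabási–Albert preferential-attachment graph (heavy
    tailed degrees); the planted module is wired over the ortholog images of
    disease-relevant genes (when a study ``truth`` is supplied) with edge
    probability ``planted_module_edge_prob`` on top of the background.
    """
    config.validate()
    c = config
    if c.planted_module_size > 1:
        max_edges = c.planted_module_size * (c.planted_module_size - 1) / 2
        if c.planted_module_edge_prob * max_edges < c.planted_module_size - 1 and \
           c.planted_module_edge_prob > 1.0:
            raise ConfigurationError("planted_module_edge_prob out of range")
    rng = np.random.default_rng(config.seed + 104729)

    nodes = [f"H{i:05d}" for i in range(c.network_nodes)]
    g = nx.barabasi_albert_graph(c.network_nodes, c.network_attach_degree,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))

    genes = _gene_ids(c.n_genes)
    # The planted module is drawn from the *up-regulated* disease genes when a
    # study truth is available: a disease module is coherently activated, and
    # mixing directions would cancel its activation score.
    if truth is not None:
        module_pool = sorted(truth.planted_deg_up)
        disease_genes = sorted(truth.planted_deg_up | truth.planted_deg_down)
    else:
        module_pool = genes[:c.planted_module_size]
        disease_genes = module_pool
    if len(module_pool) < c.planted_module_size:
        module_pool = sorted(set(module_pool) | set(genes[:c.planted_module_size]))
        disease_genes = sorted(set(disease_genes) | set(module_pool))
    module_genes = sorted(rng.choice(module_pool, size=c.planted_module_size,
                                     replace=False)) if c.planted_module_size else []

    # ortholog map: 1-to-1 for mapped genes; a tail of unmapped / ambiguous
    # genes chosen outside the planted module so recovery stays measurable.
    # When there are more mapped genes than network nodes, the excess maps to
    # off-network target ids (orthologs without interaction coverage).
    module_set = set(module_genes)
    candidates = [x for x in genes if x not in module_set]
    rng.shuffle(candidates)
    n_unmapped = int(round((1.0 - c.ortholog_mapped_frac
                            - c.ortholog_ambiguous_frac) * c.n_genes))
    n_ambig = int(round(c.ortholog_ambiguous_frac * c.n_genes))
    unmapped = set(candidates[:n_unmapped])
    ambiguous = set(candidates[n_unmapped:n_unmapped + n_ambig])
    disease_set = set(disease_genes)
    # in-network targets go to module genes first, then other disease genes,
    # then the shuffled remainder
    mapped_genes = ([x for x in module_genes]
                    + [x for x in sorted(disease_set - module_set)
                       if x not in unmapped]
                    + [x for x in candidates[n_unmapped + n_ambig:]
                       if x not in disease_set]
                    + sorted(ambiguous))
    perm = rng.permutation(c.network_nodes)
    rows = []
    for i, x in enumerate(mapped_genes):
        tgt = nodes[perm[i]] if i < c.network_nodes else f"NX{i:05d}"
        rows.append((x, tgt, x in ambiguous))
        if x in ambiguous:  # second conflicting target
            rows.append((x, nodes[perm[(i + 1) % c.network_nodes]], True))
    orthologs = pd.DataFrame(rows, columns=["source_id", "target_id", "ambiguous"])

    gene2node = {x: t for x, t, amb in rows if not amb}
    module_nodes = sorted(gene2node[x] for x in module_genes)

    # wire the module
    for i in range(len(module_nodes)):
        for j in range(i + 1, len(module_nodes)):
            if rng.random() < c.planted_module_edge_prob:
                g.add_edge(module_nodes[i], module_nodes[j])
    g.remove_edges_from(nx.selfloop_edges(g))

    # curated sets: overlap_frac of each set inside the planted module
    gene_sets = {}
    other_nodes = [n for n in nodes if n not in set(module_nodes)]
    for si, size in enumerate(c.curated_set_sizes):
        n_in = min(int(round(c.curated_set_overlap_frac * size)), len(module_nodes))
        inside = list(rng.choice(module_nodes, size=n_in, replace=False)) if n_in else []
        outside = list(rng.choice(other_nodes, size=size - n_in, replace=False))
        gene_sets[f"curated_set_{si + 1}"] = {
            "description": f"synthetic curated disease set {si + 1}",
            "members": set(inside) | set(outside),
        }

    out_truth = truth if truth is not None else GroundTruth()
    out_truth.planted_module = set(module_nodes)
    out_truth.planted_module_genes = set(module_genes)
    return NetworkBundle(g, gene_sets, orthologs, out_truth)


def recovery_metrics(detected: set, truth: set) -> dict:
    """Precision / recall / Jaccard of a detected set against a planted one.

    Empty-vs-empty returns Jaccard 1 by convention; precision and recall are
    ``None`` (flagged missing) when their denominator is empty.
    """
    detected, truth = set(detected), set(truth)
    inter = len(detected & truth)
    union = len(detected | truth)
    return {
        "precision": inter / len(detected) if detected else None,
        "recall": inter / len(truth) if truth else None,
        "jaccard": inter / union if union else 1.0,
    }
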