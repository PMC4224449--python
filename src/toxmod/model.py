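"""Model/Results facade over the module-discovery pipeline.

``DiseaseModuleModel`` holds the study data (intensities, presence flags,
sample metadata, interaction network, ortholog map, curated gene-set
collections) plus the stage parameters; ``fit()`` runs the full discovery
chain — probe filtering, disease-condition selection with replicate QC,
log-ratio construction, rank-product differential expression with the
at-least-two-conditions aggregation, co-expression clustering with activation
scoring, subnetwork extraction with node exceptions, overlapping module
detection and enrichment-based prioritization — and returns a
``DiseaseModuleResults`` carrying every intermediate product, diagnostics and
a text ``summary()``.  Significance, robustness and specificity analyses hang
off the results object.

Example
-------
>>> from toxmod.synthetic import SyntheticConfig, generate_study, generate_network
>>> from toxmod.model import DiseaseModuleModel
>>> cfg = SyntheticConfig(seed=1)
>>> study = generate_study(cfg)
>>> net = generate_network(cfg, study.truth)
>>> res = DiseaseModuleModel.from_study(study, net).fit(seed=1)
>>> print(res.summary())                               # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import networkx as nx

from . import preprocess, diffexpr, coexpress, netextract, netmodules, evaluation
from .errors import ComputationError

__all__ = ["PipelineParams", "DiseaseModuleModel", "DiseaseModuleResults"]


@dataclass
class PipelineParams:
    """Tunable stage parameters with the pipeline's reference defaults."""

    iqr_quantile: float = 0.5        # quantile of probe IQRs kept as threshold
    present_frac: float = 0.25       # fraction of conditions with all-present calls
    score_threshold: int = 1         # histopathology severity, strict inequality
    run_qc: bool = True              # replicate-clustering QC of disease conditions
    fdr_cutoff: float = 0.05         # pfp cutoff per condition and direction
    min_conditions: int = 2          # DEG must pass in at least this many conditions
    n_perm: int = 100                # rank-product null permutations
    min_cluster_size: int = 16       # dynamic tree cut minimum cluster size
    deep_split: bool = True          # aggressive branch splitting
    activation_cutoff: float = 2.0   # |A| threshold for cluster selection
    k_exceptions: int = 100          # node-exception budget per extraction run
    min_clique: int = 3              # smallest seeding clique for module detection
    alpha: float = 0.05              # BH FDR threshold for enrichment


class DiseaseModuleModel:
    """Discovery model binding study data to the pipeline parameters."""

    def __init__(self, intensity: pd.DataFrame, presence: pd.DataFrame,
                 samples: pd.DataFrame, annotation: pd.Series,
                 network: nx.Graph, orthologs: pd.DataFrame,
                 collections: dict[str, dict] | None = None,
                 params: PipelineParams | None = None):
        self.intensity = intensity
        self.presence = presence
        self.samples = samples
        self.annotation = annotation
        self.network = network
        self.orthologs = orthologs
        self.collections = collections or {}
        self.params = params or PipelineParams()

    @classmethod
    def from_study(cls, study, net, params: PipelineParams | None = None
                   ) -> "DiseaseModuleModel":
        """Build from the synthetic generator's StudyTables / NetworkBundle."""
        return cls(study.intensity, study.presence, study.samples,
                   study.probe_annotation, net.network, net.orthologs,
                   {"curated": net.gene_sets}, params)

    # ------------------------------------------------------------------ fit
    def fit(self, seed: int = 0) -> "DiseaseModuleResults":
        p = self.params

        filtered, filter_report = preprocess.filter_probes(
            self.intensity, self.presence, self.samples, self.annotation,
            iqr_quantile=p.iqr_quantile, present_frac=p.present_frac)

        candidates = preprocess.select_disease_conditions(
            self.samples, score_threshold=p.score_threshold)
        qc_report = None
        disease_conditions = list(candidates)
        if p.run_qc and len(candidates) >= 2:
            qc_report = preprocess.qc_replicate_clustering(
                filtered, self.samples, candidates)
            disease_conditions = sorted(qc_report.index[qc_report["qc_pass"]])
        if not disease_conditions:
            raise ComputationError("no disease condition survives selection and QC")

        probe_log_ratios = preprocess.condition_log_ratios(filtered, self.samples)
        winners = preprocess.collapse_winners(
            probe_log_ratios, self.annotation.reindex(probe_log_ratios.index))
        log_ratios = probe_log_ratios.loc[winners.values]
        log_ratios.index = winners.index

        gene_intensity = filtered.loc[winners.values]
        gene_intensity.index = winners.index

        # rank product per disease condition
        rp_results = {}
        for i, cid in enumerate(disease_conditions):
            t_cols = self.samples.index[
                (self.samples["condition_id"] == cid)
                & (self.samples["group"] == "treated")]
            ctrl_ids = set(self.samples.loc[t_cols, "control_condition_id"]) - {""}
            c_cols = self.samples.index[
                self.samples["condition_id"].isin(ctrl_ids)]
            rp_results[cid] = diffexpr.rank_product_test(
                gene_intensity[t_cols], gene_intensity[c_cols],
                n_perm=p.n_perm, seed=(seed + 9973 * (i + 1)) % (2**31 - 1))
        min_cond = min(p.min_conditions, len(rp_results))
        deg = diffexpr.aggregate_deg(rp_results, fdr_cutoff=p.fdr_cutoff,
                                     min_conditions=min_cond)

        # co-expression branch
        z = coexpress.zscore_standardize(log_ratios)
        clusters = coexpress.coexpression_clusters(
            log_ratios.loc[z.index], min_size=p.min_cluster_size,
            deep_split=p.deep_split)
        coexpr_genes, cluster_scores = coexpress.select_active_clusters(
            clusters, z, disease_conditions, cutoff=p.activation_cutoff)
        combined, combine_report = coexpress.combine_gene_sets(deg, coexpr_genes)

        up_clusters = cluster_scores.index[
            cluster_scores["selected"] & (cluster_scores["activation"] > 0)]
        down_clusters = cluster_scores.index[
            cluster_scores["selected"] & (cluster_scores["activation"] < 0)]
        coexpr_up = {g for g in coexpr_genes if clusters.get(g) in set(up_clusters)}
        coexpr_down = {g for g in coexpr_genes if clusters.get(g) in set(down_clusters)}

        # network branch: four extraction runs, then the union
        gene_lists = {"deg_up": deg.up, "deg_down": deg.down,
                      "coexpr_up": coexpr_up, "coexpr_down": coexpr_down}
        mapping_reports = {}
        subnets = []
        for name in sorted(gene_lists):
            genes = gene_lists[name]
            nodes, report = netextract.map_to_network(
                genes, self.orthologs, self.network)
            mapping_reports[name] = report
            if nodes:
                subnets.append(netextract.extract_subnetwork(
                    self.network, nodes, k_exceptions=p.k_exceptions,
                    seed=seed, label=name))
        if not subnets:
            raise ComputationError("no gene list mapped onto the network")
        union = netextract.union_subnetworks(subnets)
        union_graph = union.graph()

        modules = netmodules.eagle_modules(union_graph, min_clique=p.min_clique)
        activations = netmodules.module_activation(
            modules, z, disease_conditions, self.orthologs)
        background_n = self.network.number_of_nodes()
        enrichments = {
            cname: netmodules.module_collection_enrichment(
                modules, coll, background_n)
            for cname, coll in self.collections.items()}
        ranking = netmodules.prioritize_modules(activations, enrichments,
                                                alpha=p.alpha)

        return DiseaseModuleResults(
            model=self, seed=seed, filter_report=filter_report,
            qc_report=qc_report, disease_conditions=disease_conditions,
            log_ratios=log_ratios, z=z, rank_products=rp_results, deg=deg,
            clusters=clusters, cluster_scores=cluster_scores,
            coexpr_genes=coexpr_genes, combined_genes=combined,
            combine_report=combine_report, mapping_reports=mapping_reports,
            subnetworks=subnets, union_subnetwork=union, modules=modules,
            activations=activations, enrichments=enrichments, ranking=ranking)


@dataclass
class DiseaseModuleResults:
    """Everything a fitted discovery run produced."""

    model: DiseaseModuleModel
    seed: int
    filter_report: object
    qc_report: pd.DataFrame | None
    disease_conditions: list
    log_ratios: pd.DataFrame
    z: pd.DataFrame
    rank_products: dict
    deg: diffexpr.DEGSet
    clusters: pd.Series
    cluster_scores: pd.DataFrame
    coexpr_genes: set
    combined_genes: set
    combine_report: dict
    mapping_reports: dict
    subnetworks: list
    union_subnetwork: netextract.SubNetwork
    modules: netmodules.ModuleSet
    activations: pd.DataFrame
    enrichments: dict
    ranking: pd.DataFrame

    # ----------------------------------------------------------- accessors
    @property
    def top_module_id(self) -> str:
        return self.ranking.index[0]

    @property
    def top_module_nodes(self) -> set:
        return set(self.modules.modules[self.top_module_id])

    def module_genes(self, module_id: str) -> set:
        """Expression gene ids of a module's nodes (unambiguous back-map)."""
        clean = self.model.orthologs[~self.model.orthologs["ambiguous"].astype(bool)]
        node2gene = dict(zip(clean["target_id"], clean["source_id"]))
        return {node2gene[v] for v in self.modules.modules[module_id]
                if v in node2gene}

    # ------------------------------------------------------------ analyses
    def significance(self, reps: int = 1000, seed: int | None = None,
                     swaps_per_edge: int = 10) -> dict:
        """Both permutation nulls for the top module's LCC statistics."""
        seed = self.seed if seed is None else seed
        nodes = self.top_module_nodes
        rn, re_ = evaluation.random_module_null(
            self.model.network, nodes, reps=reps, seed=seed)
        dn, de = evaluation.degree_preserving_null(
            self.model.network, nodes, reps=reps,
            swaps_per_edge=swaps_per_edge, seed=seed + 1)
        return {"random_nodes": rn, "random_edges": re_,
                "rewired_nodes": dn, "rewired_edges": de}

    def stability(self, n_folds: int = 4, seed: int | None = None) -> dict:
        """Leave-one-quarter-out robustness of the top module's node set."""
        seed = self.seed if seed is None else seed
        full_top = self.top_module_nodes

        def rerun(intensity, samples):
            m = DiseaseModuleModel(
                intensity, self.model.presence[intensity.columns], samples,
                self.model.annotation, self.model.network,
                self.model.orthologs, self.model.collections, self.model.params)
            return m.fit(seed=self.seed).top_module_nodes

        return evaluation.subsample_stability(
            rerun, self.model.intensity, self.model.samples, full_top,
            n_folds=n_folds, seed=seed)

    def specificity(self) -> pd.DataFrame:
        """Per-condition mean Z over the top module's genes, ranked."""
        return evaluation.condition_specificity(
            self.module_genes(self.top_module_id), self.z,
            self.disease_conditions)

    def condition_clustering(self, max_k: int = 20):
        """Cluster all conditions on the top module's gene expression."""
        genes = sorted(self.module_genes(self.top_module_id)
                       & set(self.log_ratios.index))
        return evaluation.cluster_conditions(self.log_ratios.loc[genes],
                                             max_k=max_k)

    def timecourse(self, groups: dict, threshold: float = 0.6):
        """Per-timepoint activation profile of the top module's genes."""
        return evaluation.timepoint_profile(
            self.module_genes(self.top_module_id), self.log_ratios, groups,
            threshold=threshold)

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        r = self
        lines = [
            "Disease-module discovery results",
            "=" * 64,
            f"genes after filtering/collapse : {len(r.log_ratios)}",
            f"conditions (log-ratio columns) : {r.log_ratios.shape[1]}",
            f"disease conditions (post QC)   : {len(r.disease_conditions)} "
            f"({', '.join(r.disease_conditions)})",
            f"DEGs up / down                 : {len(r.deg.up)} / {len(r.deg.down)}",
            f"co-expression clusters         : "
            f"{int((r.cluster_scores.index != 0).sum())} "
            f"(activated: {int(r.cluster_scores['selected'].sum())}, "
            f"genes: {len(r.coexpr_genes)})",
            f"combined disease gene set      : {r.combine_report['n_union']} "
            f"(overlap {r.combine_report['n_overlap']})",
            f"union subnetwork               : {len(r.union_subnetwork.nodes)} nodes "
            f"({len(r.union_subnetwork.active)} active, "
            f"{len(r.union_subnetwork.exceptions)} exceptions)",
            f"modules (EQ={r.modules.eq:.4f})        : {len(r.modules.modules)}",
            "",
            "Top modules (rank, id, nodes, activation, enriched collections):",
        ]
        head = r.ranking.head(5)
        for mid, row in head.iterrows():
            act = row["activation"]
            act_s = f"{act:.3f}" if pd.notna(act) else "NA"
            lines.append(f"  {int(row['rank']):>2}  {mid:<6} "
                         f"{int(row['n_nodes']):>4}  {act_s:>7}  "
                         f"{int(row['n_enriched_collections'])}")
        return "\n".join(lines)
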