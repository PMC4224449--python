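# Methods

This note documents the models, statistics and design choices behind
`toxmod`, in the order the pipeline runs them, followed by the synthetic
study design and known limitations.

## Input model and preprocessing

The pipeline's contract starts at a normalized log2 intensity table
(probes × samples) with a matching 0/1 present-call table and per-sample
metadata (condition, chemical, dose in mg/kg, duration in days,
treated/control arm, link to the matched control condition, integer
histopathology severity). Array normalization, CEL-level detection calls and
outlier-array removal are upstream concerns and out of scope.

Probe filtering applies three rules in a fixed order: (1) probes without a
gene annotation are dropped; (2) probes whose inter-quartile range across
*condition means* falls below a quantile of the probe-IQR distribution are
dropped (default quantile 0.5; expressed as a quantile because a fixed
absolute cutoff would not transfer across scales); (3) a probe must be
"present" — all replicates of a condition flagged 1 — in at least 25 % of
conditions. Probe→gene collapse keeps the probe with the highest IQR, ties
broken to the lexicographically smallest probe id, so the collapse is
deterministic.

Log-ratios are per treated condition: mean over treated replicates minus
mean over the matched control condition's replicates, both already on log2
scale. The operation is linear in the intensities, which the tests exploit.

Disease conditions are those with histopathology severity strictly greater
than the threshold (default 1; strict inequality taken literally). The
replicate-clustering QC clusters all candidate treated replicates together
with their control replicates on 1 − Pearson r with average linkage and cuts
the tree into two groups; a condition fails when *all* of its treated
replicates land in the group holding the majority of control samples. The
two-group top-level cut is our choice — the outcome pattern (a treatment
indistinguishable from its controls) defines the rule, not a particular cut
height.

## Rank-product differential expression

For one condition with T treated and C control replicates we form all
K = T·C pairwise log-ratios. Per comparison genes are ranked by fold change
(descending for "up", ascending for "down"; ties get average ranks) and

    RP_g = (∏_k r_g,k)^(1/K).

Significance: with E(g) the expected number of null rank products per
permutation at or below RP_g and p(g) the position of g in the RP-sorted
list, pfp(g) = E(g)/p(g), made monotone non-decreasing along the sorted list
by a step-up pass. Two null samplers are provided:

* `uniform` (default): independent uniform rank columns per comparison —
  the classic rank-only null of this statistic. Because the K pairwise
  comparisons share replicates, their observed ranks are positively
  correlated and this null is mildly anticonservative for the pairwise
  design: under pure noise a few percent of genes per condition reach
  pfp < 0.05, which the ≥ 2-of-N aggregation rule then compounds down to
  the low-percent range genome-wide.
* `permute`: gene labels are shuffled independently within each replicate
  array and the full pairwise-ratio ranking is recomputed. This preserves
  the inter-comparison correlation and is well calibrated (pure-noise DEG
  rate ≈ 0), at the cost of sensitivity: moderate shifts that sit at the
  edge of the genome-wide noise tail are no longer called.

The default follows the field convention for this statistic; the calibrated
alternative is one keyword away. `n_perm` defaults to 100.

A gene enters the disease DEG set per direction when pfp < 0.05 (default) in
at least 2 conditions; provenance (which conditions) is recorded, and a gene
may appear in both directions if it passes up in some conditions and down in
others.

## Co-expression branch

Z-scores standardize each gene's log-ratios across *all* conditions
(denominator n−1; zero-variance rows are dropped with a logged count). Genes
are clustered on 1 − Pearson r across all conditions, average linkage. The
dynamic tree cut walks the dendrogram from the root and splits a branch
whenever both children could hold a cluster of at least `min_size` genes
(default 16); with `deep_split=False` a branch must additionally reach the
median merge height before splitting, yielding coarser clusters. Branches
too small to stand alone are shed to the unassigned pool (cluster 0). Rows
are ordered by gene id before linkage, making the partition invariant to
input row order.

The activation of a gene set over a condition subset is the arithmetic mean
of the included Z_ij (genes missing from the expression matrix are excluded
and counted — the same rule serves network modules after back-mapping).
Because every row is centered, activation over the complete condition set is
identically zero; this identity is asserted in the tests. Clusters with
|A| > 2 (strict) are selected; their genes are unioned with the DEG set to
form the disease-relevant gene set.

## Network branch

Gene ids are translated to network nodes through the unambiguous entries of
an ortholog table; ambiguous and unmapped genes and genes mapping outside
the network are counted in a report.

Subnetwork extraction solves: find a connected induced subgraph maximizing
the number of query nodes subject to at most K non-query nodes (default
K = 100 per run). The solver is a deterministic greedy — connected
components of the query-induced subgraph are joined largest-first through
minimum-exception-cost paths (Dijkstra on a directed view where entering a
non-query node costs 1), then a local pass adds non-query nodes adjacent to
at least two active nodes while budget remains and prunes exception nodes
whose removal keeps the subgraph connected. The greedy restarts from up to
five seed components (all of them on small instances) and keeps the best
solution by (active count, fewer exceptions, lexicographic node set). On
random 12-node instances it matches an exhaustive-search optimum in ≥ 95 %
of cases and never exceeds it; connectivity and the budget are asserted on
every call. Ant-colony or annealing search could improve large sparse
instances but would cost determinism. The pipeline runs the extractor once
per gene list (up/down × DEG/co-expressed; budget per run) and unions the
four subnetworks, labeling a node active if it was active in any input.

Overlapping modules come from maximal-clique agglomeration: initial
communities are the maximal cliques of ≥ 3 nodes (Bron–Kerbosch with
pivoting), discarding *subordinate* cliques — processed in decreasing size,
a clique is dropped when all its members are already covered by retained
cliques — plus singletons for uncovered nodes. Communities merge pairwise by
maximal similarity S(C1,C2) = (1/2m) Σ_{v∈C1,w∈C2} [A_vw − k_v k_w/(2m)]
(ties to the lexicographically smallest pair) until one remains; the
returned level maximizes the extended modularity

    EQ = (1/2m) Σ_modules Σ_{v,w∈module} (A_vw − k_v k_w/(2m)) / (O_v O_w),

where O_v counts the modules covering v. EQ is recomputed incrementally
(only communities touching the merged pair's shared nodes change) and the
reported value matches an independent double-loop recomputation to 1e−10 in
the tests.

Enrichment of a module against a curated node set is the one-sided
upper-tail hypergeometric probability P(X ≥ x) with draws n = |module|,
successes K = |reference|, population N = the full network node count
(14,230 in the published analysis; configurable, since a different
background is defensible). Benjamini–Hochberg runs within each collection.
One-sidedness reproduces the published enrichment table at printed
precision for the six rows with unambiguous counts; a two-sided variant of
the underlying test is available through scipy directly. Modules are ranked
by (number of collections with a significant set, activation score) both
descending, ties by module size then id.

## Evaluation statistics

* **Uniform node-sampling null**: draw |module| nodes uniformly without
  replacement, record the largest connected component's node and edge
  counts; empirical p = #(null ≥ observed)/reps (a (count+1)/(reps+1)
  correction is available behind `corrected=True`).
* **Degree-preserving null**: double-edge swaps rejecting self-loops and
  multi-edges, so every node's degree — not merely the average — is
  preserved. One chain is used: a burn-in of `swaps_per_edge × |E|`
  attempted swaps (default 10×), then |E| attempted swaps between samples;
  re-starting the burn-in per sample would be statistically equivalent and
  ~10× slower. The module's node ids are re-induced in the rewired graph.
* **Stability**: samples are dealt to folds round-robin within each
  (condition, arm) stratum after a seeded shuffle, so every condition keeps
  both arms; the pipeline is refit without each fold and the overlap
  fraction |top_fold ∩ top_full| / |top_full| reported per fold. Overlap is
  measured on module node sets.
* **Specificity**: per-condition mean Z over the top module's genes, with
  ranks (rank 1 = most activated).
* **Condition clustering**: conditions clustered on the module genes'
  log-ratios (1 − Pearson r, average linkage); the flat cut maximizes the
  silhouette over k ∈ [2, 20] — the cut criterion is our choice, made
  explicit because no standard exists.
* **Time-course profile**: per-timepoint mean log2 ratio per gene; a gene
  counts as activated above 0.6 log2 units (~1.5-fold), strict inequality.
* **External validation**: Pearson r between matched per-gene log-ratio
  vectors (≥ 3 matched genes required), with the match count reported.

## Synthetic study design

The generator emulates a DrugMatrix-like compendium at a reference scale of
2,000 genes × 100 conditions (4 disease conditions), 3 replicates per arm,
chosen to exercise every pipeline stage in seconds while keeping the
planted-signal geometry (signal-to-noise per stage) comparable to the
full-scale data the design mimics (thousands of genes, hundreds of
conditions). Key elements, all seeded:

* Replicate intensities are `base_g + effect_gj + N(0, noise_sd)` with
  noise_sd = 0.4 log2 units.
* 100 planted DEGs receive a ±1.0 log2 shift in the treated replicates of
  disease conditions only, plus a condition-level response term
  `N(0, 0.3)` across all treated conditions — disease genes are broadly
  chemical-responsive, which is what lets them pass a non-specific variance
  filter, exactly as in real compendium data.
* Eight 40-gene co-expression blocks share per-block latent condition
  factors with loadings calibrated so condition-level log-ratios correlate
  at `block_correlation` (default 0.7) after replicate averaging. Two blocks
  are disease blocks: their factor mean is shifted by ±2.5 log2 units in
  disease conditions, sized from the Z-score arithmetic so the block's
  activation lands near 3, clear of the |A| > 2 selection cutoff. Disease
  block genes are genuinely differentially expressed by construction and are
  counted in the planted DEG ground truth.
* The network is Barabási–Albert (1,500 nodes, attachment 3; heavy-tailed
  degrees) with a 60-node module wired at edge probability 0.3 over the
  ortholog images of up-regulated disease genes — a disease module is
  coherently activated; mixing directions would cancel its activation.
* The ortholog map is 1-to-1 for 92 % of genes, with ~4 % ambiguous
  (two conflicting targets, flagged) and ~4 % unmapped, placed outside the
  planted module so module-recovery ground truth stays exact; genes beyond
  the network size map to off-network identifiers.
* Presence flags are Bernoulli(0.9), except a designated "absent" gene
  subset at Bernoulli(0.1); a handful of unannotated and duplicate probes
  exercise the annotation filter and the collapse rule.
* Optionally one extra condition is labelled diseased but carries no
  expression shift — the target of the replicate-clustering QC.

What the generator does **not** emulate: batch effects, array outliers,
probe-level artifacts, dose–response kinetics, correlated noise between
conditions of the same chemical, and biological pathway structure beyond
the planted blocks/module. Passing the planted-truth tests therefore shows
the pipeline recovers the signal class it was designed for under idealized
noise; it does not certify performance on real arrays.

## Numerical choices and degenerate inputs

Distances 1 − r are clipped to [0, 2] before linkage; Z-scores use ddof 1;
rank ties get average ranks; the step-up pass makes pfp monotone; sets and
dendrogram tie-breaks are resolved lexicographically so every stage is
byte-reproducible across processes (no dependence on hash randomization).
Degenerate inputs have defined behavior: constant expression rows are
dropped before clustering; constant rank-product columns yield all-average
ranks; an empty filter result, a missing control condition, an empty module
back-map and sub-minimum clustering inputs raise typed errors; empty
disease-condition selection warns rather than fails.

## Limitations

* The rank-product default null is the field's convention and knowingly
  anticonservative for pairwise treated×control designs (see above).
* The subnetwork heuristic is exact only empirically, on small instances.
* Module detection cost grows with the number of maximal cliques; very
  dense subnetworks (hundreds of nodes with thousands of cliques) will be
  slow.
* Enrichment treats gene sets as flat lists; no ontology structure.
* The stability harness assumes at least 2 replicates per arm so every
  condition survives every fold.
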