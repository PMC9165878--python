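# Methods

This note documents the models, parameter choices and numerical
conventions behind `graftsc`, and what its synthetic-data tests do and do
not establish about real data.

## Sex-based origin inference

In a sex-mismatched transplant every cell's origin is encoded in two
binary transcriptional signals: *XIST* detection (female) and detection
of any of *RPS4Y1*, *EIF1AY*, *DDX3Y* (male). Detection means UMI
count > 0; magnitudes are not used, because droplet dropout makes
presence/absence far more robust than level comparisons for genes of this
abundance. *RPS4Y* is accepted as an alias of *RPS4Y1*.

Calls are made at the (cluster × sample) group level and broadcast to
member cells. For a group with male/female detection fractions fM and fF
(defaults: `tau_detect` = 0.05, `margin` = 2.0, `min_cells` = 10):

- **M** if fM ≥ tau and fM ≥ margin · fF;
- **F** if fF ≥ tau, fF ≥ margin · fM and fM < tau;
- **ambiguous** otherwise. Groups below `min_cells` are called but
  flagged low-confidence.

The asymmetry is deliberate: Y-gene expression is definitive evidence of
male cells, while *absence* of XIST is uninformative — female
proximal-tubule cells can be transcriptionally silent for XIST. For the
same reason, an ambiguous group whose cell type is parenchymal falls back
to donor origin with an explicit "sex-uninformative, parenchymal prior"
flag; immune or stromal groups are never resolved by prior. Same-sex
donor/recipient pairs yield `unassignable` for every group, regardless of
expression — a hard invariant.

The thresholds are calibration choices validated by simulation (group
calls are exact on homogeneous groups of ≥ 20 cells down to a per-gene
detection probability of 0.5), not published constants. A per-cell mode
(sex from each cell's own detections) exists for resolving origin
mixtures *within* a group, such as a fibroblast pool that is partly
recipient-derived; it is noisier per cell — dropout sends a fraction
1 − p of female cells to `ambiguous` — so mixture fractions estimated
from assigned cells are mildly biased toward the male class (e.g. a true
0.6 recipient-female fraction reads ≈ 0.575 at p = 0.9). This bias is
inherent to presence/absence calling and is left uncorrected; the
composition table reports ambiguous counts so users can see the
denominator.

## QC conventions

All retention bounds follow the protocol wording literally, with strict
inequalities by default and an inclusive convention switchable via
`QCThresholds(strict=False)`:

| rule | default | boundary behavior |
|---|---|---|
| gene detected in > `min_cells_per_gene` cells | 3 | exactly 3 → removed |
| `min` < genes/cell < `max` | 200, 5000 | exactly 200 or 5000 → removed |
| mito fraction > `max_mito_fraction` removed | 0.25 | exactly 0.25 → retained |

"Expressed" always means UMI count > 0. The blacklist removes RPS*/RPL*
prefixes, *MALAT1*, and small-RNA symbol classes (MIR*, SNORD*, SNORA*,
SNORB*, SCARNA*) — symbol-prefix matching is used because no annotation
source is mandated. MT- genes are dropped only in round 2, after cells
above the mitochondrial bound have been removed in round 1. Note that the
RPS prefix would also catch *RPS4Y1*; origin assignment therefore reads
the sex panel from the unfiltered count matrix, never the blacklisted
clustering matrix.

The doublet screen flags a cell when at least two disjoint lineage panels
each exceed mean log-normalized expression `tau` = 1.0 (chosen by
simulation to hold the false-flag rate under 5% at the simulated library
depths; exposed in config). In the pipeline this runs as an iterative
loop — flag, drop, re-screen — up to 3 iterations or until no flags. The
signature is blind to within-lineage doublets (e.g. two immune cell
types); the tests therefore score sensitivity on cross-lineage doublets
and specificity on all singlets.

## Clustering stack

- Log-normalization: x = ln(1 + c / total · 10,000) per cell; zeros map
  to zeros; all-zero cells are an error (filter first).
- Variable genes: per-gene raw-count variance standardized against a
  lowess fit of log10 variance on log10 mean (frac = 0.3); standardized
  values clipped at √N before taking the final variance; top ~2000 kept.
- Scaling: gene-wise z-score clipped at +10; PCA (exact SVD) on 10
  components, each component's sign fixed by forcing its
  largest-magnitude loading positive, which makes embeddings byte-stable.
- Graph: k = 20 nearest neighbors (self included), shared-neighbor
  counts converted to Jaccard weights s/(2k − s), pruned below 1/15;
  Leiden optimization of the RB-configuration objective at resolution
  0.5 with a fixed seed. Cluster ids are relabeled by decreasing size.
- Markers: one-vs-rest Wilcoxon rank-sum. Genes are prefiltered to
  detection fraction ≥ 0.25 on at least one side and |lnFC| ≥ 0.25,
  where lnFC = ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)). The
  p-value uses the exact null distribution for small tie-free samples
  and the tie-corrected normal approximation otherwise; BH adjustment is
  applied within each cluster's tested family. Clusters of < 3 cells are
  skipped.
- Annotation: a cluster's score for a cell type is the mean over the
  type's panel genes of mean normalized expression in the cluster; label
  = argmax, ties broken by panel detection fraction then lexicographic
  order, with the tie recorded.

k, the clip constants, the prune threshold and the community-detection
variant are field conventions, not published values, and are exposed in
`ClusterParams`. One property of this stack worth knowing: modularity
clustering of *low-dimensional* geometric point clouds fragments large
uniform blobs (the split partition can have genuinely higher modularity
than the truth partition). On the ~10-dimensional PCA embeddings the
pipeline actually clusters, well-separated blobs are recovered exactly;
the tests assert separability in that regime.

## Pseudobulk and the n-of-1 differential filter

"Average expression" is read as the mean over the group's cells of
per-cell library-size-normalized counts, rescaled so each (cell type,
sample) gene vector sums to exactly 10,000 — the only reading under which
the result is a composition on the stated scale. It is invariant to
global rescaling of raw counts. Profiles are computed from the round-2
(blacklisted) matrix, following pipeline order.

With a single sample per condition, replicated differential-expression
models (DESeq2/edgeR-style) are inapplicable. The filter used instead:
a gene is reported when max TPM > 2 (strict) across samples *and*
max/second ≥ 2 (ratio semantics — the worked fold numbers are only
consistent with a ratio, not an absolute difference of 2). A second-place
value of exactly 0 gives ratio +∞ and passes, provided the floor is met.
Ties for the maximum are broken by column order and flagged. The pass set
is monotone: raising either threshold never adds genes.

Matrisome scoring subsets profiles to a category (collagens,
proteoglycans, secreted factors; editable two-column TSV) and reports
log2(TPM+1) for the top genes ranked by cross-group maximum. The shipped
catalog is a small representative seed, not a vendored copy of any
published matrisome list.

## Immunoglobulin profiling

Isotype calls sum normalized expression within heavy classes
(IGHG1–4 → IGHG; IGHA1–2 → IGHA; IGHM; IGHD; IGHE) and light classes
(IGKC → IGK; IGLC* → IGL; IGLL5) and take the per-chain argmax; ties
break by the fixed class order (IGHG, IGHA, IGHM, IGHD, IGHE / IGK, IGL,
IGLL5) and are flagged. Calls are scale-invariant per cell; all-zero
cells get missing calls. Cell clustering restricts to the top 10 IG genes
by mean expression (mean, not total — the selection statistic is a
choice) and agglomerates with Euclidean distance and complete linkage,
the defaults of the R stack this analysis is usually run in. A
diagnostic IG-to-housekeeping expression ratio is reported per cell but
never enforced.

## The synthetic-data generator

Counts are negative binomial with per-gene means drawn log-uniformly from
`nb_mean_range` = (0.2, 3.0) and shared dispersion 0.5
(var = μ + 0.5 μ²) — the standard overdispersed count model for droplet
UMI data. With the default 600-gene background this puts per-cell
detection near 50% of genes, the right order for droplet libraries
restricted to a small panel. Structure is layered on top:

- **Cell types.** Each type owns a marker panel (real kidney symbols for
  known types — e.g. *MIOX*/*ANPEP*/*SLC13A1* for proximal tubule, *DCN*
  for fibroblasts; synthetic symbols otherwise). Marker genes sit at a
  low off-type baseline (mean 0.05) and are multiplied by
  `marker_boost` = 50 in their own type. The boost is high because each
  type gets only ~5 marker genes to carry the separation that dozens of
  markers provide in real data.
- **Sex signal.** Per cell and per sex-panel gene, detection is Bernoulli
  with `sex_detect_prob` (default 0.8); detected counts are 1 +
  Poisson(1) — magnitude is irrelevant to the detection-based classifier.
  Female cells of `xist_silent_types` get XIST = 0. No cell ever carries
  both signals.
- **Origin mixtures.** `recipient_fraction_per_type` is realized as an
  exact rounded count, so recovery tests measure classifier error, not
  binomial noise in the truth itself.
- **Doublets.** round(rate · n) doublets each replace two same-sample,
  same-sex (preserving sex exclusivity), different-type singlets with
  their element-wise sum (no depth downsampling); emitted columns =
  n − n_doublets, appended after the surviving singlets.
- **Mitochondrial content.** 13 MT- genes; each cell's MT counts are
  rescaled to hit a target fraction — baseline U(0.01, 0.15), outliers
  U(0.30, 0.90) — to within integer rounding; realized fractions are
  recorded in the truth table.

What the generator does **not** model: batch effects, ambient RNA,
library-size gradients between types, doublet depth scaling, correlated
gene programs beyond the marker blocks, and any read-level process.
Passing tests therefore demonstrate the pipeline's logic and its
statistical behavior under the stated noise model, not robustness to
every artifact of real tissue data.

## Problem sizes and determinism

Tests and the acceptance script run on purpose-built small problems: the
QC arithmetic fixture uses 9762 cells × ~620 genes (the one printed-total
construction), recovery suites use a few hundred to a few thousand cells
over 20 seeds, and oracle comparisons use exhaustive enumeration
(rank-sum at group sizes 4 and 5), brute-force sorting (max-gap filter,
500 genes × 3 samples × 50 tables) and O(n³) agglomeration (≤ 10 cells).
Every stochastic component takes an explicit seed; a fixed configuration
reproduces byte-identical matrices, truth tables, embeddings and cluster
assignments.
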