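# Methods

This note documents the models, parameter choices and numerical decisions
behind cellfuse, and what the synthetic-data experiments do and do not
establish about real data.

## Synthetic multimodal data

The generator draws a latent atlas of K cell types arranged in a two-level
hierarchy (subclass → type). Each gene carries a baseline log-expression
b_g ~ N(0, 1.5²); the wide spread matters because highly-variable-gene
selection discards the top-expression bin, and in real transcriptomes that
bin is occupied by constitutively high genes rather than markers. Each
subclass receives a block of shared marker genes and each type a disjoint
block of its own markers (20 each by default), elevated by `effect_size`
(default 2 natural-log units ≈ 7.4-fold) over baseline, so sibling types
differ on exactly their type-marker blocks. Chromosome labels are assigned
round-robin so any chromosome split leaves markers on both sides — a
requirement of the feature-split cross-validation. Type proportions are
uniform.

Per-modality observation models (defaults chosen once to mirror the
platforms the pipeline targets):

* **RNA** (`rna_cell`/`rna_nucleus`): per-cell depth ~ Gamma(10, depth/10)
  around 5,000 total counts; counts are negative binomial
  (gamma–Poisson) with mean proportional to softmax(coupling × program) ×
  depth and dispersion θ = 10. Nuclear datasets multiply means by a
  per-gene nuclear-retention factor (~1% of genes at 5×), emulating
  nucleus-enriched transcripts.
* **Methylation** (`mc`): gene-body coverage ~ Poisson(cell depth ×
  per-gene factor), cell depth around 100 cytosines/gene (Gamma, CV 0.2)
  and a per-gene Gamma(10, 0.1) factor. The mCH fraction is
  `global_mCH × base_g × exp(−s·z)` clipped to [0.001, 0.999], where z is
  the program z-scored per gene across types, s = |coupling| (default 1.2,
  i.e. ≈16-fold depletion in the expressing type — the repressive coupling
  the integration relies on), and base_g ~ lognormal(0, 0.5) spreads
  baseline gene-body methylation over roughly an order of magnitude, as in
  real neurons. Calls are beta-binomial with concentration 300 (mild
  extra-binomial noise). Per-cell global mCH/mCG/mCCC rates are drawn from
  beta distributions centred at 0.04 / 0.78 / 0.005.
* **ATAC** (`atac`): negative-binomial gene-body counts (dispersion 2) with
  mean proportional to exp(coupling × z) × depth at ~3,000 fragments per
  cell, matching the few-thousand unique fragments per cell typical of
  single-nucleus ATAC.

Note the `dispersion` field is the NB size parameter for count modalities
but the beta-binomial concentration for methylation.

**What the generator does not emulate:** batch effects within a modality,
doublets, ambient contamination, read-level structure (peaks, DMRs),
cell-cycle or continuous trajectories, and non-uniform type abundances by
default. Passing tests therefore demonstrate correctness of the machinery
and recoverability under clean, well-separated conditions — not robustness
to every artefact of real experiments.

`simulate_duplication` draws S fragments uniformly with replacement from F
distinct fragments; its expectation F[1 − (1 − 1/F)^S] is the model the
library-size estimator inverts (Brent's method on a bracketing interval,
relative tolerance 1e-12; S reads with no duplicates return +inf).

## Normalization and feature selection

CPM/TPM/RPM follow the platform: droplet RNA → log10(CPM+1), full-length
RNA → log10(TPM+1), ATAC → log10(RPM+1) (both length-normalized);
methylation → per-gene mCH fraction divided by the cell's global mCH, with
zero-coverage entries treated as missing (NaN), never zero. Cells with zero
totals are excluded and reported.

HVG selection (count branch) removes genes detected in fewer than 1% of
cells, bins the rest into 10 equal-count bins by mean linear expression,
drops the highest-expression bin entirely, and keeps the top 30% by
dispersion (variance/mean of the normalized values) per remaining bin. The
methylation branch keeps genes with >20× coverage in >95% of cells, bins by
mean normalized mCH and keeps the top 30% by variance in **every** bin (the
top-bin exclusion applies only to the count branch). Binning is by
quantiles (equal-count) rather than equal width — quantile bins keep the
per-bin quota stable; quotas are floor(0.3·n), at least 1. Ties in the
dispersion ranking break lexicographically by gene id, making selection
invariant to cell and gene order.

Beta-binomial posterior methylation rates fit a per-cell beta prior by
method of moments on that cell's raw per-feature fractions; the posterior
mean is (mc + α)/(cov + α + β). Cells with degenerate fraction variance
fall back to a uniform prior scaled by `prior_strength`. The exact prior
procedure is a design point: method of moments is simple, stable and keeps
the posterior strictly between the raw fraction and the prior mean.

Browser-style [0, 1] scaling maps signals linearly between the 2nd and 98th
percentiles (clip outside); methylation maps between the 2nd and 50th
percentiles and is flipped (1 − x) so high values mean low methylation.
The two percentile conventions are recorded per modality; degenerate
(constant) inputs return zeros with a flag.

## Integration

Within-modality smoothing builds a kNN graph (k = 30, Euclidean, top-50 PC
space), applies an adaptive Gaussian kernel with bandwidth equal to the
distance to the 5th neighbour (ka = 5; one standard reading of the
adaptive-kernel family), row-normalizes to a Markov matrix M, and outputs
(1 − p)X + pM X with p = 0.7 (RNA), 0.9 (mC), 0.1 (ATAC). For subsets
smaller than k + 1 cells, k shrinks to n − 1.

Restricted k-partner imputation assigns each query cell k = 20 reference
partners by ascending distance under a global greedy sweep, with each
reference cell capped at z·⌈k·n_query/n_reference⌉ uses (z = 3); the cap
prevents hub cells from absorbing all matches. Distance is 1 − ρ_Spearman
over genes highly variable in both datasets (1 + ρ for methylation — the
sign flip implements the repressive relation). Imputed features are the
mean of the partners' rows of the reference (smoothed, HVG-restricted)
matrix. All reference cells participate (no subsampling).

The stacked matrix is centred and reduced to 50 PCs; PCs whose scores
correlate with log2(detected genes) beyond a threshold can be dropped (0.7
is used inside the clustering pipeline of the cross-validation machinery,
0.6 is the embedding convention; disabled by default in the fusion PCA).
Leiden runs on the union-symmetrized unweighted kNN graph (k = 30) at
resolution 0.1 with an explicit seed. Iterative fusion re-runs the entire
pipeline (HVG re-selection, smoothing, imputation, clustering) inside every
cluster with at least `min_cells_split` = 50 cells (below that the kNN
graph is unreliable); labels nest by construction (`parent.child` strings).

The transcriptome-only consensus backend samples up to
max(100, ⌈5000/n_clusters⌉) anchor cells per cluster from each reference
dataset, finds each cell's k = 15 nearest anchors (Euclidean within
dataset, Pearson correlation across datasets — "correlation" read as
Pearson on the shared-HVG log space), weights cell pairs by the Jaccard
index of their anchor-neighbour sets, and applies seeded Louvain.
kNN-anchor imputation averages each cell's anchor neighbours in the
reference feature space.

## Consensus merging

DE between two clusters is a two-sided Wilcoxon rank-sum per gene per
dataset with BH correction within the comparison (the test itself is a
design point; rank-sum is the standard nonparametric choice and is recorded
in provenance). Fold changes are computed on linearized means — 10^x − 1
for log-transformed data with pseudocount 1 CPM, the ratio values directly
for methylation — and methylation fold changes are sign-flipped so
"up-regulated" means the same thing in every dataset. A dataset contributes
only when both clusters have ≥4 cells (SMART-like platforms) or ≥10 cells
(droplet platforms).

Conserved DE genes are significant (FDR < 0.01, >2-fold) in ≥1 dataset with
a >2-fold same-direction change in all but one dataset (merge rule) or in
≥70% of datasets (marker rule); any strong opposite-direction change
disqualifies a gene. The per-dataset separation score is
Σ min(−log10 FDR, 20) over conserved genes, thresholded at 100 by default
(the score formula is a configuration point; the capped-sum form is the
convention such thresholds in the 100–150 range imply). Merging
iterates: candidate pairs are each cluster's three nearest by centroid
Pearson correlation; the unseparable pair with the smallest score merges
first; the loop reaches a fixed point in at most n_clusters iterations
because every merge reduces the count by one.

The taxonomy tree is average-linkage agglomeration under correlation
distance over cluster-centroid marker profiles (concatenated across
reference datasets when several exist); leaves are clusters, output is
Newick with parent-minus-child branch lengths, and cluster order does not
affect the topology.

## Cluster-resolution cross-validation

Feature splits randomize chromosome order and greedily assign each
chromosome to the lighter side by gene count, so the two sides are balanced
even for small synthetic genomes and no chromosome straddles the split.
Cells are clustered on one side (HVG → 50 PCs, with PCs tracking
log2(detected genes) above |r| = 0.7 removed so per-cell depth cannot
masquerade as structure → kNN(30) → Leiden), and centroid MSE is evaluated
on the other side under k-fold cell splits (unstratified uniform folds;
stratification is exposed as future work). Clusters with no training cells
in a fold score their test cells against the global training centroid,
which keeps the MSE defined at extreme resolutions.

The resolution sweep is a 12-point geometric grid on [0.05, 20] plus an
explicit single-cluster baseline (encoded as resolution 0): on a graph of
well-separated components Leiden cannot return one cluster at any positive
resolution, yet the one-cluster model is the natural left anchor of the
U-curve and the expected optimum for structureless data. The 1-SE band
uses the s.e.m. at the minimum (the classic one-standard-error rule); ties
at the minimum report the smallest cluster count. Cross-dataset
cross-validation clusters all datasets jointly (one integration pass per
feature split, Leiden re-run per resolution) and scores each dataset on its
own validation features.

## Replicability

Fast neighbour voting: cell–cell similarity is the Spearman correlation
over shared HVGs (the intersection of per-dataset selections, computed on
at most 50,000 cells per dataset); a test cell's vote for a training
cluster is its mean similarity to that cluster's cells — no rank
standardization, no degree normalization. One-vs-all AUROC is the
Mann–Whitney probability (midrank ties) that members of a test cluster
outrank non-members. For methylation-versus-expression dataset pairs the
similarity is negated (`flip=True`), extending the scoring to
anti-correlated modalities.

One-vs-best: for each test cluster the two best training candidates by
one-vs-all AUROC (ties toward the larger cluster, then lexicographic)
contest the cluster's cells directly — a = P(a random member votes higher
for the winner than for the runner-up, ties half). The winner's entry holds
a, the runner-up 1 − a, all other entries 0, so entries per test cluster
sum to one and only the best match can exceed 0.5. The paired contest is
used because the member cells' overall similarity level varies far more
than the between-candidate difference; pairing removes that common scale.
Meta-clusters are connected components of reciprocal best hits with both
scores above the threshold (0.7 by default, the value at which replicable
structure and stringency balance).

Cross-platform divergence samples 1,000 cells per type per platform (with
replacement when fewer exist; types under 1% or under 300 cells in any
platform are omitted — both filters configurable, and scaled down for
synthetic datasets far smaller than the originals), pools counts into a
per-type gene probability vector and reports base-2 Jensen–Shannon
divergence, bounded in [0, 1] and symmetric.

## Problem sizes and numerical notes

The shipped experiments use K = 8 types in 4 subclasses with 2,000 genes
and three 1,500-cell datasets for integration and cross-dataset CV; K = 10
with 5,000 RNA cells for within-dataset CV (5 feature splits × 5 folds);
200-cell two-population instances over 20 seeds for the merge null and
alternative. These sizes make every experiment reproducible in minutes on
one CPU while leaving each conclusion's signal-to-noise comfortable.

PCA uses full (deterministic) SVD. All randomness is explicit: generators
take integer seeds, Leiden and Louvain are seeded, and a pipeline master
seed fans out to per-stage seeds. Spearman ranks use midranks with
row-normalization guarded against constant rows. Quantile-bin ties, HVG
ranking ties and best-hit ties all break deterministically (documented
above), so repeated runs produce byte-identical label files.

## Known limitations

* Recovery guarantees are demonstrated on well-separated synthetic types;
  continuously varying populations will produce broad, flat CV basins
  rather than a sharp optimum (as expected of the method).
* The restricted-k-partner matcher is a greedy approximation to the
  quota-constrained assignment problem, not an optimal matching.
* The per-cell method-of-moments beta prior is a pragmatic stand-in for a
  full empirical-Bayes fit of methylation rates.
* The one-cluster CV anchor is a convention; Leiden itself never emits a
  single cluster on a disconnected graph.
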