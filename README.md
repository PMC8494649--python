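# cellfuse

Multimodal single-cell integration and cluster validation: a tested,
reusable implementation of the computational core behind consensus cell-type
atlases that combine single-cell/single-nucleus RNA-seq, single-nucleus DNA
methylation (snmC-style gene-body mCH) and single-nucleus ATAC gene-body
counts.

## Who this is for

Anyone who needs to (a) integrate cell-by-gene matrices from datasets that
measure *different* molecular modalities at different depths, (b) decide how
many clusters the data actually support, and (c) quantify whether a cluster
found in one dataset replicates in another. The package ships a synthetic
multimodal data generator with known ground truth, so every stage is
testable end to end without downloading any external data.

## What it implements

**Library-size estimation.** The number of unique reads observed after
sequencing S reads from a library of F distinct fragments is
`N_unique = F [1 − (1 − 1/F)^S]`; `estimate_library_size` inverts this
monotone relation by bracketed root finding.

**Normalization and feature selection.** log10(CPM+1) for droplet RNA,
log10(TPM+1) for full-length RNA, log10(RPM+1) for ATAC gene bodies, and the
per-gene mCH fraction divided by the cell's global mCH for methylation.
Highly variable genes are chosen by binned dispersion (variance/mean) for
count data and binned variance for methylation; beta-binomial posterior
shrinkage of methylation rates is available.

**Cross-modality integration.** Each dataset is smoothed within its own
modality by a Markov diffusion on an adaptive-kernel kNN graph
(`X ← (1−p)X + pMX`, p = 0.7 RNA / 0.9 mC / 0.1 ATAC). Cells of every
non-reference dataset are then imputed onto a reference RNA feature space
through restricted k-partner matching (k = 20 partners, quota relaxation
z = 3) under a Spearman-correlation distance, sign-flipped for methylation,
which anti-correlates with expression. The stacked matrix is reduced to 50
principal components and clustered with Leiden (kNN graph, k = 30,
resolution 0.1), iteratively within each cluster to produce nested label
levels (L0/L1/L2). An anchor-based Jaccard-graph/Louvain backend covers
transcriptome-only consensus clustering.

**Consensus merging.** Cluster pairs are tested per dataset with a
Wilcoxon rank-sum test (Benjamini–Hochberg FDR); conserved differentially
expressed genes must be significant in at least one dataset with a >2-fold
same-direction change in all but one dataset. Pairs whose separation score
(Σ min(−log10 FDR, 20) over conserved genes) stays below threshold are
merged to a fixed point. Marker selection and an average-linkage
correlation-distance taxonomy dendrogram (Newick output) operate on the
merged clusters.

**Cluster-resolution cross-validation.** Features are split by chromosome
into clustering and validation halves; cells are clustered on one half and
scored by how well training-cell cluster centroids predict the held-out
half for test cells (mean squared error). Test MSE against the number of
clusters traces a U-shaped curve; its minimum and the minimum + 1 s.e.m.
band estimate the supportable resolution, within one dataset or across
datasets through joint clustering.

**Replicability.** A fast neighbor-voting AUROC (Spearman similarity, no
rank standardization or degree normalization) scores how well a training
cluster's votes rank a test cluster's cells; one-vs-all scores are
sharpened to one-vs-best (best match holds a, runner-up 1−a, rest 0), and
meta-clusters are connected components of reciprocal best hits above
AUROC 0.7. A base-2 Jensen–Shannon divergence compares pooled per-type
expression profiles between platforms.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import cellfuse as cf

atlas = cf.default_atlas(seed=1)                       # 8 types, 4 subclasses
datasets = [cf.simulate_dataset(atlas, s)              # RNA + mC + ATAC
            for s in cf.default_dataset_specs(seed=1, n_cells=600)]
assign = cf.iterative_fusion(datasets, "rna", rounds=2, seed=1)
truth = np.concatenate([d.cells["true_type"].to_numpy() for d in datasets])
print("clusters per level:",
      {lvl: assign.cells[lvl].nunique() for lvl in assign.levels})
print("ARI vs planted types: %.3f"
      % adjusted_rand_score(truth, assign.labels(assign.levels[-1])))
print("library size from 2,000 reads with 865 unique: %.0f"
      % cf.estimate_library_size(2000, 865))
```

prints

```
clusters per level: {'L0': 8, 'L1': 8}
ARI vs planted types: 0.994
library size from 2,000 reads with 865 unique: 1000
```

The integration recovers all eight planted types across the three
modalities (ARI 0.994 against ground truth), and the duplicate-rate model
recovers the true library size of 1,000 fragments from 2,000 reads of which
865 were unique.

A command-line interface mirrors the library:
`cellfuse simulate`, `cellfuse normalize`, `cellfuse hvg`,
`cellfuse libsize`, `cellfuse fuse`, `cellfuse cv`, `cellfuse run`.

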