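"""Synthetic multimodal single-cell data with known cell-type structure.

Generates a latent atlas of cell types arranged in a shallow two-level
hierarchy (subclass -> type) together with per-type gene programs, then
simulates modality-specific observations from it:

* RNA (whole-cell or nuclear): overdispersed UMI/read counts, negative
  binomial around ``softmax(program) * depth``; nuclear datasets apply a
  per-gene nuclear-retention factor emulating nucleus-enriched transcripts
  such as *Malat1*.
* DNA methylation (mc): paired (methylated-call, coverage) count matrices
  over gene bodies, beta-binomial with a mean mCH fraction that decreases
  with the gene program (methylation represses expression), plus per-cell
  global mCH/mCG/mCCC rates.
* ATAC: sparse overdispersed gene-body fragment counts increasing with the
  program.

Also provides a read-duplication simulator used to exercise the
library-size estimator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

MODALITIES = ("rna_cell", "rna_nucleus", "mc", "atac")

#: genes get chromosome labels "chr1".."chrN" assigned round-robin so that
#: any split of chromosomes leaves markers on both sides.
def _chromosome_labels(n_genes: int, n_chromosomes: int) -> np.ndarray:
    return np.array([f"chr{(i % n_chromosomes) + 1}" for i in range(n_genes)])


@dataclass
class LatentAtlas:
    """Ground-truth cell-type structure shared by all simulated datasets."""

    n_types: int
    type_labels: list[str]
    type_parent: dict[str, str]  # type -> subclass
    gene_programs: np.ndarray  # (n_types, n_genes) mean log-expression
    genes: pd.DataFrame  # gene_id, chromosome, length, nuclear_retention
    type_proportions: np.ndarray
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.type_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("type_proportions must sum to 1")
        if set(self.type_labels) != set(self.type_parent):
            raise ValueError("every type needs a parent subclass")
        if (self.genes["length"] <= 0).any():
            raise ValueError("gene_length must be positive")

    @property
    def n_genes(self) -> int:
        return self.gene_programs.shape[1]

    @property
    def subclasses(self) -> list[str]:
        seen: list[str] = []
        for t in self.type_labels:
            s = self.type_parent[t]
            if s not in seen:
                seen.append(s)
        return seen


@dataclass
class DatasetSpec:
    """Attributes of one simulated dataset (emulating platform trade-offs)."""

    modality: str
    platform: str = "10x"
    n_cells: int = 1000
    depth: float = 5000.0  # mean total counts (RNA/ATAC) or mean coverage (mc)
    dispersion: float = 10.0
    coupling: float = 1.0  # signed link to gene programs; mc must be <= 0
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.modality == "mc" and self.coupling > 0:
            raise ValueError("mc coupling must be <= 0 (methylation is repressive)")
        if self.modality in ("rna_cell", "rna_nucleus", "atac") and self.coupling < 0:
            raise ValueError("RNA/ATAC coupling must be >= 0")


@dataclass
class OmicsDataset:
    """One dataset's cells x genes raw measurements plus metadata.

    ``values`` holds counts with cells as rows.  Methylation datasets carry
    an additional ``coverage`` matrix of identical shape; ``values`` then
    holds methylated-cytosine calls.
    """

    modality: str
    platform: str
    cells: pd.DataFrame  # indexed by cell_id
    genes: pd.DataFrame  # indexed by gene_id
    values: sp.csr_matrix
    coverage: Optional[sp.csr_matrix] = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError("values shape does not match cells x genes")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.modality == "mc":
            if self.coverage is None:
                raise ValueError("mc dataset requires a coverage matrix")
            self.coverage = sp.csr_matrix(self.coverage)
            if self.coverage.shape != self.values.shape:
                raise ValueError("coverage shape mismatch")
            if (self.values.toarray() > self.coverage.toarray()).any():
                raise ValueError("methylated calls exceed coverage")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "OmicsDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return OmicsDataset(
            modality=self.modality,
            platform=self.platform,
            cells=self.cells.iloc[idx].copy(),
            genes=self.genes,
            values=self.values[idx],
            coverage=None if self.coverage is None else self.coverage[idx],
            name=self.name,
        )

    def subset_genes(self, gene_ids) -> "OmicsDataset":
        pos = self.genes.index.get_indexer(pd.Index(gene_ids))
        if (pos < 0).any():
            raise KeyError("unknown gene ids in subset")
        return OmicsDataset(
            modality=self.modality,
            platform=self.platform,
            cells=self.cells,
            genes=self.genes.iloc[pos].copy(),
            values=sp.csr_matrix(self.values[:, pos]),
            coverage=None if self.coverage is None else sp.csr_matrix(self.coverage[:, pos]),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# atlas generation
# ---------------------------------------------------------------------------

def generate_atlas(
    n_types: int,
    n_genes: int,
    n_chromosomes: int = 10,
    effect_size: float = 2.0,
    seed: int = 0,
    n_subclasses: Optional[int] = None,
    markers_per_type: int = 20,
    markers_per_subclass: int = 20,
    nuclear_fraction: float = 0.01,
    nuclear_factor: float = 5.0,
    baseline_sd: float = 1.5,
) -> LatentAtlas:
    """Draw a latent atlas with planted subclass- and type-level markers.

    Each type receives ``markers_per_type`` genes whose mean log-expression
    exceeds all sibling types by exactly ``effect_size``; each subclass
    additionally receives shared markers separating it from other
    subclasses.  Chromosomes are assigned round-robin.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if n_genes < 10 * n_types:
        raise ValueError("n_genes must be >= 10 * n_types")
    if n_chromosomes < 2:
        raise ValueError("n_chromosomes must be >= 2")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_subclasses is None:
        n_subclasses = max(1, n_types // 2)
    if n_subclasses > n_types:
        raise ValueError("n_subclasses cannot exceed n_types")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(0.0, baseline_sd, size=n_genes)
    programs = np.tile(baseline, (n_types, 1))

    need = n_subclasses * markers_per_subclass + n_types * markers_per_type
    if need > n_genes:
        raise ValueError("not enough genes for the requested marker blocks")

    type_labels = [f"t{i:02d}" for i in range(n_types)]
    subclass_labels = [f"s{i:02d}" for i in range(n_subclasses)]
    # types distributed round-robin over subclasses
    type_parent = {t: subclass_labels[i % n_subclasses] for i, t in enumerate(type_labels)}

    marker_genes: dict[str, list[str]] = {}
    cursor = 0
    for s_idx, s in enumerate(subclass_labels):
        block = range(cursor, cursor + markers_per_subclass)
        cursor += markers_per_subclass
        members = [i for i, t in enumerate(type_labels) if type_parent[t] == s]
        programs[np.ix_(members, list(block))] += effect_size
        marker_genes[s] = [gene_ids[g] for g in block]
    for t_idx, t in enumerate(type_labels):
        block = range(cursor, cursor + markers_per_type)
        cursor += markers_per_type
        programs[t_idx, list(block)] += effect_size
        marker_genes[t] = [gene_ids[g] for g in block]

    retention = np.ones(n_genes)
    n_nuc = int(np.ceil(nuclear_fraction * n_genes))
    nuc_idx = rng.choice(n_genes, size=n_nuc, replace=False)
    retention[nuc_idx] = nuclear_factor

    genes = pd.DataFrame(
        {
            "chromosome": _chromosome_labels(n_genes, n_chromosomes),
            "length": rng.integers(500, 50_001, size=n_genes),
            "nuclear_retention": retention,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    proportions = np.full(n_types, 1.0 / n_types)
    proportions[-1] = 1.0 - proportions[:-1].sum()  # exact simplex
    return LatentAtlas(
        n_types=n_types,
        type_labels=type_labels,
        type_parent=type_parent,
        gene_programs=programs,
        genes=genes,
        type_proportions=proportions,
        marker_genes=marker_genes,
    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: var = m + m^2 / dispersion."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=dispersion, scale=mean[pos] / dispersion)
    return rng.poisson(lam)


def _standardized_programs(programs: np.ndarray) -> np.ndarray:
    """Per-gene z-score of the program across types (0 where constant)."""
    mu = programs.mean(axis=0)
    sd = programs.std(axis=0)
    z = np.zeros_like(programs)
    ok = sd > 1e-12
    z[:, ok] = (programs[:, ok] - mu[ok]) / sd[ok]
    return z


def simulate_dataset(atlas: LatentAtlas, spec: DatasetSpec) -> OmicsDataset:
    """Simulate one dataset from the atlas according to its modality."""
    if atlas.n_genes != len(atlas.genes):
        raise ValueError("atlas inconsistent")
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, atlas.n_genes
    types = rng.choice(atlas.n_types, size=n, p=atlas.type_proportions)
    type_names = np.array(atlas.type_labels)[types]
    subclass = np.array([atlas.type_parent[t] for t in type_names])
    cell_ids = [f"{spec.name or spec.modality}_c{i:05d}" for i in range(n)]

    meta = pd.DataFrame(
        {"true_type": type_names, "true_subclass": subclass},
        index=pd.Index(cell_ids, name="cell_id"),
    )

    if spec.modality in ("rna_cell", "rna_nucleus", "atac"):
        if spec.modality == "atac":
            z = _standardized_programs(atlas.gene_programs)
            w = np.exp(spec.coupling * z)
        else:
            w = np.exp(spec.coupling * (atlas.gene_programs - atlas.gene_programs.max()))
            if spec.modality == "rna_nucleus":
                w = w * atlas.genes["nuclear_retention"].to_numpy()
        probs = w / w.sum(axis=1, keepdims=True)
        depth_cell = (
            rng.gamma(shape=10.0, scale=spec.depth / 10.0, size=n) if spec.depth > 0 else np.zeros(n)
        )
        mean = probs[types] * depth_cell[:, None]
        counts = _nb_counts(rng, mean, spec.dispersion)
        values = sp.csr_matrix(counts)
        meta["total_reads"] = counts.sum(axis=1)
        meta["n_detected_genes"] = (counts > 0).sum(axis=1)
        return OmicsDataset(
            modality=spec.modality,
            platform=spec.platform,
            cells=meta,
            genes=atlas.genes,
            values=values,
            name=spec.name or spec.modality,
        )

    # methylation branch: coupling <= 0, strength = |coupling|
    strength = -spec.coupling
    z = _standardized_programs(atlas.gene_programs)
    global_mch = rng.beta(8.0, 192.0, size=n)  # mean 0.04
    global_mcg = rng.beta(39.0, 11.0, size=n)  # mean 0.78
    global_mccc = rng.beta(2.0, 398.0, size=n)  # mean 0.005
    # gene-body coverage: deep and fairly even across genes, with modest
    # per-cell and per-gene variation
    depth_cell = rng.gamma(shape=25.0, scale=spec.depth / 25.0, size=n) if spec.depth > 0 else np.zeros(n)
    gene_factor = rng.gamma(shape=10.0, scale=0.1, size=g)
    cov = rng.poisson(depth_cell[:, None] * gene_factor[None, :])
    # per-gene baseline mCH spreads over ~an order of magnitude across genes,
    # as gene-body methylation does in real neurons
    gene_base = rng.lognormal(0.0, 0.5, size=g)
    frac = np.clip(
        global_mch[:, None] * gene_base[None, :] * np.exp(-strength * z[types]), 1e-3, 0.999
    )
    kappa = spec.dispersion
    f = rng.beta(frac * kappa, (1.0 - frac) * kappa)
    calls = rng.binomial(cov, f)
    meta["total_reads"] = rng.poisson(1_500_000, size=n)
    meta["n_detected_genes"] = (cov > 0).sum(axis=1)
    meta["global_mch"] = global_mch
    meta["global_mcg"] = global_mcg
    meta["global_mccc"] = global_mccc
    return OmicsDataset(
        modality="mc",
        platform=spec.platform,
        cells=meta,
        genes=atlas.genes,
        values=sp.csr_matrix(calls),
        coverage=sp.csr_matrix(cov),
        name=spec.name or "mc",
    )


def shuffle_cell_type_correspondence(dataset: OmicsDataset, seed: int = 0) -> OmicsDataset:
    """Negative control: destroy the cell-to-type correspondence of a dataset
    by independently permuting the cells within every gene column (for mc,
    the methylated-call/coverage pair moves together).  Per-gene marginal
    distributions are preserved; per-cell profiles become type-incoherent.
    """
    rng = np.random.default_rng(seed)
    vals = np.asarray(dataset.values.todense())
    cov = None if dataset.coverage is None else np.asarray(dataset.coverage.todense())
    for j in range(vals.shape[1]):
        perm = rng.permutation(vals.shape[0])
        vals[:, j] = vals[perm, j]
        if cov is not None:
            cov[:, j] = cov[perm, j]
    return OmicsDataset(
        modality=dataset.modality,
        platform=dataset.platform,
        cells=dataset.cells,
        genes=dataset.genes,
        values=sp.csr_matrix(vals),
        coverage=None if cov is None else sp.csr_matrix(cov),
        name=dataset.name,
    )


def simulate_duplication(true_library_size: int, n_reads: int, seed: int = 0) -> int:
    """Draw ``n_reads`` fragments uniformly with replacement from a library
    of ``true_library_size`` distinct fragments; return the number of
    distinct fragments observed.  E[unique] = F * (1 - (1 - 1/F)^S).
    """
    if true_library_size < 1 or n_reads < 1:
        raise ValueError("true_library_size and n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, true_library_size, size=n_reads)
    return int(np.unique(draws).size)


def default_atlas(seed: int = 0) -> LatentAtlas:
    """The study-condition atlas: 8 types in 4 subclasses, 2,000 genes."""
    return generate_atlas(
        n_types=8, n_genes=2000, n_chromosomes=10, effect_size=2.0, seed=seed, n_subclasses=4
    )


def default_dataset_specs(seed: int = 0, n_cells: int = 1500) -> list[DatasetSpec]:
    """Three-modality study conditions: RNA (10x-like), mc and ATAC."""
    return [
        DatasetSpec("rna_cell", platform="10x", n_cells=n_cells, depth=5000.0,
                    dispersion=10.0, coupling=1.0, seed=seed * 1000 + 1, name="rna"),
        DatasetSpec("mc", platform="snmc", n_cells=n_cells, depth=100.0,
                    dispersion=300.0, coupling=-1.2, seed=seed * 1000 + 2, name="mc"),
        DatasetSpec("atac", platform="snatac", n_cells=n_cells, depth=3000.0,
                    dispersion=2.0, coupling=0.8, seed=seed * 1000 + 3, name="atac"),
    ]
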