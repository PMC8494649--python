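"""Quality control, normalization, highly-variable-gene selection and the
duplicate-rate library-size estimator.

Normalization is modality-specific: droplet RNA uses log10(CPM+1),
full-length (SMART-like) RNA uses log10(TPM+1), ATAC gene-body counts use
log10(RPM+1) (length-normalized), and methylation uses the per-gene mCH
fraction divided by the cell's global mCH rate (zero-coverage entries are
missing, not zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .synth import OmicsDataset


@dataclass
class QcThresholds:
    """Cell-filtering thresholds (all strict inequalities as printed)."""

    mc_max_mccc: float = 0.03
    mc_min_mcg: float = 0.5
    mc_max_mch: float = 0.2
    mc_min_reads: int = 500_000
    mc_min_mapping_rate: float = 0.5
    # per-class detected-gene minima: cells vs nuclei
    rna_cell_neuron: int = 2000
    rna_cell_non_neuron: int = 1000
    rna_nucleus_neuron: int = 1000
    rna_nucleus_non_neuron: int = 500


@dataclass
class NormalizedMatrix:
    """Modality-normalized cells x genes values with the transform recorded."""

    values: np.ndarray  # dense, NaN marks missing (mc zero-coverage)
    transform: str  # log10_cpm1 | log10_tpm1 | log10_rpm1 | mch_ratio
    modality: str
    gene_ids: pd.Index
    cell_ids: pd.Index
    scale_factors: np.ndarray  # per-cell totals / global rates used
    excluded_cells: list = field(default_factory=list)
    n_detected_genes: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def subset_cells(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[idx],
            transform=self.transform,
            modality=self.modality,
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            scale_factors=self.scale_factors[idx],
            n_detected_genes=None if self.n_detected_genes is None else self.n_detected_genes[idx],
        )

    def restrict_genes(self, gene_ids) -> "NormalizedMatrix":
        pos = self.gene_ids.get_indexer(pd.Index(gene_ids))
        if (pos < 0).any():
            raise KeyError("unknown gene ids")
        return NormalizedMatrix(
            values=self.values[:, pos],
            transform=self.transform,
            modality=self.modality,
            gene_ids=pd.Index(gene_ids),
            cell_ids=self.cell_ids,
            scale_factors=self.scale_factors,
            n_detected_genes=self.n_detected_genes,
        )


@dataclass
class HvgSet:
    """Ordered set of highly variable genes plus the selection parameters."""

    gene_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("HvgSet must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in HvgSet")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


# ---------------------------------------------------------------------------
# library size
# ---------------------------------------------------------------------------

def expected_unique(library_size: float, n_sequenced: int) -> float:
    """E[unique reads] = F * (1 - (1 - 1/F)^S) for library size F, reads S."""
    F, S = float(library_size), float(n_sequenced)
    if F <= 1.0:
        return 1.0
    return F * -math.expm1(S * math.log1p(-1.0 / F))


def estimate_library_size(n_sequenced: int, n_unique: int) -> float:
    """Invert the duplicate-rate model for the total library size F.

    Solves n_unique = F[1 - (1 - 1/F)^S] by bracketed root finding; the
    right-hand side is strictly increasing in F.  When no duplicates were
    observed (n_unique == S) the library size is unbounded and ``inf`` is
    returned.
    """
    if not (1 <= n_unique <= n_sequenced):
        raise ValueError("need 1 <= n_unique <= n_sequenced")
    if n_unique == n_sequenced:
        return math.inf
    if n_unique == 1:
        return 1.0

    def g(F: float) -> float:
        return expected_unique(F, n_sequenced) - n_unique

    lo = float(n_unique)
    if g(lo) >= 0:
        return lo
    hi = 2.0 * lo
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - defensive
            return math.inf
    return float(brentq(g, lo, hi, rtol=1e-12, maxiter=200))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter_mc(dataset: OmicsDataset, thresholds: QcThresholds | None = None) -> OmicsDataset:
    """Retain methylation cells passing all global-rate/read-count criteria.

    mCCC < 0.03, mCG > 0.5, mCH < 0.2, total reads > 500,000 and, when a
    ``mapping_rate`` column is present, mapping rate > 0.5.  All strict.
    """
    if dataset.modality != "mc":
        raise ValueError("qc_filter_mc requires an mc dataset")
    th = thresholds or QcThresholds()
    meta = dataset.cells
    required = ["global_mccc", "global_mcg", "global_mch", "total_reads"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise KeyError(f"missing metadata columns: {missing}")
    keep = (
        (meta["global_mccc"] < th.mc_max_mccc)
        & (meta["global_mcg"] > th.mc_min_mcg)
        & (meta["global_mch"] < th.mc_max_mch)
        & (meta["total_reads"] > th.mc_min_reads)
    )
    if "mapping_rate" in meta.columns:
        keep &= meta["mapping_rate"] > th.mc_min_mapping_rate
    return dataset.subset_cells(keep.to_numpy())


def qc_filter_rna(
    dataset: OmicsDataset,
    class_labels,
    thresholds: QcThresholds | None = None,
) -> OmicsDataset:
    """Drop RNA cells below their class-specific detected-gene minimum.

    Neurons and non-neuronal cells have different minima, and nuclei have
    lower minima than whole cells; "detected" means a nonzero count.
    """
    if dataset.modality not in ("rna_cell", "rna_nucleus"):
        raise ValueError("qc_filter_rna requires an RNA dataset")
    th = thresholds or QcThresholds()
    labels = np.asarray(class_labels)
    if len(labels) != dataset.n_cells:
        raise ValueError("class_labels length mismatch")
    bad = set(np.unique(labels)) - {"neuron", "non_neuron"}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    detected = np.asarray((dataset.values > 0).sum(axis=1)).ravel()
    if dataset.modality == "rna_cell":
        minima = {"neuron": th.rna_cell_neuron, "non_neuron": th.rna_cell_non_neuron}
    else:
        minima = {"neuron": th.rna_nucleus_neuron, "non_neuron": th.rna_nucleus_non_neuron}
    cut = np.array([minima[c] for c in labels]) if len(labels) else np.array([])
    keep = detected >= cut  # "fewer than N" removed => >= N retained
    return dataset.subset_cells(keep)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(dataset: OmicsDataset) -> NormalizedMatrix:
    """Modality-specific normalization to a dense cells x genes matrix."""
    if dataset.modality == "mc":
        return _normalize_mc(dataset)
    counts = np.asarray(dataset.values.todense(), dtype=float)
    totals_raw = counts.sum(axis=1)
    keep = totals_raw > 0
    excluded = list(dataset.cells.index[~keep])
    counts = counts[keep]
    if dataset.modality == "atac":
        transform = "log10_rpm1"
        per_len = counts / dataset.genes["length"].to_numpy()
        totals = per_len.sum(axis=1)
        scaled = per_len / totals[:, None] * 1e6
    elif dataset.platform.lower().startswith("smart"):
        transform = "log10_tpm1"
        per_len = counts / dataset.genes["length"].to_numpy()
        totals = per_len.sum(axis=1)
        scaled = per_len / totals[:, None] * 1e6
    else:
        transform = "log10_cpm1"
        totals = counts.sum(axis=1)
        scaled = counts / totals[:, None] * 1e6
    return NormalizedMatrix(
        values=np.log10(scaled + 1.0),
        transform=transform,
        modality=dataset.modality,
        gene_ids=dataset.genes.index,
        cell_ids=dataset.cells.index[keep],
        scale_factors=totals,
        excluded_cells=excluded,
        n_detected_genes=(counts > 0).sum(axis=1),
    )


def _normalize_mc(dataset: OmicsDataset) -> NormalizedMatrix:
    mc = np.asarray(dataset.values.todense(), dtype=float)
    cov = np.asarray(dataset.coverage.todense(), dtype=float)
    if "global_mch" not in dataset.cells.columns:
        raise KeyError("mc dataset requires per-cell global_mch")
    g = dataset.cells["global_mch"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
        vals = frac / g[:, None]
    return NormalizedMatrix(
        values=vals,
        transform="mch_ratio",
        modality="mc",
        gene_ids=dataset.genes.index,
        cell_ids=dataset.cells.index,
        scale_factors=g,
        n_detected_genes=(cov > 0).sum(axis=1),
    )


def posterior_mc_rate(
    mc_counts: np.ndarray, coverage: np.ndarray, prior_strength: float = 1.0
) -> np.ndarray:
    """Beta-binomial posterior-mean methylation rates with per-cell priors.

    For each cell a beta prior (alpha, beta) is fit by method of moments to
    that cell's per-feature raw fractions; the shrunk rate is
    (mc + alpha) / (cov + alpha + beta).  Cells whose fraction variance is
    degenerate fall back to a uniform prior scaled by ``prior_strength``.
    """
    mc = np.atleast_2d(np.asarray(mc_counts, dtype=float))
    cov = np.atleast_2d(np.asarray(coverage, dtype=float))
    if mc.shape != cov.shape:
        raise ValueError("shape mismatch")
    if (mc < 0).any() or (cov < 0).any():
        raise ValueError("negative counts")
    if (mc > cov).any():
        raise ValueError("mc exceeds coverage")
    out = np.empty_like(mc)
    for i in range(mc.shape[0]):
        has = cov[i] > 0
        alpha = beta = prior_strength
        if has.sum() >= 2:
            f = mc[i, has] / cov[i, has]
            m, v = f.mean(), f.var()
            if v > 1e-12 and 0.0 < m < 1.0:
                kappa = m * (1.0 - m) / v - 1.0
                if kappa > 0:
                    alpha, beta = m * kappa, (1.0 - m) * kappa
        out[i] = (mc[i] + alpha) / (cov[i] + alpha + beta)
    return out


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def _quantile_bins(order_vals: np.ndarray, gene_ids: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Equal-count bins by ascending value; stable tie-break by gene id."""
    order = np.lexsort((gene_ids, order_vals))
    return [chunk for chunk in np.array_split(order, n_bins) if chunk.size]


def _top_by(score: np.ndarray, gene_ids: np.ndarray, members: np.ndarray, quota: int) -> list[int]:
    sub = members[np.lexsort((gene_ids[members], -score[members]))]
    return list(sub[:quota])


def select_hvg_count(
    norm: NormalizedMatrix,
    n_bins: int = 10,
    top_fraction: float = 0.3,
    min_cell_fraction: float = 0.01,
) -> HvgSet:
    """Binned-dispersion HVG selection for RNA/ATAC normalized matrices.

    Genes detected in fewer than ``min_cell_fraction`` of cells are removed;
    the remainder are split into ``n_bins`` equal-count bins by mean linear
    expression (CPM/TPM/RPM scale); the highest-expression bin is dropped
    entirely and the top ``top_fraction`` of genes by dispersion
    (variance/mean of the normalized values) is kept from each other bin.
    Ties break lexicographically by gene id.
    """
    if norm.modality == "mc":
        raise ValueError("use select_hvg_mc for methylation")
    vals = norm.values
    gene_ids = np.asarray(norm.gene_ids)
    detected = (vals > 0).mean(axis=0)
    keep = np.flatnonzero(detected >= min_cell_fraction)
    if keep.size == 0:
        raise ValueError("no gene passes the detection filter")
    linear = 10.0 ** vals[:, keep] - 1.0
    mean_lin = linear.mean(axis=0)
    mean_norm = vals[:, keep].mean(axis=0)
    var_norm = vals[:, keep].var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean_norm > 0, var_norm / mean_norm, 0.0)
    eff_bins = n_bins
    if keep.size < n_bins:
        warnings.warn(f"fewer genes ({keep.size}) than bins; reducing bin count")
        eff_bins = keep.size
    bins = _quantile_bins(mean_lin, gene_ids[keep], eff_bins)
    selected: list[int] = []
    for b in bins[:-1]:  # drop the top-expression bin
        quota = max(1, int(np.floor(top_fraction * b.size)))
        selected.extend(_top_by(dispersion, gene_ids[keep], b, quota))
    chosen = gene_ids[keep][np.array(sorted(selected), dtype=int)]
    return HvgSet(
        gene_ids=list(chosen),
        params={
            "method": "count",
            "n_bins": n_bins,
            "top_fraction": top_fraction,
            "min_cell_fraction": min_cell_fraction,
        },
    )


def select_hvg_mc(
    dataset: OmicsDataset,
    min_cov: int = 20,
    min_cell_fraction: float = 0.95,
    n_bins: int = 10,
    top_fraction: float = 0.3,
) -> HvgSet:
    """Binned-variance HVG selection for methylation datasets.

    Keeps genes with > ``min_cov`` cytosine coverage in more than
    ``min_cell_fraction`` of cells, bins them by mean normalized mCH and
    retains the top ``top_fraction`` by variance within every bin.
    """
    if dataset.modality != "mc":
        raise ValueError("select_hvg_mc requires an mc dataset")
    cov = np.asarray(dataset.coverage.todense(), dtype=float)
    frac_covered = (cov > min_cov).mean(axis=0)
    keep = np.flatnonzero(frac_covered > min_cell_fraction)
    if keep.size == 0:
        raise ValueError("no gene passes the coverage filter")
    norm = normalize(dataset)
    gene_ids = np.asarray(norm.gene_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_mch = np.nanmean(norm.values[:, keep], axis=0)
        var_mch = np.nanvar(norm.values[:, keep], axis=0)
    mean_mch = np.nan_to_num(mean_mch)
    var_mch = np.nan_to_num(var_mch)
    eff_bins = n_bins
    if keep.size < n_bins:
        warnings.warn(f"fewer genes ({keep.size}) than bins; reducing bin count")
        eff_bins = keep.size
    bins = _quantile_bins(mean_mch, gene_ids[keep], eff_bins)
    selected: list[int] = []
    for b in bins:  # all bins retained for the mc branch
        quota = max(1, int(np.floor(top_fraction * b.size)))
        selected.extend(_top_by(var_mch, gene_ids[keep], b, quota))
    chosen = gene_ids[keep][np.array(sorted(selected), dtype=int)]
    return HvgSet(
        gene_ids=list(chosen),
        params={
            "method": "mc",
            "min_cov": min_cov,
            "min_cell_fraction": min_cell_fraction,
            "n_bins": n_bins,
            "top_fraction": top_fraction,
        },
    )


# ---------------------------------------------------------------------------
# browser-style [0, 1] scaling
# ---------------------------------------------------------------------------

def scale_unit_interval(values: np.ndarray, modality: str) -> tuple[np.ndarray, bool]:
    """Map one gene's per-cell signal to [0, 1] for cross-modal display.

    Non-methylation signals are mapped linearly between their 2nd and 98th
    percentiles then clipped; methylation uses the 2nd and 50th percentiles
    and is flipped (1 - x) so that a high value means low methylation.
    Returns (scaled, degenerate_flag).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cells")
    if modality == "mc":
        lo, hi = np.nanpercentile(x, [2, 50])
    else:
        lo, hi = np.nanpercentile(x, [2, 98])
    if hi == lo:
        return np.zeros_like(x), True
    scaled = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    if modality == "mc":
        scaled = 1.0 - scaled
    return scaled, False
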