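"""Cross-dataset and cross-modality integration.

Two backends are provided:

* The diffusion/imputation backend: each dataset is smoothed within its own
  modality by a Markov diffusion on a kNN graph, query cells are mapped onto
  a reference RNA feature space through restricted k-partner (RKP)
  imputation with a (flipped, for methylation) Spearman distance, and the
  stacked matrix is clustered with Leiden on a symmetrized unweighted kNN
  graph.  ``iterative_fusion`` reapplies the whole procedure within each
  cluster to produce nested label levels (L0, L1, L2, ...).
* The anchor/Jaccard consensus backend for transcriptome-only integration:
  per-cluster anchor sampling from reference datasets, kNN of every cell
  among anchors, a Jaccard-weighted shared-neighbor graph, and Louvain
  community detection; expression is harmonized by kNN-anchor imputation.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .qcnorm import NormalizedMatrix, HvgSet, normalize, select_hvg_count, select_hvg_mc
from .synth import OmicsDataset


@dataclass
class SmoothingParams:
    """Diffusion-smoothing parameters; ``p`` is the modality-specific weight."""

    ndim: int = 50
    k: int = 30
    ka: int = 5
    p: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.ka >= self.k:
            raise ValueError("ka must be < k")


#: default diffusion weights per modality: heavier smoothing for sparse or
#: noisy modalities (methylation), light smoothing for ATAC.
DIFFUSION_P = {"rna_cell": 0.7, "rna_nucleus": 0.7, "mc": 0.9, "atac": 0.1}


@dataclass
class ImputationParams:
    k: int = 20  # restricted partners per query cell
    z: int = 3  # relaxation of the per-reference-cell quota
    distance: str = "spearman"

    def __post_init__(self) -> None:
        if self.k < 1 or self.z < 1:
            raise ValueError("k and z must be >= 1")


@dataclass
class ClusterAssignment:
    """Per-cell labels at nested resolution levels with provenance."""

    cells: pd.DataFrame  # columns: dataset, cell_id, L0, L1, ... (strings)
    method: str
    params: dict = field(default_factory=dict)

    @property
    def levels(self) -> list[str]:
        return [c for c in self.cells.columns if c.startswith("L")]

    def labels(self, level: str) -> np.ndarray:
        return self.cells[level].to_numpy()

    def check_nesting(self) -> bool:
        """Labels at level n+1 must refine the partition at level n."""
        levels = self.levels
        for fine, coarse in zip(levels[1:], levels[:-1]):
            grouped = self.cells.groupby(fine)[coarse].nunique()
            if (grouped > 1).any():
                return False
        return True


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _fill_nan_colmean(x: np.ndarray) -> np.ndarray:
    if not np.isnan(x).any():
        return x
    out = x.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col = np.nanmean(out, axis=0)
    col = np.nan_to_num(col)
    ii, jj = np.nonzero(np.isnan(out))
    out[ii, jj] = col[jj]
    return out


def _pca_scores(x: np.ndarray, ndim: int, center: bool = True) -> np.ndarray:
    ndim = min(ndim, min(x.shape) - 1)
    if ndim < 1:
        return x - x.mean(axis=0) if center else x
    return PCA(n_components=ndim, svd_solver="full").fit_transform(x)


def markov_matrix(x: np.ndarray, k: int, ka: int, ndim: int = 50) -> sp.csr_matrix:
    """Row-stochastic diffusion operator from an adaptive Gaussian kNN kernel.

    Neighbors are found with Euclidean distance in the top-``ndim`` PC space;
    the kernel bandwidth for each cell is its distance to the ka-th
    neighbor.  The cell itself enters with weight 1 before row
    normalization.
    """
    n = x.shape[0]
    if k >= n:
        raise ValueError("k must be < n_cells")
    pcs = _pca_scores(_fill_nan_colmean(x), ndim)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)  # includes self at distance 0
    sigma = np.maximum(dist[:, min(ka, k)], 1e-12)
    w = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k + 1)
    m = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    norm = np.asarray(m.sum(axis=1)).ravel()
    return sp.diags(1.0 / norm) @ m


def smooth_within_modality(values: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Diffusion smoothing: (1 - p) X + p M X on the HVG-restricted matrix."""
    x = _fill_nan_colmean(np.asarray(values, dtype=float))
    if params.p == 0.0:
        return x.copy()
    m = markov_matrix(x, params.k, params.ka, params.ndim)
    return (1.0 - params.p) * x + params.p * (m @ x)


# ---------------------------------------------------------------------------
# cross-modality imputation (restricted k-partners)
# ---------------------------------------------------------------------------

def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Midrank each row (average ranks for ties), centered and normalized."""
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(x)
    n = x.shape[1]
    arange = np.arange(1, n + 1, dtype=float)
    for i in range(x.shape[0]):
        xi = x[i, order[i]]
        r = arange.copy()
        # average ranks over tie runs
        start = 0
        for j in range(1, n + 1):
            if j == n or xi[j] != xi[start]:
                r[start:j] = r[start:j].mean()
                start = j
        ranks[i, order[i]] = r
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    norm[norm == 0] = 1.0
    return ranks / norm[:, None]


def spearman_distance(query: np.ndarray, reference: np.ndarray, flip: bool = False) -> np.ndarray:
    """1 - rho (or 1 + rho for anti-correlated modalities) across genes."""
    q = _rank_rows(_fill_nan_colmean(np.asarray(query, dtype=float)))
    r = _rank_rows(_fill_nan_colmean(np.asarray(reference, dtype=float)))
    rho = q @ r.T
    return 1.0 + rho if flip else 1.0 - rho


def restricted_k_partners(dist: np.ndarray, k: int, z: int) -> np.ndarray:
    """Greedy globally-sorted partner assignment with reference quotas.

    Pairs are visited by ascending distance; a query takes a reference cell
    as partner if it still needs partners and the reference has not hit its
    quota z * ceil(k * n_query / n_reference).  Returns (n_query, k) partner
    indices.
    """
    nq, nr = dist.shape
    quota = z * int(np.ceil(k * nq / nr))
    if quota * nr < k * nq:
        min_z = int(np.ceil(k * nq / (np.ceil(k * nq / nr) * nr)))
        raise ValueError(f"RKP quota infeasible; minimal feasible z = {min_z}")
    if k > nr:
        raise ValueError("k exceeds the number of reference cells")
    flat = np.argsort(dist, axis=None, kind="stable")
    partners = np.full((nq, k), -1, dtype=int)
    n_assigned = np.zeros(nq, dtype=int)
    usage = np.zeros(nr, dtype=int)
    remaining = nq * k
    for f in flat:
        qi, ri = divmod(int(f), nr)
        if n_assigned[qi] >= k or usage[ri] >= quota:
            continue
        partners[qi, n_assigned[qi]] = ri
        n_assigned[qi] += 1
        usage[ri] += 1
        remaining -= 1
        if remaining == 0:
            break
    if remaining:  # pragma: no cover - capacity argument makes this rare
        for qi in np.flatnonzero(n_assigned < k):
            order = np.argsort(dist[qi], kind="stable")
            for ri in order:
                if n_assigned[qi] >= k:
                    break
                if ri not in partners[qi, : n_assigned[qi]]:
                    partners[qi, n_assigned[qi]] = ri
                    n_assigned[qi] += 1
    return partners


def impute_cross_modality(
    reference: NormalizedMatrix,
    query: NormalizedMatrix,
    shared_hvg: HvgSet | list[str],
    params: ImputationParams | None = None,
    flip: Optional[bool] = None,
) -> np.ndarray:
    """Impute reference features for query cells via restricted k-partners.

    Distances are (flipped) Spearman correlations over the shared highly
    variable genes; each query cell's imputed profile is the mean of its k
    partners' rows of the reference matrix (the full reference feature
    space, not just the shared genes).
    """
    params = params or ImputationParams()
    shared = list(shared_hvg)
    if not shared:
        raise ValueError("shared_hvg must be non-empty")
    if flip is None:
        flip = query.modality == "mc"
    q = query.restrict_genes(shared).values
    r = reference.restrict_genes(shared).values
    dist = spearman_distance(q, r, flip=flip)
    partners = restricted_k_partners(dist, params.k, params.z)
    return reference.values[partners].mean(axis=1)


# ---------------------------------------------------------------------------
# joint reduction and Leiden clustering
# ---------------------------------------------------------------------------

def joint_reduce(
    stacked: np.ndarray,
    n_pcs: int = 50,
    ngene_corr_max: float = 1.0,
    log2_ngenes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Centered PCA of the stacked imputed matrix, optionally dropping PCs
    correlated with log2(detected genes) above ``ngene_corr_max``."""
    x = _fill_nan_colmean(np.asarray(stacked, dtype=float))
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs truncated from {n_pcs} to {max_rank}")
        n_pcs = max_rank
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    if log2_ngenes is not None and ngene_corr_max < 1.0:
        lg = np.asarray(log2_ngenes, dtype=float)
        keep = []
        for j in range(pcs.shape[1]):
            c = np.corrcoef(pcs[:, j], lg)[0, 1]
            if not np.isfinite(c) or abs(c) <= ngene_corr_max:
                keep.append(j)
        pcs = pcs[:, keep]
    return pcs


def knn_graph(pcs: np.ndarray, k: int = 30) -> ig.Graph:
    """Symmetrized (union), unweighted kNN graph on Euclidean distances."""
    n = pcs.shape[0]
    if k >= n:
        raise ValueError("k must be < n_cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def leiden_cluster(
    pcs: np.ndarray, k: int = 30, resolution: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Leiden partition of the kNN graph at the given resolution (seeded)."""
    g = knn_graph(pcs, k=min(k, pcs.shape[0] - 1))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# iterative fusion (diffusion backend)
# ---------------------------------------------------------------------------

def _dataset_hvg(dataset: OmicsDataset, norm: NormalizedMatrix) -> HvgSet:
    if dataset.modality == "mc":
        return select_hvg_mc(dataset)
    return select_hvg_count(norm)


def _smooth_params_for(modality: str, base: SmoothingParams, n_cells: int) -> SmoothingParams:
    k = min(base.k, max(2, n_cells - 1))
    ka = min(base.ka, k - 1)
    return replace(base, k=k, ka=max(1, ka), p=DIFFUSION_P.get(modality, base.p))


def fuse_datasets(
    datasets: list[OmicsDataset],
    reference: str,
    smoothing: SmoothingParams | None = None,
    imputation: ImputationParams | None = None,
    hvg_sets: Optional[dict[str, HvgSet]] = None,
    n_pcs: int = 50,
    ngene_corr_max: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One integration pass: smooth, impute onto the reference RNA feature
    space, and reduce to principal components.

    Returns (pc_matrix, cell_frame) where cell_frame holds (dataset,
    cell_id) rows aligned with the PC matrix.
    """
    smoothing = smoothing or SmoothingParams()
    imputation = imputation or ImputationParams()
    by_name = {d.name: d for d in datasets}
    if reference not in by_name:
        raise KeyError(f"reference dataset {reference!r} not found")
    if by_name[reference].modality not in ("rna_cell", "rna_nucleus"):
        raise ValueError("reference must be an RNA dataset")

    norms = {d.name: normalize(d) for d in datasets}
    hvgs: dict[str, HvgSet] = {}
    for d in datasets:
        if hvg_sets and d.name in hvg_sets:
            hvgs[d.name] = hvg_sets[d.name]
        else:
            hvgs[d.name] = _dataset_hvg(d, norms[d.name])

    ref_hvg = list(hvgs[reference])
    smoothed: dict[str, NormalizedMatrix] = {}
    for d in datasets:
        nm = norms[d.name].restrict_genes(list(hvgs[d.name]))
        params = _smooth_params_for(d.modality, smoothing, nm.n_cells)
        vals = (
            smooth_within_modality(nm.values, params)
            if nm.n_cells > params.k
            else _fill_nan_colmean(nm.values)
        )
        smoothed[d.name] = NormalizedMatrix(
            values=vals,
            transform=nm.transform,
            modality=nm.modality,
            gene_ids=nm.gene_ids,
            cell_ids=nm.cell_ids,
            scale_factors=nm.scale_factors,
            n_detected_genes=norms[d.name].n_detected_genes,
        )

    ref_sm = smoothed[reference].restrict_genes(ref_hvg)
    blocks, frames, lg = [], [], []
    for d in datasets:
        sm = smoothed[d.name]
        if d.name == reference:
            block = ref_sm.values
        else:
            shared = [g for g in ref_hvg if g in set(sm.gene_ids)]
            if len(shared) < 10:
                shared = [g for g in ref_hvg if g in set(norms[d.name].gene_ids)]
                donor = norms[d.name]
            else:
                donor = sm
            block = impute_cross_modality(
                ref_sm, donor, shared, imputation, flip=d.modality == "mc"
            )
        blocks.append(block)
        frames.append(pd.DataFrame({"dataset": d.name, "cell_id": sm.cell_ids}))
        ng = norms[d.name].n_detected_genes
        lg.append(np.log2(np.maximum(ng, 1)) if ng is not None else np.zeros(sm.n_cells))
    stacked = np.vstack(blocks)
    pcs = joint_reduce(stacked, n_pcs=n_pcs, ngene_corr_max=ngene_corr_max,
                       log2_ngenes=np.concatenate(lg))
    return pcs, pd.concat(frames, ignore_index=True)


def iterative_fusion(
    datasets: list[OmicsDataset],
    reference: str,
    rounds: int = 3,
    resolution: float = 0.1,
    k: int = 30,
    min_cells_split: int = 50,
    seed: int = 0,
    smoothing: SmoothingParams | None = None,
    imputation: ImputationParams | None = None,
) -> ClusterAssignment:
    """Iterative multi-round integration producing nested cluster levels.

    Round one integrates all cells (level L0); each subsequent round
    re-runs the full pipeline (HVG re-selection, smoothing, imputation,
    clustering) within every cluster large enough to split, refining labels
    while preserving nesting.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    pcs, frame = fuse_datasets(datasets, reference, smoothing, imputation)
    base = leiden_cluster(pcs, k=k, resolution=resolution, seed=seed)
    frame["L0"] = [str(c) for c in base]

    by_name = {d.name: d for d in datasets}
    for level in range(1, rounds):
        prev, cur = f"L{level - 1}", f"L{level}"
        frame[cur] = frame[prev]
        for label in sorted(frame[prev].unique()):
            mask = (frame[prev] == label).to_numpy()
            if mask.sum() < min_cells_split:
                continue
            sub_datasets = []
            for name, d in by_name.items():
                ids = frame.loc[mask & (frame["dataset"] == name).to_numpy(), "cell_id"]
                if len(ids) == 0:
                    continue
                pos = d.cells.index.get_indexer(ids)
                sub_datasets.append(d.subset_cells(pos))
            names = [d.name for d in sub_datasets]
            if reference not in names or min(d.n_cells for d in sub_datasets) < 2:
                continue
            try:
                sub_pcs, sub_frame = fuse_datasets(
                    sub_datasets, reference, smoothing, imputation
                )
                sub_labels = leiden_cluster(
                    sub_pcs, k=min(k, sub_pcs.shape[0] - 1),
                    resolution=resolution, seed=seed + level,
                )
            except (ValueError, KeyError) as err:
                warnings.warn(f"cluster {label} left unsplit at {cur}: {err}")
                continue
            sub_frame["sub"] = [f"{label}.{c}" for c in sub_labels]
            key = pd.MultiIndex.from_frame(sub_frame[["dataset", "cell_id"]])
            lookup = pd.Series(sub_frame["sub"].to_numpy(), index=key)
            rows = frame.index[mask]
            row_key = pd.MultiIndex.from_frame(frame.loc[rows, ["dataset", "cell_id"]])
            frame.loc[rows, cur] = lookup.reindex(row_key).to_numpy()
    return ClusterAssignment(
        cells=frame,
        method="iterative_fusion",
        params={
            "reference": reference,
            "rounds": rounds,
            "resolution": resolution,
            "k": k,
            "min_cells_split": min_cells_split,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# anchor / Jaccard consensus backend
# ---------------------------------------------------------------------------

def select_anchors(labels: np.ndarray, seed: int = 0, budget: int = 5000,
                   floor: int = 100) -> np.ndarray:
    """Per-cluster uniform anchor sample, capped at max(floor, budget/k)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    clusters = np.unique(labels)
    cap = max(floor, int(np.ceil(budget / len(clusters))))
    chosen: list[np.ndarray] = []
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if members.size <= cap:
            chosen.append(members)
        else:
            chosen.append(np.sort(rng.choice(members, size=cap, replace=False)))
    return np.concatenate(chosen)


def _knn_among(
    query: np.ndarray, anchors: np.ndarray, k: int, metric: str
) -> np.ndarray:
    """k nearest anchors per query row (euclidean) or top-k by correlation."""
    if k > anchors.shape[0]:
        raise ValueError("k exceeds the number of anchor cells")
    if metric == "euclidean":
        nn = NearestNeighbors(n_neighbors=k).fit(anchors)
        _, idx = nn.kneighbors(query)
        return idx
    qc = query - query.mean(axis=1, keepdims=True)
    ac = anchors - anchors.mean(axis=1, keepdims=True)
    qn = np.sqrt((qc**2).sum(axis=1, keepdims=True))
    an = np.sqrt((ac**2).sum(axis=1, keepdims=True))
    qn[qn == 0] = 1.0
    an[an == 0] = 1.0
    corr = (qc / qn) @ (ac / an).T
    return np.argsort(-corr, axis=1, kind="stable")[:, :k]


def jaccard_graph(
    features: dict[str, np.ndarray],
    anchors: dict[str, np.ndarray],
    k: int = 15,
) -> tuple[ig.Graph, pd.DataFrame, sp.csr_matrix]:
    """Shared-nearest-anchor Jaccard graph over cells of all datasets.

    ``features`` maps dataset name to its cells x shared-HVG matrix;
    ``anchors`` maps reference dataset names to local anchor indices.  Each
    cell's kNN (k per reference dataset) is found with Euclidean distance
    within its own dataset and correlation similarity across datasets; edge
    weights are |shared kNN| / |combined kNN| (zero edges omitted).
    """
    names = list(features)
    offsets, total = {}, 0
    for n in names:
        offsets[n] = total
        total += features[n].shape[0]
    anchor_cols: dict[str, tuple[int, int]] = {}
    n_anchor_total = 0
    for r in anchors:
        anchor_cols[r] = (n_anchor_total, n_anchor_total + len(anchors[r]))
        n_anchor_total += len(anchors[r])

    rows, cols = [], []
    for d in names:
        x = features[d]
        for r, a_idx in anchors.items():
            a = features[r][a_idx]
            metric = "euclidean" if d == r else "correlation"
            idx = _knn_among(x, a, k, metric)
            base = anchor_cols[r][0]
            rows.append(np.repeat(np.arange(x.shape[0]) + offsets[d], k))
            cols.append(idx.ravel() + base)
    b = sp.csr_matrix(
        (np.ones(sum(r.size for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(total, n_anchor_total),
    )
    b.data[:] = 1.0
    inter = (b @ b.T).tocoo()
    sizes = np.asarray(b.sum(axis=1)).ravel()
    mask = inter.row < inter.col
    ri, ci, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    union = sizes[ri] + sizes[ci] - shared
    w = shared / union
    keep = w > 0
    g = ig.Graph(
        n=total,
        edges=list(zip(ri[keep].tolist(), ci[keep].tolist())),
        directed=False,
    )
    g.es["weight"] = w[keep].tolist()
    frame = pd.concat(
        [pd.DataFrame({"dataset": n, "local_idx": np.arange(features[n].shape[0])}) for n in names],
        ignore_index=True,
    )
    return g, frame, b


def louvain_cluster(graph: ig.Graph, seed: int = 0) -> np.ndarray:
    """Seeded Louvain community detection on a weighted graph."""
    ig.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(weights="weight" if "weight" in graph.es.attributes() else None)
    ig.set_random_number_generator(random)
    return np.asarray(part.membership, dtype=int)


def impute_knn_anchor(neighbors: np.ndarray, anchor_features: np.ndarray) -> np.ndarray:
    """Mean of each cell's anchor-neighbor rows in the reference feature
    space; rows with no valid neighbor (index < 0) are returned as NaN."""
    neighbors = np.asarray(neighbors)
    out = np.full((neighbors.shape[0], anchor_features.shape[1]), np.nan)
    for i, nb in enumerate(neighbors):
        nb = nb[nb >= 0]
        if nb.size:
            out[i] = anchor_features[nb].mean(axis=0)
    return out
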