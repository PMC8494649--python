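"""Cluster-resolution validation: downsampling curves, within-dataset
cross-validation with chromosome-split features, and cross-dataset
cross-validation through joint clustering.

The central idea: cluster cells using one half of the gene features (split
by chromosome so linked genes never straddle the split), then score how well
cluster centroids learned from training cells predict the *other* half of
the features for held-out test cells.  Plotted against the number of
clusters, the test mean squared error traces a U-shaped curve whose minimum
(and minimum + 1 s.e.m. band) estimates the supportable cluster resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .fusion import (
    ImputationParams,
    SmoothingParams,
    _fill_nan_colmean,
    fuse_datasets,
    joint_reduce,
    leiden_cluster,
)
from .qcnorm import NormalizedMatrix, select_hvg_count
from .synth import OmicsDataset

#: default resolution sweep: geometric grid spanning under- to over-clustering,
#: anchored by the single-cluster baseline (resolution 0 denotes one cluster)
DEFAULT_RESOLUTIONS: tuple[float, ...] = (0.0,) + tuple(
    float(r) for r in np.geomspace(0.05, 20.0, 12)
)


@dataclass
class FeatureSplit:
    clustering_genes: list[str]
    validation_genes: list[str]
    chromosomes_a: list[str]
    chromosomes_b: list[str]

    def __post_init__(self) -> None:
        if set(self.clustering_genes) & set(self.validation_genes):
            raise ValueError("feature sets must be disjoint")


@dataclass
class CvCurve:
    """Per-resolution cluster counts and train/test MSE summaries."""

    table: pd.DataFrame  # resolution, n_clusters, mse_test, sem_test, mse_train, sem_train
    provenance: dict = field(default_factory=dict)

    def optimal(self) -> tuple[float, list[float]]:
        return optimal_resolution(self)


def split_features_by_chromosome(genes: pd.DataFrame, seed: int = 0) -> FeatureSplit:
    """Randomly partition chromosomes into two sets balanced by gene count.

    Chromosomes are visited in a random order and greedily assigned to the
    currently lighter side, so genes from the same chromosome always end up
    on the same side of the split.
    """
    chroms = genes["chromosome"].to_numpy()
    uniq = np.unique(chroms)
    if uniq.size < 2:
        raise ValueError("need at least 2 chromosomes to split features")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    counts = pd.Series(chroms).value_counts()
    side_a: list[str] = []
    side_b: list[str] = []
    wa = wb = 0
    for c in order:
        if wa <= wb:
            side_a.append(c)
            wa += int(counts[c])
        else:
            side_b.append(c)
            wb += int(counts[c])
    in_a = np.isin(chroms, side_a)
    return FeatureSplit(
        clustering_genes=list(genes.index[in_a]),
        validation_genes=list(genes.index[~in_a]),
        chromosomes_a=sorted(side_a),
        chromosomes_b=sorted(side_b),
    )


def centroid_mse(
    labels: np.ndarray,
    validation: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[float, float]:
    """MSE of predicting held-out features as the training-cell centroid.

    Clusters with no training cell score their test cells against the global
    training centroid.  Returns (mse_train, mse_test), averaged over cells
    and genes.
    """
    labels = np.asarray(labels)
    v = _fill_nan_colmean(np.asarray(validation, dtype=float))
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if test_idx.size == 0:
        raise ValueError("empty test set")
    global_centroid = v[train_idx].mean(axis=0)
    centroids: dict = {}
    for c in np.unique(labels):
        tr = train_idx[labels[train_idx] == c]
        centroids[c] = v[tr].mean(axis=0) if tr.size else global_centroid

    def _mse(idx: np.ndarray) -> float:
        err = 0.0
        for c in np.unique(labels[idx]):
            m = idx[labels[idx] == c]
            err += ((v[m] - centroids[c]) ** 2).sum()
        return err / (idx.size * v.shape[1])

    return _mse(train_idx), _mse(test_idx)


def _cluster_pipeline(
    norm: NormalizedMatrix,
    resolutions,
    seed: int,
    n_pcs: int = 50,
    k: int = 30,
    ngene_corr_max: float = 0.7,
) -> dict[float, np.ndarray]:
    """HVG -> PCA -> kNN -> Leiden at each resolution (graph built once).

    Principal components tracking log2(detected genes) above
    ``ngene_corr_max`` are removed so per-cell depth does not masquerade as
    cluster structure.
    """
    try:
        hvg = select_hvg_count(norm)
        vals = norm.restrict_genes(list(hvg)).values
    except ValueError:
        vals = norm.values
    lg = None
    if norm.n_detected_genes is not None:
        lg = np.log2(np.maximum(np.asarray(norm.n_detected_genes, dtype=float), 1.0))
    pcs = joint_reduce(_fill_nan_colmean(vals), n_pcs=n_pcs,
                       ngene_corr_max=ngene_corr_max, log2_ngenes=lg)
    out: dict[float, np.ndarray] = {}
    for r in resolutions:
        if float(r) == 0.0:  # single-cluster baseline
            out[0.0] = np.zeros(pcs.shape[0], dtype=int)
        else:
            out[float(r)] = leiden_cluster(
                pcs, k=min(k, pcs.shape[0] - 1), resolution=float(r), seed=seed
            )
    return out


def _aggregate_curve(records: list[dict], provenance: dict) -> CvCurve:
    df = pd.DataFrame(records)
    rows = []
    for r, grp in df.groupby("resolution"):
        rows.append(
            {
                "resolution": r,
                "n_clusters": grp["n_clusters"].mean(),
                "mse_test": grp["mse_test"].mean(),
                "sem_test": grp["mse_test"].sem(ddof=1) if len(grp) > 1 else 0.0,
                "mse_train": grp["mse_train"].mean(),
                "sem_train": grp["mse_train"].sem(ddof=1) if len(grp) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).sort_values("resolution").reset_index(drop=True)
    return CvCurve(table=table, provenance=provenance)


def within_dataset_cv(
    norm: NormalizedMatrix,
    genes: pd.DataFrame,
    resolutions=DEFAULT_RESOLUTIONS,
    n_feature_splits: int = 5,
    n_cell_folds: int = 5,
    seed: int = 0,
    n_pcs: int = 50,
    k: int = 30,
) -> CvCurve:
    """Within-dataset cluster-resolution cross-validation.

    For each chromosome-balanced feature split, cells are clustered on the
    clustering genes at every resolution and scored by k-fold centroid MSE
    on the validation genes.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for s in range(n_feature_splits):
        split = split_features_by_chromosome(genes, seed=int(rng.integers(2**31 - 1)))
        clust_norm = norm.restrict_genes(split.clustering_genes)
        val_matrix = norm.restrict_genes(split.validation_genes).values
        labels_by_res = _cluster_pipeline(
            clust_norm, resolutions, seed=seed + s, n_pcs=n_pcs, k=k
        )
        kf = KFold(n_splits=n_cell_folds, shuffle=True, random_state=seed + s)
        folds = list(kf.split(np.arange(norm.n_cells)))
        for r, labels in labels_by_res.items():
            for train_idx, test_idx in folds:
                mtr, mte = centroid_mse(labels, val_matrix, train_idx, test_idx)
                records.append(
                    {
                        "resolution": r,
                        "n_clusters": len(np.unique(labels)),
                        "mse_train": mtr,
                        "mse_test": mte,
                    }
                )
    return _aggregate_curve(
        records,
        {
            "n_feature_splits": n_feature_splits,
            "n_cell_folds": n_cell_folds,
            "seed": seed,
            "mode": "within_dataset",
        },
    )


def optimal_resolution(curve: CvCurve) -> tuple[float, list[float]]:
    """(cluster count at minimum test MSE, cluster counts within min+1SE).

    Ties at the minimum report the smallest cluster count; the one-standard-
    error band uses the s.e.m. at the minimum.
    """
    t = curve.table
    if t.empty:
        raise ValueError("empty curve")
    min_mse = t["mse_test"].min()
    at_min = t[t["mse_test"] == min_mse]
    k_at_min = float(at_min["n_clusters"].min())
    sem = float(at_min.loc[at_min["n_clusters"].idxmin(), "sem_test"])
    band = t[t["mse_test"] <= min_mse + sem]["n_clusters"].tolist()
    return k_at_min, [float(b) for b in band]


def downsample_cluster_curve(
    norm: NormalizedMatrix,
    fractions,
    resolution: float = 6.0,
    k: int = 30,
    n_reps: int = 10,
    seed: int = 0,
    n_pcs: int = 50,
) -> pd.DataFrame:
    """Cluster count versus number of sampled cells at fixed resolution.

    Returns a frame with (fraction, n_cells, mean_clusters, sem_clusters).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        n_sub = int(round(frac * norm.n_cells))
        if n_sub < k + 2:
            warnings.warn(f"fraction {frac} leaves too few cells; skipped")
            continue
        counts = []
        for _ in range(n_reps):
            idx = np.sort(rng.choice(norm.n_cells, size=n_sub, replace=False))
            sub = norm.subset_cells(idx)
            labels = _cluster_pipeline(sub, [resolution], seed=seed, n_pcs=n_pcs, k=k)[
                float(resolution)
            ]
            counts.append(len(np.unique(labels)))
        counts = np.array(counts, dtype=float)
        rows.append(
            {
                "fraction": frac,
                "n_cells": n_sub,
                "mean_clusters": counts.mean(),
                "sem_clusters": counts.std(ddof=1) / np.sqrt(len(counts)) if len(counts) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cross_dataset_cv(
    datasets: list[OmicsDataset],
    reference: str,
    resolutions=DEFAULT_RESOLUTIONS,
    n_feature_splits: int = 3,
    n_cell_folds: int = 5,
    seed: int = 0,
    k: int = 30,
    smoothing: SmoothingParams | None = None,
    imputation: ImputationParams | None = None,
) -> dict[str, CvCurve]:
    """Cross-dataset cross-validation through joint clustering.

    Joint labels come from one integration pass run on the clustering half
    of the features; each dataset is then scored by centroid-MSE
    cross-validation on its own validation features.  Returns one curve per
    dataset.
    """
    from .qcnorm import normalize  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    genes = datasets[0].genes
    norms_full = {d.name: normalize(d) for d in datasets}
    records: dict[str, list[dict]] = {d.name: [] for d in datasets}
    for s in range(n_feature_splits):
        split = split_features_by_chromosome(genes, seed=int(rng.integers(2**31 - 1)))
        sub = [d.subset_genes(split.clustering_genes) for d in datasets]
        pcs, frame = fuse_datasets(sub, reference, smoothing, imputation)
        for r in resolutions:
            if float(r) == 0.0:  # single-cluster baseline
                joint = np.zeros(pcs.shape[0], dtype=int)
            else:
                joint = leiden_cluster(pcs, k=min(k, pcs.shape[0] - 1),
                                       resolution=float(r), seed=seed + s)
            for d in datasets:
                mask = (frame["dataset"] == d.name).to_numpy()
                labels = joint[mask]
                ids = frame.loc[mask, "cell_id"]
                nf = norms_full[d.name]
                pos = nf.cell_ids.get_indexer(ids)
                val = nf.restrict_genes(
                    [g for g in split.validation_genes if g in set(nf.gene_ids)]
                ).values[pos]
                kf = KFold(n_splits=n_cell_folds, shuffle=True, random_state=seed + s)
                for train_idx, test_idx in kf.split(np.arange(val.shape[0])):
                    mtr, mte = centroid_mse(labels, val, train_idx, test_idx)
                    records[d.name].append(
                        {
                            "resolution": float(r),
                            "n_clusters": len(np.unique(joint)),
                            "mse_train": mtr,
                            "mse_test": mte,
                        }
                    )
    prov = {
        "n_feature_splits": n_feature_splits,
        "n_cell_folds": n_cell_folds,
        "seed": seed,
        "mode": "cross_dataset",
        "reference": reference,
    }
    return {name: _aggregate_curve(recs, prov) for name, recs in records.items()}
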