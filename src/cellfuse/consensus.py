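"""Conserved differential expression, cluster merging, marker selection and
the marker-centroid taxonomy dendrogram.

Differential expression between two clusters is tested per dataset with a
two-sided Wilcoxon rank-sum test and Benjamini-Hochberg correction; fold
changes are computed on linearized means with a pseudocount.  A gene is a
*conserved* DE gene when it is significant in at least one dataset while
showing a greater-than-twofold change in the same direction in nearly all
datasets ("all but one" for the merge step, a 70%-of-datasets variant for
marker selection).  Clusters that the conserved-DE evidence cannot separate
are merged iteratively to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .qcnorm import NormalizedMatrix


@dataclass
class MergePolicy:
    fold_change_min: float = 2.0
    fdr_max: float = 0.01
    #: platform -> minimum cells per cluster for that dataset to contribute
    min_cells: dict = field(default_factory=lambda: {"smart": 4, "10x": 10})
    min_cells_default: int = 10
    de_score_threshold: float = 100.0
    de_score_cap: float = 20.0  # per-gene -log10(FDR) cap
    n_candidate_neighbors: int = 3
    conserved_rule: str = "all_but_one"  # or "fraction"
    conserved_fraction: float = 0.7
    pseudocount: float = 1.0

    def min_cells_for(self, platform: str) -> int:
        for key, v in self.min_cells.items():
            if platform.lower().startswith(key):
                return v
        return self.min_cells_default


@dataclass
class DeResult:
    """Per-dataset, per-gene statistics for one cluster pair."""

    cluster_a: str
    cluster_b: str
    tables: dict  # dataset -> DataFrame(gene, lfc, fdr)
    skipped: list = field(default_factory=list)


def _linear_mean(vals: np.ndarray, transform: str) -> np.ndarray:
    """Mean on the linear scale of the recorded transform."""
    if transform.startswith("log10"):
        return np.nanmean(10.0 ** vals - 1.0, axis=0)
    return np.nanmean(vals, axis=0)  # mch_ratio values are already linear


def pairwise_de(
    norms: dict[str, NormalizedMatrix],
    labels: dict[str, np.ndarray],
    cluster_a: str,
    cluster_b: str,
    policy: MergePolicy | None = None,
    platforms: Optional[dict[str, str]] = None,
) -> DeResult:
    """Per-gene rank-sum DE between two clusters, tested in each dataset.

    A dataset contributes only when both clusters have at least the
    platform-specific minimum number of cells in it.
    """
    policy = policy or MergePolicy()
    platforms = platforms or {}
    tables: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for name, norm in norms.items():
        lab = np.asarray(labels[name])
        ia = np.flatnonzero(lab == cluster_a)
        ib = np.flatnonzero(lab == cluster_b)
        min_cells = policy.min_cells_for(platforms.get(name, "10x"))
        if ia.size < min_cells or ib.size < min_cells:
            skipped.append(name)
            continue
        xa, xb = norm.values[ia], norm.values[ib]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
            pvals = np.asarray(stat.pvalue, dtype=float)
        pvals = np.nan_to_num(pvals, nan=1.0)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        pc = policy.pseudocount if norm.transform.startswith("log10") else 0.05
        lfc = np.log2(
            (_linear_mean(xa, norm.transform) + pc)
            / (_linear_mean(xb, norm.transform) + pc)
        )
        if norm.modality == "mc":
            # methylation depletion marks expression: align direction with
            # the expression datasets
            lfc = -lfc
        tables[name] = pd.DataFrame(
            {"lfc": lfc, "fdr": fdr}, index=pd.Index(norm.gene_ids, name="gene")
        )
    if not tables:
        raise ValueError(f"no dataset has enough cells for {cluster_a} vs {cluster_b}")
    return DeResult(cluster_a=cluster_a, cluster_b=cluster_b, tables=tables, skipped=skipped)


def conserved_de_genes(de: DeResult, policy: MergePolicy | None = None) -> pd.DataFrame:
    """Genes conserved across datasets, split by direction.

    Returns a frame indexed by gene with columns ``direction`` ("up" means
    higher in cluster_a) and ``score`` (summed capped -log10 FDR across
    datasets, the per-gene contribution to the separation score).
    """
    policy = policy or MergePolicy()
    names = list(de.tables)
    n = len(names)
    genes = de.tables[names[0]].index
    lfc = np.column_stack([de.tables[d]["lfc"].to_numpy() for d in names])
    fdr = np.column_stack([de.tables[d]["fdr"].to_numpy() for d in names])
    thr = np.log2(policy.fold_change_min)
    sig = (fdr < policy.fdr_max) & (np.abs(lfc) > thr)
    if policy.conserved_rule == "all_but_one":
        need = max(1, n - 1)
    else:
        need = max(1, int(np.ceil(policy.conserved_fraction * n)))
    up_fold = (lfc > thr).sum(axis=1)
    dn_fold = (lfc < -thr).sum(axis=1)
    any_sig_up = (sig & (lfc > 0)).any(axis=1)
    any_sig_dn = (sig & (lfc < 0)).any(axis=1)
    # direction consistency: no dataset may show a strong opposite fold change
    up_ok = any_sig_up & (up_fold >= need) & (dn_fold == 0)
    dn_ok = any_sig_dn & (dn_fold >= need) & (up_fold == 0)
    contrib = np.minimum(-np.log10(np.maximum(fdr, 1e-300)), policy.de_score_cap)
    rows = []
    for mask, direction in ((up_ok, "up"), (dn_ok, "down")):
        for gi in np.flatnonzero(mask):
            rows.append((genes[gi], direction, contrib[gi].sum()))
    out = pd.DataFrame(rows, columns=["gene", "direction", "score"]).set_index("gene")
    return out


def de_scores(de: DeResult, conserved: pd.DataFrame, policy: MergePolicy | None = None) -> dict[str, float]:
    """Per-dataset separation score: sum over conserved DE genes of the
    capped -log10(FDR)."""
    policy = policy or MergePolicy()
    out: dict[str, float] = {}
    for name, tab in de.tables.items():
        if conserved.empty:
            out[name] = 0.0
            continue
        f = tab.loc[conserved.index, "fdr"].to_numpy()
        out[name] = float(np.minimum(-np.log10(np.maximum(f, 1e-300)), policy.de_score_cap).sum())
    return out


def _pair_separation(
    norms, labels, a, b, policy, platforms
) -> tuple[float, bool]:
    """(max per-dataset de_score, separable flag) for a cluster pair."""
    try:
        de = pairwise_de(norms, labels, a, b, policy, platforms)
    except ValueError:
        return 0.0, False
    conserved = conserved_de_genes(de, policy)
    scores = de_scores(de, conserved, policy)
    best = max(scores.values()) if scores else 0.0
    return best, best > policy.de_score_threshold


def _centroids(norms: dict[str, NormalizedMatrix], labels: dict[str, np.ndarray]) -> pd.DataFrame:
    """Cluster centroids: per-dataset means averaged over datasets."""
    clusters = sorted(set().union(*(set(np.asarray(l)) for l in labels.values())))
    mats = []
    for name, norm in norms.items():
        lab = np.asarray(labels[name])
        rows = {}
        for c in clusters:
            m = lab == c
            if m.any():
                rows[c] = np.nan_to_num(np.nanmean(norm.values[m], axis=0))
        mats.append(pd.DataFrame.from_dict(rows, orient="index"))
    stacked = pd.concat(mats)
    return stacked.groupby(stacked.index).mean()


def merge_clusters(
    labels: dict[str, np.ndarray],
    norms: dict[str, NormalizedMatrix],
    policy: MergePolicy | None = None,
    platforms: Optional[dict[str, str]] = None,
) -> dict[str, np.ndarray]:
    """Merge cluster pairs that conserved DE evidence cannot separate.

    Each iteration finds, for every cluster, its three nearest clusters by
    centroid correlation, tests those pairs, and merges the unseparable pair
    with the smallest separation score; repeats to a fixed point.
    """
    policy = policy or MergePolicy()
    labels = {k: np.asarray(v, dtype=object).astype(str) for k, v in labels.items()}
    n_start = len(set().union(*(set(l) for l in labels.values())))
    for _ in range(n_start):
        cents = _centroids(norms, labels)
        clusters = list(cents.index)
        if len(clusters) < 2:
            break
        x = cents.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        nrm = np.sqrt((xc**2).sum(axis=1, keepdims=True))
        nrm[nrm == 0] = 1.0
        corr = (xc / nrm) @ (xc / nrm).T
        np.fill_diagonal(corr, -np.inf)
        pairs = set()
        for i, c in enumerate(clusters):
            top = np.argsort(-corr[i], kind="stable")[: policy.n_candidate_neighbors]
            for j in top:
                if np.isfinite(corr[i, j]):
                    pairs.add(tuple(sorted((c, clusters[int(j)]))))
        failing = []
        for a, b in sorted(pairs):
            score, separable = _pair_separation(norms, labels, a, b, policy, platforms)
            if not separable:
                failing.append((score, a, b))
        if not failing:
            break
        _, a, b = min(failing)
        for name in labels:
            labels[name] = np.where(labels[name] == b, a, labels[name])
    return labels


def select_markers(
    labels: dict[str, np.ndarray],
    norms: dict[str, NormalizedMatrix],
    top_n: int = 50,
    policy: MergePolicy | None = None,
    platforms: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Top conserved DE genes per direction for every cluster pair, pooled.

    Uses the 70%-of-datasets conservation rule; genes are ranked by their
    summed capped -log10(FDR) contribution.  Returns a frame with columns
    (gene, pair, direction, score); the pooled marker set is the unique
    gene column.
    """
    base = policy or MergePolicy()
    policy = MergePolicy(**{**base.__dict__, "conserved_rule": "fraction"})
    clusters = sorted(set().union(*(set(np.asarray(l).astype(str)) for l in labels.values())))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    labels = {k: np.asarray(v).astype(str) for k, v in labels.items()}
    rows = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            try:
                de = pairwise_de(norms, labels, a, b, policy, platforms)
            except ValueError:
                continue
            conserved = conserved_de_genes(de, policy)
            for direction in ("up", "down"):
                sub = conserved[conserved["direction"] == direction]
                sub = sub.sort_values("score", ascending=False, kind="stable")
                for gene, r in sub.head(top_n).iterrows():
                    rows.append((gene, f"{a}|{b}", direction, r["score"]))
    return pd.DataFrame(rows, columns=["gene", "pair", "direction", "score"])


def build_taxonomy_tree(centroids: pd.DataFrame):
    """Average-linkage, correlation-distance dendrogram over cluster
    centroids (rows = clusters, columns = marker features, possibly
    concatenated across reference datasets).

    Returns (linkage_matrix, leaf_labels, newick_string).
    """
    if len(centroids) < 2:
        raise ValueError("need at least 2 clusters")
    order = centroids.index.argsort(kind="stable")
    cent = centroids.iloc[order]
    z = linkage(cent.to_numpy(), method="average", metric="correlation")
    labels = list(cent.index.astype(str))

    def _newick(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _newick(node.get_left(), node.dist)
        right = _newick(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    tree = to_tree(z)
    left = _newick(tree.get_left(), tree.dist)
    right = _newick(tree.get_right(), tree.dist)
    newick = f"({left},{right});"
    return z, labels, newick
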