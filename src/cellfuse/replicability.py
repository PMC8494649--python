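"""Cluster replicability across datasets by fast neighbor voting.

Given two datasets with their own cluster labels and a shared set of highly
variable genes, each training cluster casts votes on test cells: a test
cell's vote is its mean Spearman similarity to the training cluster's cells
(fast mode: no rank standardization of the similarity network, no node
degree normalization).  The AUROC that members of a test cluster outrank
non-members under these votes measures how replicable the pair of clusters
is.  One-vs-all AUROCs are sharpened into one-vs-best scores (best match
versus runner-up only), reciprocal best hits above a threshold define
meta-clusters, and a Jensen-Shannon divergence quantifies cross-platform
expression differences within cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from .fusion import _rank_rows
from .qcnorm import normalize, select_hvg_count, select_hvg_mc
from .synth import OmicsDataset


@dataclass
class AurocMatrix:
    """train_cluster x test_cluster replicability scores."""

    values: pd.DataFrame  # rows: train clusters, columns: test clusters
    convention: str  # one_vs_all | one_vs_best
    train_dataset: str = ""
    test_dataset: str = ""
    low_confidence: list = field(default_factory=list)  # single-cell clusters


@dataclass
class VoteResult:
    """Neighbor-voting scores retained for one-vs-best recomputation."""

    votes: pd.DataFrame  # rows: test cells, columns: train clusters
    test_labels: np.ndarray
    train_sizes: pd.Series
    auroc: AurocMatrix


@dataclass
class MetaClusterSet:
    components: list[set]  # sets of "dataset|cluster" node names
    threshold: float
    mean_auroc: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shared HVGs
# ---------------------------------------------------------------------------

def shared_hvg(
    datasets: list[OmicsDataset], max_cells_per_dataset: int = 50_000, seed: int = 0
) -> list[str]:
    """Genes detected as highly variable in every dataset (ordered by the
    first dataset's gene order)."""
    rng = np.random.default_rng(seed)
    sets = []
    for d in datasets:
        if d.n_cells > max_cells_per_dataset:
            idx = np.sort(rng.choice(d.n_cells, size=max_cells_per_dataset, replace=False))
            d = d.subset_cells(idx)
        if d.modality == "mc":
            sets.append(set(select_hvg_mc(d)))
        else:
            sets.append(set(select_hvg_count(normalize(d))))
    common = set.intersection(*sets)
    if not common:
        raise ValueError(
            "no gene is highly variable in all datasets; relax the per-dataset selection"
        )
    return [g for g in datasets[0].genes.index if g in common]


# ---------------------------------------------------------------------------
# neighbor voting
# ---------------------------------------------------------------------------

def _auroc_from_scores(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUROC with midrank ties: P(member outranks non-member)."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def neighbor_vote_auroc(
    train_values: np.ndarray,
    train_labels,
    test_values: np.ndarray,
    test_labels,
    train_dataset: str = "train",
    test_dataset: str = "test",
    flip: bool = False,
) -> VoteResult:
    """One-vs-all neighbor-voting AUROC between two labeled datasets.

    Both value matrices must already be restricted to the shared gene set
    (cells x genes).  Similarity is the Spearman correlation across genes;
    the vote of a test cell for a training cluster is its mean similarity to
    that cluster's cells.  ``flip`` negates the similarity, for comparing a
    methylation dataset against an expression/accessibility dataset whose
    signals anti-correlate.
    """
    train_labels = np.asarray(train_labels).astype(str)
    test_labels = np.asarray(test_labels).astype(str)
    q = _rank_rows(np.asarray(test_values, dtype=float))
    r = _rank_rows(np.asarray(train_values, dtype=float))
    sim = q @ r.T  # test cells x train cells
    if flip:
        sim = -sim
    clusters = np.unique(train_labels)
    votes = np.column_stack([sim[:, train_labels == c].mean(axis=1) for c in clusters])
    votes_df = pd.DataFrame(votes, columns=clusters)
    test_clusters = np.unique(test_labels)
    auroc = pd.DataFrame(index=clusters, columns=test_clusters, dtype=float)
    low_conf = []
    for t in test_clusters:
        pos = test_labels == t
        if pos.sum() == 1:
            low_conf.append(t)
        for c in clusters:
            auroc.loc[c, t] = _auroc_from_scores(votes_df[c].to_numpy(), pos)
    sizes = pd.Series({c: int((train_labels == c).sum()) for c in clusters})
    return VoteResult(
        votes=votes_df,
        test_labels=test_labels,
        train_sizes=sizes,
        auroc=AurocMatrix(
            values=auroc,
            convention="one_vs_all",
            train_dataset=train_dataset,
            test_dataset=test_dataset,
            low_confidence=low_conf,
        ),
    )


def one_vs_best(vote: VoteResult) -> AurocMatrix:
    """Sharpen a one-vs-all AUROC matrix into the one-vs-best convention.

    For each test cluster the two best-matching training clusters are
    selected by one-vs-all AUROC (ties resolved toward the larger training
    cluster, then lexicographically).  The vote matrix is then restricted to
    those two candidate columns and the candidates contest the test
    cluster's cells directly: ``a`` is the probability that a random member
    cell votes higher for the winning candidate than for the runner-up
    (ties counted half).  The best entry holds ``a``, the runner-up 1 - a,
    all others 0, so per test cluster the two entries sum to one and only
    the best match can exceed 0.5.  With a single training cluster the
    score is undefined (NaN).
    """
    ova = vote.auroc.values
    out = pd.DataFrame(0.0, index=ova.index, columns=ova.columns)
    for t in ova.columns:
        col = ova[t]
        if len(col) < 2:
            out[t] = np.nan
            continue
        order = sorted(
            col.index,
            key=lambda c: (-col[c], -vote.train_sizes.get(c, 0), c),
        )
        c1, c2 = order[0], order[1]
        members = vote.test_labels == t
        d = vote.votes.loc[members, c1].to_numpy() - vote.votes.loc[members, c2].to_numpy()
        a = float((d > 0).mean() + 0.5 * (d == 0).mean())
        if a < 0.5:  # the contest, not the one-vs-all ranking, names the best
            c1, c2, a = c2, c1, 1.0 - a
        out.loc[c1, t] = a
        out.loc[c2, t] = 1.0 - a
    return AurocMatrix(
        values=out,
        convention="one_vs_best",
        train_dataset=vote.auroc.train_dataset,
        test_dataset=vote.auroc.test_dataset,
        low_confidence=vote.auroc.low_confidence,
    )


def meta_clusters(
    ovb_matrices: dict[tuple[str, str], AurocMatrix],
    threshold: float = 0.7,
    cluster_sizes: dict[str, dict[str, int]] | None = None,
) -> MetaClusterSet:
    """Connected components of reciprocal best hits above a threshold.

    ``ovb_matrices`` maps (train_dataset, test_dataset) pairs to one-vs-best
    matrices.  An undirected edge joins cluster A@D1 and B@D2 when each is
    the other's best hit with both restricted AUROCs above the threshold.
    """
    best_hit: dict[tuple[str, str, str], tuple[str, float]] = {}
    nodes = set()
    for (train_ds, test_ds), mat in ovb_matrices.items():
        vals = mat.values
        for t in vals.columns:
            nodes.add(f"{test_ds}|{t}")
            col = vals[t].astype(float)
            if col.isna().all():
                continue
            sizes = (cluster_sizes or {}).get(train_ds, {})
            order = sorted(
                col.index, key=lambda c: (-col[c], -sizes.get(c, 0), c)
            )
            c = order[0]
            best_hit[(test_ds, t, train_ds)] = (c, float(col[c]))
        for c in vals.index:
            nodes.add(f"{train_ds}|{c}")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (test_ds, t, train_ds), (c, a) in best_hit.items():
        back = best_hit.get((train_ds, c, test_ds))
        if back is None:
            continue
        c_back, a_back = back
        if c_back == t and a > threshold and a_back > threshold:
            g.add_edge(f"{test_ds}|{t}", f"{train_ds}|{c}", weight=(a + a_back) / 2.0)
    components = [set(comp) for comp in nx.connected_components(g)]
    components.sort(key=lambda s: (-len(s), sorted(s)))
    means = []
    for comp in components:
        ws = [g.edges[e]["weight"] for e in g.edges(comp) if set(e) <= comp]
        means.append(float(np.mean(ws)) if ws else np.nan)
    return MetaClusterSet(components=components, threshold=threshold, mean_auroc=means)


def count_replicable(metaclusters: MetaClusterSet, min_datasets: int = 2) -> int:
    """Number of meta-clusters spanning at least ``min_datasets`` datasets."""
    n = 0
    for comp in metaclusters.components:
        datasets = {node.split("|", 1)[0] for node in comp}
        if len(datasets) >= min_datasets:
            n += 1
    return n


# ---------------------------------------------------------------------------
# cross-platform Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def platform_jsd(
    datasets: dict[str, OmicsDataset],
    labels: dict[str, np.ndarray],
    n_sample: int = 1000,
    min_fraction: float = 0.01,
    min_cells: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-type, per-platform-pair expression divergence (base-2 JSD).

    For every shared cell type, ``n_sample`` cells are drawn per platform
    (with replacement when fewer are available), their counts pooled and
    normalized to a gene probability vector; the JSD between platform pairs
    is bounded in [0, 1].  Types falling below the abundance filters in any
    platform are omitted.
    """
    rng = np.random.default_rng(seed)
    platforms = list(datasets)
    if len(platforms) < 2:
        raise ValueError("need at least 2 platforms")
    lab = {p: np.asarray(labels[p]).astype(str) for p in platforms}
    common_types = set(lab[platforms[0]])
    for p in platforms[1:]:
        common_types &= set(lab[p])
    kept = []
    for t in sorted(common_types):
        ok = True
        for p in platforms:
            n = int((lab[p] == t).sum())
            if n < min_cells or n / lab[p].size < min_fraction:
                ok = False
                break
        if ok:
            kept.append(t)
    rows = []
    for t in kept:
        profiles = {}
        for p in platforms:
            members = np.flatnonzero(lab[p] == t)
            replace = members.size < n_sample
            idx = rng.choice(members, size=n_sample, replace=replace)
            pooled = np.asarray(datasets[p].values[idx].sum(axis=0)).ravel().astype(float)
            total = pooled.sum()
            profiles[p] = pooled / total if total > 0 else pooled
        for i, p1 in enumerate(platforms):
            for p2 in platforms[i + 1 :]:
                jsd = float(jensenshannon(profiles[p1], profiles[p2], base=2) ** 2)
                rows.append({"cell_type": t, "platform_a": p1, "platform_b": p2, "jsd": jsd})
    out = pd.DataFrame(rows, columns=["cell_type", "platform_a", "platform_b", "jsd"])
    if out.empty:
        import warnings

        warnings.warn("no shared cell types pass the abundance filters")
    return out
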