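"""Run configuration and the end-to-end pipeline driver.

``run_pipeline`` executes simulate/ingest -> QC -> normalize -> fuse ->
merge -> cluster-resolution CV -> replicability and emits a JSON + Markdown
report.  All randomness fans out from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustercv, consensus, fusion, io, qcnorm, replicability, synth

log = logging.getLogger("cellfuse")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard default values."""

    seed: int = 0
    # synthetic atlas
    n_types: int = 8
    n_subclasses: int = 4
    n_genes: int = 2000
    n_chromosomes: int = 10
    effect_size: float = 2.0
    n_cells: int = 1500
    # smoothing / imputation
    ndim: int = 50
    knn_k: int = 30
    ka: int = 5
    rkp_k: int = 20
    rkp_z: int = 3
    # clustering
    leiden_resolution: float = 0.1
    rounds: int = 3
    min_cells_split: int = 50
    # cross-validation
    cv_feature_splits: int = 5
    cv_cell_folds: int = 5
    # replicability
    auroc_threshold: float = 0.7
    jsd_min_cells: int = 300

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _ari(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(np.asarray(a).astype(str), np.asarray(b).astype(str)))


def run_pipeline(config: RunConfig, outdir: str | Path, datasets=None) -> dict:
    """Execute the full synthetic pipeline and write a report.

    When ``datasets`` is None, the default synthetic atlas is simulated at
    the configured size; otherwise the given OmicsDatasets are used (the
    first RNA dataset serves as the integration reference).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2**31 - 1)) for s in
                   ("atlas", "datasets", "fusion", "cv", "replicability", "jsd")}
    report: dict = {"config": asdict(config), "stage_seeds": stage_seeds}

    if datasets is None:
        atlas = synth.generate_atlas(
            n_types=config.n_types,
            n_genes=config.n_genes,
            n_chromosomes=config.n_chromosomes,
            effect_size=config.effect_size,
            seed=stage_seeds["atlas"],
            n_subclasses=config.n_subclasses,
        )
        specs = synth.default_dataset_specs(seed=stage_seeds["datasets"], n_cells=config.n_cells)
        datasets = [synth.simulate_dataset(atlas, s) for s in specs]
        log.info("simulated %d datasets from a %d-type atlas", len(datasets), atlas.n_types)

    # QC: methylation filter where metadata allow it
    kept = []
    for d in datasets:
        if d.modality == "mc":
            d = qcnorm.qc_filter_mc(d)
        kept.append(d)
    datasets = kept
    reference = next(d.name for d in datasets if d.modality in ("rna_cell", "rna_nucleus"))
    if len(datasets) == 1:
        report["mode"] = "single_dataset"

    # fusion
    assign = fusion.iterative_fusion(
        datasets,
        reference,
        rounds=config.rounds,
        resolution=config.leiden_resolution,
        k=config.knn_k,
        min_cells_split=config.min_cells_split,
        seed=stage_seeds["fusion"],
    )
    io.write_labels(assign, out / "labels.tsv")
    report["fusion"] = {
        "levels": {lvl: int(assign.cells[lvl].nunique()) for lvl in assign.levels},
        "nesting_ok": bool(assign.check_nesting()),
    }
    truth_cols = [d.cells["true_type"] for d in datasets if "true_type" in d.cells.columns]
    if truth_cols:
        truth = np.concatenate([t.to_numpy() for t in truth_cols])
        deepest = assign.levels[-1]
        report["fusion"]["ari_vs_truth"] = _ari(truth, assign.labels(deepest))

    # merging on the deepest level
    norms = {d.name: qcnorm.normalize(d) for d in datasets}
    labels_by_ds = {
        d.name: assign.cells.loc[assign.cells["dataset"] == d.name, assign.levels[-1]].to_numpy()
        for d in datasets
    }
    merged = consensus.merge_clusters(labels_by_ds, norms)
    report["merge"] = {
        "n_before": int(assign.cells[assign.levels[-1]].nunique()),
        "n_after": len(set().union(*(set(v) for v in merged.values()))),
    }

    # within-dataset CV on the reference dataset
    ref_ds = next(d for d in datasets if d.name == reference)
    curve = clustercv.within_dataset_cv(
        norms[reference],
        ref_ds.genes,
        n_feature_splits=min(config.cv_feature_splits, 3),
        n_cell_folds=config.cv_cell_folds,
        seed=stage_seeds["cv"],
    )
    k_min, band = clustercv.optimal_resolution(curve)
    curve.table.to_csv(out / "cv_curve.tsv", sep="\t", index=False)
    report["cv"] = {"k_at_min": k_min, "k_range_1se": band}

    # replicability between per-dataset labelings
    genes = replicability.shared_hvg(datasets, seed=stage_seeds["replicability"])
    mats = {}
    feats = {}
    for d in datasets:
        nm = norms[d.name].restrict_genes([g for g in genes if g in set(norms[d.name].gene_ids)])
        feats[d.name] = nm.values
    sizes = {d.name: dict(zip(*np.unique(labels_by_ds[d.name], return_counts=True)))
             for d in datasets}
    for a in datasets:
        for b in datasets:
            if a.name == b.name:
                continue
            vote = replicability.neighbor_vote_auroc(
                feats[a.name], labels_by_ds[a.name], feats[b.name], labels_by_ds[b.name],
                train_dataset=a.name, test_dataset=b.name,
                flip=(a.modality == "mc") != (b.modality == "mc"),
            )
            mats[(a.name, b.name)] = replicability.one_vs_best(vote)
    if mats:
        mcs = replicability.meta_clusters(mats, threshold=config.auroc_threshold,
                                          cluster_sizes=sizes)
        report["replicability"] = {
            "n_meta_clusters": len(mcs.components),
            "n_replicable": replicability.count_replicable(mcs),
        }
    else:
        report["replicability"] = {"note": "single dataset; no cross-dataset scoring"}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    md = ["# cellfuse pipeline report", ""]
    for section, content in report.items():
        md.append(f"## {section}\n\n```\n{json.dumps(content, indent=2, default=float)}\n```\n")
    (out / "report.md").write_text("\n".join(md))
    return report
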