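"""Readers and writers for the on-disk dataset layout.

A dataset directory holds ``matrix.mtx`` (Matrix Market, genes x cells, so
cells are columns, mirroring the 10x convention), ``barcodes.tsv``,
``features.tsv`` (gene_id, chromosome, length, nuclear_retention) and
``cell_metadata.tsv``.  Methylation datasets write ``mc.mtx`` + ``cov.mtx``
instead of ``matrix.mtx``.  A manifest JSON lists datasets, modalities and
seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .synth import OmicsDataset


class SchemaError(ValueError):
    """Raised when an on-disk dataset fails validation."""


def write_dataset(dataset: OmicsDataset, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset.modality == "mc":
        sio.mmwrite(out / "mc.mtx", sp.coo_matrix(dataset.values.T))
        sio.mmwrite(out / "cov.mtx", sp.coo_matrix(dataset.coverage.T))
    else:
        sio.mmwrite(out / "matrix.mtx", sp.coo_matrix(dataset.values.T))
    pd.Series(dataset.cells.index).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    dataset.genes.to_csv(out / "features.tsv", sep="\t")
    dataset.cells.to_csv(out / "cell_metadata.tsv", sep="\t")
    (out / "dataset.json").write_text(
        json.dumps({"modality": dataset.modality, "platform": dataset.platform, "name": dataset.name})
    )
    return out


def _read_mtx(path: Path) -> sp.csr_matrix:
    if not path.exists():
        raise SchemaError(f"missing matrix file: {path}")
    try:
        m = sio.mmread(path)
    except Exception as err:
        raise SchemaError(f"malformed Matrix Market file {path}: {err}") from err
    return sp.csr_matrix(m).T.tocsr()  # back to cells x genes


def read_dataset(indir: str | Path) -> OmicsDataset:
    d = Path(indir)
    info_path = d / "dataset.json"
    if not info_path.exists():
        raise SchemaError(f"missing dataset.json in {d}")
    info = json.loads(info_path.read_text())
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    genes = pd.read_csv(d / "features.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(d / "cell_metadata.tsv", sep="\t", index_col=0)
    if list(cells.index) != barcodes:
        raise SchemaError(f"{d}: barcodes.tsv does not match cell_metadata.tsv")
    coverage = None
    if info["modality"] == "mc":
        values = _read_mtx(d / "mc.mtx")
        coverage = _read_mtx(d / "cov.mtx")
        if (values.toarray() > coverage.toarray()).any():
            raise SchemaError(f"{d}: methylated calls exceed coverage")
    else:
        values = _read_mtx(d / "matrix.mtx")
    if values.shape != (len(cells), len(genes)):
        raise SchemaError(
            f"{d}: matrix shape {values.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    return OmicsDataset(
        modality=info["modality"],
        platform=info["platform"],
        cells=cells,
        genes=genes,
        values=values,
        coverage=coverage,
        name=info.get("name", d.name),
    )


def write_manifest(entries: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"datasets": entries}, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    entries = data["datasets"]
    ids = [e["id"] for e in entries]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate dataset ids in manifest")
    for e in entries:
        if not Path(e["path"]).exists():
            raise SchemaError(f"manifest path does not exist: {e['path']}")
    return entries


def write_labels(assignment, path: str | Path) -> None:
    """Write a ClusterAssignment's cell table as TSV."""
    assignment.cells.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
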