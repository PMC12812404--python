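"""Readers and writers for the flat-file formats the package exchanges.

Supported inputs: a Matrix Market triplet directory (matrix.mtx +
features.tsv + barcodes.tsv, either orientation — rows are matched to the
barcode file) or a dense CSV/TSV with cells as rows, a header row of
feature ids and the first column holding cell ids. Outputs are plain CSVs
(latent matrices, loss traces, truth tables) and a CSV-pair round-trip for
:class:`~lorentzvae.preprocessing.ProcessedDataset`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocessing import CountMatrix, ProcessedDataset


def read_mtx_dir(path, modality: str) -> CountMatrix:
    """Read a matrix.mtx/features.tsv/barcodes.tsv triplet.

    Orientation is resolved against the id files: if the matrix has
    len(features) rows and len(barcodes) columns it is transposed to
    cell-major. Ambiguous (square) matrices are assumed cell-major.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    mat = spio.mmread(mtx)
    if sparse.issparse(mat):
        mat = mat.toarray()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(features), len(barcodes)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (cells={len(barcodes)}, "
            f"features={len(features)}) nor its transpose")
    return CountMatrix(np.asarray(mat), barcodes, features, modality)


def write_mtx_dir(X: CountMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(X.counts))
    pd.Series(X.feature_ids).to_csv(path / "features.tsv", sep="\t",
                                    header=False, index=False)
    pd.Series(X.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)


def read_csv_counts(path, modality: str) -> CountMatrix:
    """Dense counts: header = feature ids, first column = cell ids."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(df.to_numpy(), df.index.astype(str).tolist(),
                       df.columns.astype(str).tolist(), modality)


def write_csv_counts(X: CountMatrix, path) -> None:
    pd.DataFrame(X.counts, index=X.cell_ids, columns=X.feature_ids).to_csv(path)


def read_counts(path, modality: str) -> CountMatrix:
    """Dispatch on input kind: directory -> MTX triplet, file -> dense CSV/TSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_dir(path, modality)
    return read_csv_counts(path, modality)


def read_label_csv(path, column: Optional[str] = None) -> np.ndarray:
    """Per-cell labels: single column, or named column of a table with a
    cell-id index column first."""
    df = pd.read_csv(path)
    if column is not None:
        return df[column].to_numpy()
    return df[df.columns[-1]].to_numpy()


def save_processed(ds: ProcessedDataset, path) -> None:
    """Persist a ProcessedDataset as a raw/normalized CSV pair + JSON meta."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.raw_counts, index=ds.cell_ids,
                 columns=ds.selected_features).to_csv(path / "raw_counts.csv")
    pd.DataFrame(ds.model_input, index=ds.cell_ids,
                 columns=ds.selected_features).to_csv(path / "model_input.csv")
    meta = {"modality": ds.modality,
            "library_sizes": ds.library_sizes.tolist()}
    (path / "meta.json").write_text(json.dumps(meta))


def load_processed(path) -> ProcessedDataset:
    path = Path(path)
    raw = pd.read_csv(path / "raw_counts.csv", index_col=0)
    norm = pd.read_csv(path / "model_input.csv", index_col=0)
    meta = json.loads((path / "meta.json").read_text())
    return ProcessedDataset(
        raw_counts=raw.to_numpy(),
        model_input=norm.to_numpy(),
        selected_features=raw.columns.astype(str).tolist(),
        library_sizes=np.asarray(meta["library_sizes"], dtype=np.float64),
        cell_ids=raw.index.astype(str).tolist(),
        modality=meta["modality"],
    )


def write_latent_csv(Z: np.ndarray, cell_ids, path) -> None:
    cols = [f"latent_{i}" for i in range(Z.shape[1])]
    pd.DataFrame(Z, index=cell_ids, columns=cols).to_csv(path)
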