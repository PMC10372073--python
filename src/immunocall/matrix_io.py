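"""Reading and writing gene-by-cell count matrices and per-cell tables.

Supported inputs are the 10x-style MatrixMarket triplet (matrix.mtx plus
genes/features and barcodes sidecars) and dense TSV/CSV matrices.  Gzipped
files are detected by magic bytes.  The in-memory container is
:class:`CellMatrix`: a sparse genes × cells matrix with a layer tag tracking
where it sits in the raw → normalized → log-normalized pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "MatrixFormatError",
    "read_counts_mtx",
    "read_counts_dense",
    "write_counts_mtx",
    "write_calls",
    "read_calls",
    "read_labels",
    "CALL_COLUMNS",
]

#: Column order of the per-cell calls CSV.
CALL_COLUMNS = (
    "barcode",
    "rho_max",
    "total_immune_expression",
    "linear_score",
    "is_immune",
    "signature_type",
    "category",
    "tcell_subtype",
)

LAYERS = ("raw", "normalized", "lognormalized")


class MatrixFormatError(ValueError):
    """Input does not conform to the expected matrix format."""


@dataclass
class CellMatrix:
    """Sparse gene-by-cell expression matrix.

    ``counts`` is genes (rows) × cells (columns), CSC for fast per-cell
    access.  ``layer`` records the processing state: ``raw`` entries must be
    non-negative integers; ``normalized`` columns sum to the scale constant;
    ``lognormalized`` holds log1p of normalized values.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csc_matrix
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        G, N = self.counts.shape
        if len(self.genes) != G:
            raise MatrixFormatError(
                f"{len(self.genes)} gene symbols for a {G}-row matrix"
            )
        if len(self.barcodes) != N:
            raise MatrixFormatError(
                f"{len(self.barcodes)} barcodes for a {N}-column matrix"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixFormatError("negative entry in count matrix")
        if self.layer == "raw" and self.counts.nnz:
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise MatrixFormatError("non-integer entry in raw count matrix")
        if len(set(self.genes)) != len(self.genes):
            dup = pd.Index(self.genes)
            dup = dup[dup.duplicated()][0]
            raise MatrixFormatError(f"duplicate gene symbol {dup!r}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixFormatError("duplicate cell barcodes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell column sums."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        """New matrix keeping the cells where ``mask`` is true, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        return CellMatrix(
            genes=list(self.genes),
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            counts=self.counts[:, mask],
            layer=self.layer,
        )


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_binary(path: str | Path) -> IO[bytes]:
    path = Path(path)
    if _is_gzip(path):
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_sidecar(path: str | Path, kind: str) -> list[str]:
    # 10x genes.tsv has (id, symbol); features.tsv adds a type column; a bare
    # one-column list is also accepted.  The symbol column is preferred.
    with _open_text(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        return []
    ncol = len(rows[0])
    col = 1 if (kind == "genes" and ncol >= 2) else 0
    return [r[col] for r in rows]


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CellMatrix:
    """Read a 10x-style MatrixMarket triplet into a raw :class:`CellMatrix`.

    The matrix file uses 1-based MatrixMarket coordinates with genes as rows
    and cells as columns; sidecars list gene symbols and cell barcodes in
    matrix order.
    """
    with _open_binary(matrix_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise MatrixFormatError(f"{matrix_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    genes = _read_sidecar(genes_path, "genes")
    barcodes = _read_sidecar(barcodes_path, "barcodes")
    if len(genes) != mat.shape[0]:
        raise MatrixFormatError(
            f"matrix declares {mat.shape[0]} genes but sidecar lists {len(genes)}"
        )
    if len(barcodes) != mat.shape[1]:
        raise MatrixFormatError(
            f"matrix declares {mat.shape[1]} cells but sidecar lists {len(barcodes)}"
        )
    return CellMatrix(genes=genes, barcodes=barcodes, counts=mat, layer="raw")


def read_counts_dense(
    path: str | Path, orientation: str = "genes-by-cells"
) -> CellMatrix:
    """Read a dense TSV/CSV count matrix.

    ``orientation`` declares the file layout; the result is always canonical
    genes-by-cells.
    """
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise MatrixFormatError(f"{path}: ragged or missing entries")
    if orientation == "cells-by-genes":
        df = df.T
    return CellMatrix(
        genes=[str(g) for g in df.index],
        barcodes=[str(b) for b in df.columns],
        counts=sp.csc_matrix(df.to_numpy()),
        layer="raw",
    )


def write_counts_mtx(m: CellMatrix, out_dir: str | Path) -> None:
    """Write a CellMatrix as a 10x-style triplet (matrix.mtx, genes.tsv, barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts))
    with open(out / "genes.tsv", "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\t{g}\n")
    with open(out / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(m.barcodes) + ("\n" if m.barcodes else ""))


def write_calls(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-cell results as CSV with the canonical column set.

    Missing optional columns are emitted blank; floats are fixed to six
    decimals so repeated runs are byte-identical.
    """
    df = table.copy()
    for col in CALL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[list(CALL_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.6f")


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls CSV written by :func:`write_calls`."""
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation TSV indexed by barcode.

    Any subset of the columns (true cell type, sample id, group id) may be
    present; barcodes must be unique.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        raise MatrixFormatError(f"{path}: duplicate barcodes")
    return df
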