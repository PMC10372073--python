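"""Per-cell quality filtering and total-count normalization.

The input pipeline is deliberately minimal: drop cells with fewer than 500
total counts, rescale each remaining cell to a fixed total of 10,000, and —
only where a downstream consumer asks for it — take the natural log1p.  No
gene-level filtering is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix_io import CellMatrix

__all__ = ["PreprocessConfig", "filter_cells", "normalize_cells", "log_normalize"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Quality-control and normalization settings.

    min_total_count
        Cells with raw total strictly below this are removed (default 500;
        a cell at exactly the threshold is retained).
    scale
        Post-normalization per-cell total (default 10,000).
    """

    min_total_count: int = 500
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def filter_cells(m: CellMatrix, cfg: PreprocessConfig = PreprocessConfig()) -> CellMatrix:
    """Drop cells whose total count is below ``cfg.min_total_count``.

    Gene set and barcode order are preserved; an empty result is valid.
    """
    if m.layer != "raw":
        raise ValueError(f"filter_cells expects the raw layer, got {m.layer!r}")
    return m.subset_cells(m.cell_totals() >= cfg.min_total_count)


def normalize_cells(
    m: CellMatrix, cfg: PreprocessConfig = PreprocessConfig()
) -> CellMatrix:
    """Rescale every cell so its total equals ``cfg.scale``.

    Raises if any cell has zero total: filter first.
    """
    totals = m.cell_totals()
    if m.n_cells and totals.min() == 0:
        raise ValueError(
            "zero-total cell present; apply filter_cells before normalize_cells"
        )
    counts = sp.csc_matrix(m.counts, dtype=np.float64, copy=True)
    if m.n_cells:
        inv = cfg.scale / totals
        counts = counts @ sp.diags(inv)
    return CellMatrix(
        genes=list(m.genes),
        barcodes=list(m.barcodes),
        counts=counts,
        layer="normalized",
    )


def log_normalize(m: CellMatrix) -> CellMatrix:
    """Entrywise natural log1p of a normalized matrix."""
    if m.layer != "normalized":
        raise ValueError(
            f"log_normalize expects the normalized layer, got {m.layer!r}"
        )
    counts = sp.csc_matrix(m.counts, copy=True)
    counts.data = np.log1p(counts.data)
    return CellMatrix(
        genes=list(m.genes),
        barcodes=list(m.barcodes),
        counts=counts,
        layer="lognormalized",
    )
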