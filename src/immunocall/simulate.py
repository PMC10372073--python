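"""Synthetic ground-truth data with the statistical structure the method
assumes.

Counts are drawn from a negative-binomial model with gene-independent
dispersion, multiplicative per-cell library-size factors and independent
Bernoulli dropout.  Immune cells of a given type over-express that type's
marker block of the signature; non-immune cells put only a small, tunable
fraction of their expected mass on signature genes, so the immune gate's
two metrics separate the classes the way the method expects (immune total
signature expression well above the decision threshold, non-immune well
below).  This is a deliberately simple emulation: it reproduces marker
contrast and over-dispersion, not transcriptome-wide co-expression,
ambient RNA or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import CellMatrix
from .signature import LM22_TYPES, SignatureMatrix

__all__ = [
    "SimConfig",
    "generate_signature",
    "simulate_cells",
    "simulate_tcell_sources",
    "DEFAULT_CD4_MARKERS",
    "DEFAULT_CD8_MARKERS",
]

#: Default marker panels for the synthetic CD4/CD8 sources: the canonical
#: surface/effector markers plus generic filler symbols.
DEFAULT_CD4_MARKERS: tuple[str, ...] = (
    "CD4", "CD40LG", "IL2", "TNFRSF4",
    *(f"CD4SIM{i:02d}" for i in range(5, 21)),
)
DEFAULT_CD8_MARKERS: tuple[str, ...] = (
    "CD8A", "CD8B", "CTSW", "NKG7",
    *(f"CD8SIM{i:02d}" for i in range(5, 21)),
)


def generate_signature(
    n_genes: int,
    n_types: int,
    markers_per_type: int,
    seed: int = 0,
    type_names: Optional[Sequence[str]] = None,
) -> SignatureMatrix:
    """Block-structured binary signature: disjoint marker blocks per type.

    Gene ``i`` is a marker of type ``i // markers_per_type`` for the first
    ``n_types * markers_per_type`` genes; any remaining genes are
    marker-free rows (as in the real leukocyte matrix, where most genes
    mark few types).  With ``n_types == 22`` the columns take the real
    LM22 labels so the shipped category map applies directly.  The layout
    is deterministic; ``seed`` is accepted for interface symmetry.
    """
    if n_types * markers_per_type > n_genes:
        raise ValueError(
            f"{n_types} types x {markers_per_type} markers exceed {n_genes} genes"
        )
    if type_names is None:
        type_names = list(LM22_TYPES) if n_types == 22 else [
            f"SimType{k + 1:02d}" for k in range(n_types)
        ]
    if len(type_names) != n_types:
        raise ValueError("type_names length must equal n_types")
    values = np.zeros((n_genes, n_types), dtype=np.int8)
    for k in range(n_types):
        values[k * markers_per_type : (k + 1) * markers_per_type, k] = 1
    genes = [f"SIG{i + 1:04d}" for i in range(n_genes)]
    return SignatureMatrix(genes=genes, types=list(type_names), values=values)


@dataclass
class SimConfig:
    """Generative settings for the mixed immune / non-immune population.

    Defaults emulate a well-powered benchmark condition: 10,000 immune
    cells split evenly over the 22 signature types plus 3,000 non-immune
    cells, a 547-gene block signature plus 2,000 background genes, marker
    means an order of magnitude above off-signature leak, moderate
    over-dispersion, 30% dropout and a lognormal library-size spread.
    Under these settings an immune cell's expected total signature
    expression is ≈2,600 (of the 10,000 normalization scale) and a
    non-immune cell's ≈200, straddling the default gate threshold of 413.
    """

    signature: Optional[SignatureMatrix] = None
    n_genes_background: int = 2000
    cells_per_type: int | Mapping[str, int] = 10_000  # int = total immune cells
    n_nonimmune: int = 3000
    mu_marker: float = 10.0
    mu_offsignature: float = 0.2
    mu_background: float = 0.5
    dispersion: float = 2.0  # NB size; np.inf gives the Poisson limit
    dropout_rate: float = 0.3
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    nonimmune_marker_fraction: float = 0.02
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu_marker, self.mu_background) <= 0 or self.mu_offsignature < 0:
            raise ValueError("mean expression levels must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 <= self.nonimmune_marker_fraction < 1:
            raise ValueError("nonimmune_marker_fraction must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def resolved_signature(self) -> SignatureMatrix:
        if self.signature is None:
            self.signature = generate_signature(547, 22, 24, seed=self.seed)
        return self.signature

    def type_counts(self) -> dict[str, int]:
        sig = self.resolved_signature()
        if isinstance(self.cells_per_type, Mapping):
            unknown = set(self.cells_per_type) - set(sig.types)
            if unknown:
                raise ValueError(f"cells_per_type names unknown types: {unknown}")
            return dict(self.cells_per_type)
        total = int(self.cells_per_type)
        K = sig.n_types
        base, extra = divmod(total, K)
        return {t: base + (1 if k < extra else 0) for k, t in enumerate(sig.types)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial counts with the given mean matrix (Poisson at inf)."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _draw_block(
    rng: np.random.Generator,
    mu: np.ndarray,
    n_cells: int,
    cfg_dispersion: float,
    dropout: float,
    lib_mu_sd: tuple[float, float],
) -> sp.csc_matrix:
    lib = rng.lognormal(lib_mu_sd[0], lib_mu_sd[1], size=n_cells)
    mean = np.outer(mu, lib)
    counts = _nb_draw(rng, mean, cfg_dispersion)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)
    return sp.csc_matrix(counts, dtype=np.float64)


def simulate_cells(cfg: SimConfig) -> tuple[CellMatrix, pd.DataFrame]:
    """Draw a mixed immune / non-immune raw count matrix with truth labels.

    Returns the raw :class:`CellMatrix` (signature genes first, then
    background genes) and a truth table with columns barcode, true_type
    ("non-immune" for the background population), is_immune and sample.
    """
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.resolved_signature()
    G, n_bg = sig.n_genes, cfg.n_genes_background
    genes = list(sig.genes) + [f"BG{i + 1:05d}" for i in range(n_bg)]

    counts_by_type = cfg.type_counts()
    marker_counts = sig.values.sum(axis=0)
    # Match non-immune expected library size to the immune average so the
    # QC filter treats both classes alike.
    imm_totals = (
        marker_counts * cfg.mu_marker
        + (G - marker_counts) * cfg.mu_offsignature
        + n_bg * cfg.mu_background
    )
    total_mean = float(imm_totals.mean())
    f = cfg.nonimmune_marker_fraction
    mu_non = np.concatenate(
        [np.full(G, f * total_mean / G), np.full(n_bg, (1 - f) * total_mean / n_bg)]
    )

    blocks, types = [], []
    for k, t in enumerate(sig.types):
        n = counts_by_type[t]
        if n == 0:
            continue
        mu = np.concatenate(
            [
                np.where(sig.values[:, k] == 1, cfg.mu_marker, cfg.mu_offsignature),
                np.full(n_bg, cfg.mu_background),
            ]
        )
        blocks.append(
            _draw_block(rng, mu, n, cfg.dispersion, cfg.dropout_rate,
                        cfg.library_size_lognormal)
        )
        types.extend([t] * n)
    if cfg.n_nonimmune:
        blocks.append(
            _draw_block(rng, mu_non, cfg.n_nonimmune, cfg.dispersion,
                        cfg.dropout_rate, cfg.library_size_lognormal)
        )
        types.extend(["non-immune"] * cfg.n_nonimmune)

    counts = sp.hstack(blocks).tocsc()
    n_cells = counts.shape[1]
    barcodes = [f"cell{i + 1:06d}" for i in range(n_cells)]
    samples = [f"S{rng.integers(cfg.n_samples) + 1}" for _ in range(n_cells)]
    from .signature import DEFAULT_CATEGORY_MAP

    def category_of(t: str) -> str:
        if t == "non-immune":
            return "non-immune"
        return DEFAULT_CATEGORY_MAP.mapping.get(t, t)

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_type": types,
            "true_category": [category_of(t) for t in types],
            "is_immune": [t != "non-immune" for t in types],
            "sample": samples,
        }
    )
    matrix = CellMatrix(genes=genes, barcodes=barcodes, counts=counts, layer="raw")
    return matrix, truth


def simulate_tcell_sources(
    n_sources_cd4: int = 10,
    n_sources_cd8: int = 5,
    cells_per_source: int = 1300,
    cd4_markers: Sequence[str] = DEFAULT_CD4_MARKERS,
    cd8_markers: Sequence[str] = DEFAULT_CD8_MARKERS,
    n_genes: int = 500,
    mu_marker: float = 8.0,
    mu_offmarker: float = 0.2,
    mu_background: float = 0.5,
    dispersion: float = 2.0,
    dropout_rate: float = 0.3,
    library_size_lognormal: tuple[float, float] = (0.0, 0.3),
    batch_effect_sd: float = 0.2,
    seed: int = 0,
) -> list[tuple[CellMatrix, str]]:
    """Multi-study CD4/CD8 T-cell sources with per-source batch effects.

    Every source shares one gene universe (the two disjoint marker panels
    plus background genes up to ``n_genes``) and draws a per-gene lognormal
    batch factor with sd ``batch_effect_sd``, shared by all its cells —
    emulating study-to-study expression shifts that motivate pooling many
    sources for training.  CD4 sources elevate the CD4 panel, CD8 sources
    the CD8 panel.
    """
    cd4_markers, cd8_markers = list(cd4_markers), list(cd8_markers)
    overlap = set(cd4_markers) & set(cd8_markers)
    if overlap:
        raise ValueError(f"CD4 and CD8 marker panels overlap: {sorted(overlap)}")
    n_markers = len(cd4_markers) + len(cd8_markers)
    if n_markers > n_genes:
        raise ValueError("marker panels exceed the gene universe")
    genes = cd4_markers + cd8_markers + [
        f"TBG{i + 1:04d}" for i in range(n_genes - n_markers)
    ]
    base_cd4 = np.concatenate(
        [
            np.full(len(cd4_markers), mu_marker),
            np.full(len(cd8_markers), mu_offmarker),
            np.full(n_genes - n_markers, mu_background),
        ]
    )
    base_cd8 = np.concatenate(
        [
            np.full(len(cd4_markers), mu_offmarker),
            np.full(len(cd8_markers), mu_marker),
            np.full(n_genes - n_markers, mu_background),
        ]
    )
    rng = np.random.default_rng(seed)
    sources: list[tuple[CellMatrix, str]] = []
    plan = [("CD4", base_cd4)] * n_sources_cd4 + [("CD8", base_cd8)] * n_sources_cd8
    for s, (label, base) in enumerate(plan):
        batch = (
            rng.lognormal(0.0, batch_effect_sd, size=n_genes)
            if batch_effect_sd > 0
            else np.ones(n_genes)
        )
        block = _draw_block(
            rng, base * batch, cells_per_source, dispersion, dropout_rate,
            library_size_lognormal,
        )
        barcodes = [f"{label.lower()}s{s + 1:02d}c{i + 1:05d}"
                    for i in range(cells_per_source)]
        sources.append(
            (CellMatrix(genes=list(genes), barcodes=barcodes, counts=block,
                        layer="raw"), label)
        )
    return sources
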