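"""The two-metric immune gate: maximum profile correlation and total
signature expression, combined by a linear decision rule.

For every cell (normalized to a fixed total), two quantities are computed
over the signature gene basis:

* ``rho_max`` — the largest Pearson correlation between the cell's
  normalized expression across the signature genes and any of the binary
  cell-type profiles;
* ``T`` — the summed normalized expression over all signature genes
  (bounded by the normalization scale).

A cell is called immune when ``A * rho_max + T > theta`` (strict).  The
default constants, A = 1580.7 and theta = 413, were calibrated against
large multi-study compendia of immune and non-immune cells and are applied
unchanged across datasets; refitting is an explicit, optional step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import sklearn.metrics

from .matrix_io import CellMatrix
from .signature import SignatureMatrix

__all__ = [
    "BoundaryParams",
    "align_to_signature",
    "profile_correlations",
    "correlation_matrix",
    "score_cells",
    "fit_boundary",
    "roc_curve",
    "roc_auc",
]


@dataclass(frozen=True)
class BoundaryParams:
    """Parameters of the linear immune/non-immune decision rule."""

    A: float = 1580.7
    theta: float = 413.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and np.isfinite(self.theta)):
            raise ValueError("boundary parameters must be finite")

    def linear_score(self, rho_max, T):
        """The gate statistic ``A * rho_max + T``."""
        return self.A * np.asarray(rho_max) + np.asarray(T)

    def is_immune(self, rho_max, T):
        """Strict-inequality immune call: linear score > theta."""
        return self.linear_score(rho_max, T) > self.theta


def align_to_signature(
    m: CellMatrix, sig: SignatureMatrix, allow_sparse_signature: bool = False
) -> tuple[CellMatrix, int]:
    """Restrict ``m`` to the signature gene basis, in signature order.

    Signature genes absent from ``m`` become all-zero rows, keeping the
    fixed G-gene basis so the gate threshold is comparable across datasets.
    Returns the aligned matrix and the number of missing signature genes;
    raises when more than half the signature is missing unless
    ``allow_sparse_signature``.
    """
    pos_of = {g: i for i, g in enumerate(sig.genes)}
    m_pos = sig.gene_positions(m.genes)
    present = m_pos >= 0
    n_missing = sig.n_genes - int(present.sum())
    if n_missing == sig.n_genes:
        raise ValueError("no signature genes found in the count matrix")
    if n_missing > sig.n_genes / 2 and not allow_sparse_signature:
        raise ValueError(
            f"{n_missing}/{sig.n_genes} signature genes missing from the "
            "matrix; pass allow_sparse_signature=True to proceed"
        )
    counts = m.counts.tocsr()
    aligned = sp.lil_matrix((sig.n_genes, m.n_cells), dtype=np.float64)
    src = np.flatnonzero(present)
    aligned[m_pos[src], :] = counts[src, :]
    out = CellMatrix(
        genes=list(sig.genes),
        barcodes=list(m.barcodes),
        counts=aligned.tocsc(),
        layer=m.layer,
    )
    return out, n_missing


def correlation_matrix(X: sp.spmatrix, S: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X against every binary profile.

    X is genes × cells (aligned to the signature basis), S is the G × K
    binary membership matrix.  Zero-variance cases (constant cell vector, or
    an all-ones profile) return 0 by convention.
    """
    X = sp.csc_matrix(X)
    G = X.shape[0]
    S = np.asarray(S, dtype=np.float64)
    sum_x = np.asarray(X.sum(axis=0)).ravel()
    sumsq_x = np.asarray(X.multiply(X).sum(axis=0)).ravel()
    sum_s = S.sum(axis=0)
    dot = np.asarray((X.T @ S))
    num = dot - np.outer(sum_x, sum_s) / G
    var_x = np.maximum(sumsq_x - sum_x**2 / G, 0.0)
    var_s = np.maximum(sum_s - sum_s**2 / G, 0.0)  # binary: s.s == sum_s
    denom = np.sqrt(np.outer(var_x, var_s))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def profile_correlations(cell: np.ndarray, sig: SignatureMatrix) -> np.ndarray:
    """Correlation of one cell vector (signature basis) to each profile."""
    vec = np.asarray(cell, dtype=np.float64).ravel()
    if vec.size != sig.n_genes:
        raise ValueError(
            f"cell vector has {vec.size} entries for a {sig.n_genes}-gene signature"
        )
    return correlation_matrix(sp.csc_matrix(vec[:, None]), sig.values)[0]


def score_cells(
    m: CellMatrix,
    sig: SignatureMatrix,
    params: BoundaryParams = BoundaryParams(),
    allow_sparse_signature: bool = False,
) -> pd.DataFrame:
    """Per-cell immune-gate scores.

    ``m`` must be on the normalized layer.  Returns one row per cell with
    columns barcode, rho_max, argmax_type (first maximizer in signature
    column order on ties), total_immune_expression, linear_score, is_immune.
    """
    if m.layer != "normalized":
        raise ValueError(f"score_cells expects the normalized layer, got {m.layer!r}")
    aligned, _ = align_to_signature(m, sig, allow_sparse_signature)
    rho = correlation_matrix(aligned.counts, sig.values)
    T = aligned.cell_totals()
    arg = rho.argmax(axis=1)  # np.argmax takes the first maximum on ties
    rho_max = rho[np.arange(rho.shape[0]), arg]
    score = params.linear_score(rho_max, T)
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "rho_max": rho_max,
            "argmax_type": [sig.types[j] for j in arg],
            "total_immune_expression": T,
            "linear_score": score,
            "is_immune": score > params.theta,
        }
    )


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """ROC staircase of (threshold, sensitivity, 1 - specificity)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes in labels")
    fpr, tpr, thr = sklearn.metrics.roc_curve(labels, np.asarray(scores, dtype=float))
    return pd.DataFrame(
        {"threshold": thr, "sensitivity": tpr, "one_minus_specificity": fpr}
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (ties counted half)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both classes in labels")
    return float(sklearn.metrics.roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class BoundaryGrid:
    """Search grid for :func:`fit_boundary`: coarse sweep then local refinement."""

    A_max: float = 5000.0
    theta_max: float = 10_000.0
    coarse_steps: int = 101
    refine_factor: int = 10

    def __post_init__(self) -> None:
        if self.A_max <= 0 or self.theta_max <= 0 or self.coarse_steps < 2:
            raise ValueError("degenerate boundary search grid")


def _best_on_grid(rho, T, labels, A_grid, theta_grid):
    # For each A, J(theta) over the whole theta grid via vectorized counts.
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best = (-np.inf, np.inf, np.inf)  # (J, A, theta)
    for A in A_grid:
        s = A * rho + T
        # immune call: s > theta
        above = s[:, None] > theta_grid[None, :]
        tp = (above & labels[:, None]).sum(axis=0)
        fp = (above & ~labels[:, None]).sum(axis=0)
        J = tp / n_pos + (n_neg - fp) / n_neg - 1.0
        j = int(J.argmax())  # first (smallest theta) maximizer
        if J[j] > best[0] + 1e-12:
            best = (float(J[j]), float(A), float(theta_grid[j]))
    return best


def fit_boundary(
    immune_scores: Sequence[tuple[float, float]],
    nonimmune_scores: Sequence[tuple[float, float]],
    grid: BoundaryGrid = BoundaryGrid(),
) -> tuple[BoundaryParams, float, float, float]:
    """Refit the linear gate by maximizing Youden's J over a grid.

    ``immune_scores`` and ``nonimmune_scores`` are (rho_max, T) pairs of
    cells with known class.  Returns the selected :class:`BoundaryParams`
    together with the AUC of the linear score at the selected slope and the
    sensitivity/specificity at the selected threshold.  Ties are broken
    toward smaller A, then smaller theta.
    """
    imm = np.asarray(immune_scores, dtype=float)
    non = np.asarray(nonimmune_scores, dtype=float)
    if imm.size == 0 or non.size == 0:
        raise ValueError("both immune and non-immune score lists must be non-empty")
    rho = np.concatenate([imm[:, 0], non[:, 0]])
    T = np.concatenate([imm[:, 1], non[:, 1]])
    labels = np.concatenate(
        [np.ones(len(imm), dtype=bool), np.zeros(len(non), dtype=bool)]
    )

    A_grid = np.linspace(0.0, grid.A_max, grid.coarse_steps)
    t_grid = np.linspace(0.0, grid.theta_max, grid.coarse_steps)
    _, A0, t0 = _best_on_grid(rho, T, labels, A_grid, t_grid)

    dA = A_grid[1] - A_grid[0]
    dt = t_grid[1] - t_grid[0]
    A_fine = np.linspace(max(A0 - dA, 0.0), min(A0 + dA, grid.A_max),
                         2 * grid.refine_factor + 1)
    t_fine = np.linspace(max(t0 - dt, 0.0), min(t0 + dt, grid.theta_max),
                         2 * grid.refine_factor + 1)
    _, A1, t1 = _best_on_grid(rho, T, labels, A_fine, t_fine)

    params = BoundaryParams(A=A1, theta=t1)
    score = params.linear_score(rho, T)
    pred = score > params.theta
    sens = float((pred & labels).sum() / labels.sum())
    spec = float((~pred & ~labels).sum() / (~labels).sum())
    return params, roc_auc(score, labels), sens, spec
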