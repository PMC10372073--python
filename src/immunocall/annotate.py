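"""Category assignment for gated cells and per-sample composition tables.

Gating order is fixed: the immune/non-immune decision comes first, and only
cells passing the gate are typed.  Typing maps the cell's best-correlated
signature profile through the 22 → 9 category map; cells landing on the
generic T-cell category can then be refined into CD4+/CD8+ by a trained
discriminator.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .matrix_io import CellMatrix
from .preprocess import PreprocessConfig, log_normalize, normalize_cells
from .signature import CATEGORIES, CategoryMap, DEFAULT_CATEGORY_MAP

__all__ = ["NON_IMMUNE", "FINAL_CATEGORIES", "annotate_cells", "composition_of"]

NON_IMMUNE = "non-immune"

#: The ten final categories after CD4/CD8 refinement.
FINAL_CATEGORIES: tuple[str, ...] = (
    "B cell",
    "plasma cell",
    "CD4+ T cell",
    "CD8+ T cell",
    "NK cell",
    "monocyte",
    "dendritic cell",
    "macrophage",
    "neutrophil",
    "other myeloid",
)


def annotate_cells(
    scores: pd.DataFrame,
    cmap: CategoryMap = DEFAULT_CATEGORY_MAP,
    tmodel=None,
    m: Optional[CellMatrix] = None,
    refine_tcells: Optional[bool] = None,
) -> pd.DataFrame:
    """Turn immune-gate scores into per-cell category calls.

    Parameters
    ----------
    scores
        Output of :func:`immunocall.identify.score_cells` for ``m``.
    cmap
        Signature-column → category map.
    tmodel
        Trained CD4/CD8 discriminator (:class:`immunocall.tcell.TCellModel`);
        required when refinement is requested and any cell maps to T cell.
    m
        The matrix the scores were computed on (normalized layer); needed
        only for refinement, which consumes its log-normalized expression.
    refine_tcells
        Force refinement on/off; default: refine iff ``tmodel`` is given.

    Returns a frame with columns barcode, is_immune, signature_type,
    category, tcell_subtype, tcell_score.  Non-immune cells get blank
    signature_type and category "non-immune" regardless of their argmax.
    """
    if refine_tcells is None:
        refine_tcells = tmodel is not None
    calls = pd.DataFrame(
        {
            "barcode": scores["barcode"].to_numpy(),
            "is_immune": scores["is_immune"].to_numpy(),
        }
    )
    immune = calls["is_immune"].to_numpy()
    sig_type = np.where(immune, scores["argmax_type"].to_numpy(), "")
    category = np.array(
        [cmap.category_of(t) if t else NON_IMMUNE for t in sig_type], dtype=object
    )
    calls["signature_type"] = sig_type
    calls["category"] = category
    calls["tcell_subtype"] = ""
    calls["tcell_score"] = np.nan

    t_mask = category == "T cell"
    if refine_tcells and t_mask.any():
        if tmodel is None:
            raise ValueError("T-cell refinement requested but no model supplied")
        if m is None:
            raise ValueError("T-cell refinement requires the expression matrix")
        if m.layer == "raw":
            m = normalize_cells(m, PreprocessConfig(min_total_count=0))
        if m.layer == "normalized":
            m = log_normalize(m)
        sub = m.subset_cells(t_mask)
        labels, margins = tmodel.predict(sub)
        calls.loc[t_mask, "tcell_subtype"] = labels
        calls.loc[t_mask, "tcell_score"] = margins
        calls.loc[t_mask, "category"] = [f"{lab}+ T cell" for lab in labels]
    return calls


def composition_of(
    calls: pd.DataFrame, sample_of: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-sample category proportions among immune cells.

    Every barcode in ``calls`` must map to a sample.  Rows are samples;
    category columns hold proportions over the immune cells of that sample
    (summing to 1); the ``non_immune_fraction`` column reports the
    non-immune share of all cells separately.  A sample with no immune
    cells gets NaN proportions.
    """
    sample_of = pd.Series(dict(sample_of)) if not isinstance(sample_of, pd.Series) else sample_of
    barcodes = calls["barcode"]
    missing = barcodes[~barcodes.isin(sample_of.index)]
    if len(missing):
        raise KeyError(f"barcodes without a sample assignment: {list(missing[:3])}...")
    df = calls.copy()
    df["sample"] = sample_of.loc[barcodes].to_numpy()

    cats = [c for c in df.loc[df["is_immune"], "category"].unique() if c != NON_IMMUNE]
    canonical = list(dict.fromkeys((*FINAL_CATEGORIES, *CATEGORIES)))
    columns = [c for c in canonical if c in cats]
    columns += sorted(set(cats) - set(columns))

    rows = {}
    for sample, grp in df.groupby("sample", sort=True):
        imm = grp[grp["is_immune"]]
        if len(imm):
            props = imm["category"].value_counts(normalize=True)
            rows[sample] = [float(props.get(c, 0.0)) for c in columns] + [
                1.0 - len(imm) / len(grp)
            ]
        else:
            rows[sample] = [np.nan] * len(columns) + [1.0]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=columns + ["non_immune_fraction"]
    )
    out.index.name = "sample"
    return out
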