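"""Accuracy, binomial confidence intervals, confusion matrices and
immune-gate sensitivity/specificity."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["accuracy_ci", "confusion", "gate_metrics"]


def accuracy_ci(
    n_correct: int, n_total: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Accuracy with a binomial confidence interval, clipped to [0, 1].

    The default is the Wald normal-approximation interval
    p ± z·sqrt(p(1−p)/n); ``method="wilson"`` gives the Wilson score
    interval for small-n use.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    p = n_correct / n_total
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n_total)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z**2 / n_total
        center = (p + z**2 / (2 * n_total)) / denom
        half = z * np.sqrt(p * (1 - p) / n_total + z**2 / (4 * n_total**2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, float(max(lo, 0.0)), float(min(hi, 1.0))


def confusion(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    vocabulary: Sequence[str],
    truth_column: str = "true_type",
) -> pd.DataFrame:
    """Confusion matrix of predicted categories against truth labels.

    Rows are true labels, columns predicted categories, both indexed by
    ``vocabulary`` (order preserved); every call barcode must appear in the
    truth table and every truth label in the vocabulary.
    """
    vocab = list(vocabulary)
    truth_of = truth.set_index("barcode")[truth_column] if "barcode" in truth else truth[truth_column]
    missing = calls["barcode"][~calls["barcode"].isin(truth_of.index)]
    if len(missing):
        raise KeyError(f"call barcodes absent from truth: {list(missing[:3])}")
    true = truth_of.loc[calls["barcode"]].to_numpy()
    bad = sorted(set(true) - set(vocab))
    if bad:
        raise ValueError(f"truth labels outside the vocabulary: {bad}")
    pred = calls["category"].to_numpy()
    mat = pd.crosstab(
        pd.Categorical(true, categories=vocab),
        pd.Categorical(pred, categories=vocab),
        dropna=False,
    )
    mat.index.name, mat.columns.name = "true", "predicted"
    return mat


def gate_metrics(
    calls: pd.DataFrame, truth: pd.DataFrame
) -> tuple[float, float]:
    """(sensitivity, specificity) of the immune/non-immune gate.

    Sensitivity is the fraction of truly immune cells called immune;
    specificity the fraction of truly non-immune cells called non-immune.
    """
    truth_of = truth.set_index("barcode")["is_immune"] if "barcode" in truth else truth["is_immune"]
    true = truth_of.loc[calls["barcode"]].to_numpy(dtype=bool)
    if true.all() or not true.any():
        raise ValueError("gate metrics need both classes in the truth")
    pred = calls["is_immune"].to_numpy(dtype=bool)
    sensitivity = float((pred & true).sum() / true.sum())
    specificity = float((~pred & ~true).sum() / (~true).sum())
    return sensitivity, specificity
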