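"""Two-group comparison of per-sample immune composition tables.

Given per-sample category proportions (rows samples, columns categories)
and a two-group sample assignment, each category is compared between the
groups with a two-sided Mann–Whitney U test — exact enumeration when both
groups have at most eight samples, tie-corrected normal approximation
otherwise.  Raw p-values are reported by default; Benjamini–Hochberg
adjustment and a Welch t alternative are available behind flags.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compare_groups", "EXACT_MAX_N"]

#: Largest per-group size at which the exact U distribution is enumerated.
EXACT_MAX_N = 8


def _mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(np.sort(a), np.sort(b)) and np.all(a == a[0]) and np.all(b == b[0]):
        return 1.0  # all observations identical: no evidence either way
    method = "exact" if (len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N
                         and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                         ) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_groups(
    comp: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    test: str = "mannwhitney",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-category two-group comparison of composition proportions.

    ``comp`` is the per-sample composition table (samples × categories);
    ``groups`` maps each sample to one of exactly two group labels, each
    with at least two samples.  Returns one row per category with the two
    group means, the effect direction, and the two-sided p-value (plus a
    BH-adjusted column when ``fdr``).
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    missing = [s for s in comp.index if s not in groups.index]
    if missing:
        raise KeyError(f"samples without a group assignment: {missing[:3]}")
    assign = groups.loc[comp.index]
    labels = sorted(assign.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a_label, b_label = labels
    n_a, n_b = (assign == a_label).sum(), (assign == b_label).sum()
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least two samples")

    categories = [c for c in comp.columns if c != "non_immune_fraction"]
    rows = []
    for cat in categories:
        vals = comp[cat].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        a = vals[ok & (assign == a_label).to_numpy()]
        b = vals[ok & (assign == b_label).to_numpy()]
        if len(a) < 2 or len(b) < 2:
            rows.append((cat, np.nan, np.nan, "", np.nan))
            continue
        if test == "mannwhitney":
            p = _mwu_p(a, b)
        elif test == "welch":
            p = float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        mean_a, mean_b = float(a.mean()), float(b.mean())
        direction = (
            f"higher in {b_label}" if mean_b > mean_a
            else f"higher in {a_label}" if mean_a > mean_b
            else "equal"
        )
        rows.append((cat, mean_a, mean_b, direction, p))
    out = pd.DataFrame(
        rows,
        columns=["category", f"mean_{a_label}", f"mean_{b_label}", "direction",
                 "p_value"],
    )
    if fdr:
        ok = out["p_value"].notna()
        adjusted = np.full(len(out), np.nan)
        if ok.any():
            adjusted[ok.to_numpy()] = multipletests(
                out.loc[ok, "p_value"], method="fdr_bh"
            )[1]
        out["p_adjusted"] = adjusted
    return out
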