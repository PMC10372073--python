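"""Binarized leukocyte signature matrices and the 22-type → 9-category map.

The signature matrix is a gene × cell-type membership matrix with entries in
{0, 1}: a 1 marks a gene as part of a cell type's marker profile.  The
canonical instance is a binarized form of the 547-gene, 22-column LM22
leukocyte matrix, but any binary matrix with the same layout is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "CategoryMap",
    "LM22_TYPES",
    "CATEGORIES",
    "DEFAULT_CATEGORY_MAP",
    "load_signature",
    "write_signature",
    "binarize_signature",
]

#: The 22 column labels of the LM22 leukocyte signature matrix.
LM22_TYPES: tuple[str, ...] = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

#: The nine pre-refinement output categories (CD4/CD8 split happens later).
CATEGORIES: tuple[str, ...] = (
    "B cell",
    "plasma cell",
    "T cell",
    "NK cell",
    "monocyte",
    "macrophage",
    "dendritic cell",
    "neutrophil",
    "other myeloid",
)

_DEFAULT_MAP: dict[str, str] = {
    "B cells naive": "B cell",
    "B cells memory": "B cell",
    "Plasma cells": "plasma cell",
    "T cells CD8": "T cell",
    "T cells CD4 naive": "T cell",
    "T cells CD4 memory resting": "T cell",
    "T cells CD4 memory activated": "T cell",
    "T cells follicular helper": "T cell",
    "T cells regulatory (Tregs)": "T cell",
    "T cells gamma delta": "T cell",
    "NK cells resting": "NK cell",
    "NK cells activated": "NK cell",
    "Monocytes": "monocyte",
    "Macrophages M0": "macrophage",
    "Macrophages M1": "macrophage",
    "Macrophages M2": "macrophage",
    "Dendritic cells resting": "dendritic cell",
    "Dendritic cells activated": "dendritic cell",
    "Mast cells resting": "other myeloid",
    "Mast cells activated": "other myeloid",
    "Eosinophils": "other myeloid",
    "Neutrophils": "neutrophil",
}


class SignatureFormatError(ValueError):
    """The file is not a valid binary signature matrix."""


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class SignatureMatrix:
    """Binary gene × cell-type marker membership matrix.

    Parameters
    ----------
    genes
        Ordered gene symbols, unique after whitespace-stripping and case
        normalization (length G).
    types
        Ordered cell-type column labels (length K).
    values
        G × K matrix with entries strictly in {0, 1}.
    """

    genes: list[str]
    types: list[str]
    values: np.ndarray

    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        G, K = self.values.shape
        if len(self.genes) != G or len(self.types) != K:
            raise SignatureFormatError(
                f"matrix is {G}x{K} but {len(self.genes)} genes and "
                f"{len(self.types)} types were given"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SignatureFormatError(
                f"non-binary entry {self.values[i, j]!r} at gene "
                f"{self.genes[i]!r}, column {self.types[j]!r}"
            )
        self.values = self.values.astype(np.int8)
        canon = [_canon(g) for g in self.genes]
        if len(set(canon)) != len(canon):
            seen: set[str] = set()
            dup = next(c for c in canon if c in seen or seen.add(c))
            raise SignatureFormatError(f"duplicate gene symbol {dup!r}")
        empty = np.flatnonzero(self.values.sum(axis=0) == 0)
        if empty.size:
            raise SignatureFormatError(
                f"column {self.types[empty[0]]!r} has no marker genes"
            )
        self._gene_index = {c: i for i, c in enumerate(canon)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_types(self) -> int:
        return len(self.types)

    def marker_count(self, type_label: str) -> int:
        """Number of genes marked 1 in the profile of ``type_label``."""
        try:
            j = self.types.index(type_label)
        except ValueError:
            raise KeyError(f"unknown signature type {type_label!r}") from None
        return int(self.values[:, j].sum())

    def gene_positions(self, symbols: list[str]) -> np.ndarray:
        """Position of each symbol in this signature's gene order, -1 if absent.

        Matching is case-insensitive with surrounding whitespace stripped.
        """
        return np.array(
            [self._gene_index.get(_canon(s), -1) for s in symbols], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.types)


def profile_marker_count(sig: SignatureMatrix, type_label: str) -> int:
    """Number of 1-entries in the column ``type_label`` of ``sig``."""
    return sig.marker_count(type_label)


@dataclass(frozen=True)
class CategoryMap:
    """Total map from signature column labels to output categories."""

    mapping: Mapping[str, str]

    def __call__(self, type_label: str) -> str:
        return self.category_of(type_label)

    def category_of(self, type_label: str) -> str:
        try:
            return self.mapping[type_label]
        except KeyError:
            raise KeyError(f"no category for signature type {type_label!r}") from None

    def validate_total(self, sig: SignatureMatrix) -> None:
        """Raise if any column of ``sig`` lacks a category."""
        missing = [t for t in sig.types if t not in self.mapping]
        if missing:
            raise KeyError(f"signature types without a category: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryMap":
        """Load an override map from a two-column TSV (type_label, category)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["type", "category"])
        bad = sorted(set(df["category"]) - set(CATEGORIES))
        if bad:
            raise ValueError(f"unknown categories in map file: {bad}")
        return cls(dict(zip(df["type"], df["category"])))


DEFAULT_CATEGORY_MAP = CategoryMap(_DEFAULT_MAP)


def map_to_category(cmap: CategoryMap, type_label: str) -> str:
    """Output category for a signature column label under ``cmap``."""
    return cmap.category_of(type_label)


def load_signature(path: str | Path, dialect: str = "binary-tsv") -> SignatureMatrix:
    """Load a binarized signature matrix from TSV.

    Expected layout: a header row ``gene<TAB>Type1...TypeK`` followed by one
    row per gene, ``SYMBOL<TAB>0/1...``.  Entries must parse exactly as 0 or
    1; duplicate gene symbols and marker-free columns are rejected.
    """
    if dialect != "binary-tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise SignatureFormatError(f"{path}: no type columns found")
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        raw = df[col].str.strip()
        ok = raw.isin(("0", "1"))
        if not ok.all():
            gene = df.index[int(np.flatnonzero(~ok.to_numpy())[0])]
            raise SignatureFormatError(
                f"{path}: non-binary entry {raw[~ok].iloc[0]!r} at gene "
                f"{gene!r}, column {col!r}"
            )
        values[:, j] = raw.astype(np.int8)
    return SignatureMatrix(
        genes=[str(g) for g in df.index], types=[str(t) for t in df.columns],
        values=values,
    )


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    """Write ``sig`` in the TSV layout accepted by :func:`load_signature`."""
    df = sig.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def binarize_signature(continuous: pd.DataFrame) -> SignatureMatrix:
    """Binarize a continuous gene × type signature by row-maximum membership.

    Gene g is marked 1 for type k iff k attains the maximum of row g (ties
    mark every maximizing type).  This is a pragmatic stand-in rule for users
    holding the continuous LM22: the published binarization rule for it is
    not public, so matrices binarized upstream are the canonical input.
    """
    arr = continuous.to_numpy(dtype=float)
    values = (arr == arr.max(axis=1, keepdims=True)).astype(np.int8)
    return SignatureMatrix(
        genes=[str(g) for g in continuous.index],
        types=[str(t) for t in continuous.columns],
        values=values,
    )
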