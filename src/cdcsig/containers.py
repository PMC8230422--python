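"""Core in-memory containers shared by every pipeline stage.

The common currency is :class:`ExpressionMatrix`: a gene-by-sample matrix of
log2 intensities/abundances with per-sample annotations (dataset of origin and
histology/class label). :class:`CountMatrix` specializes it for raw RNA-seq
counts and carries the per-sample library sizes and TMM normalization factors.
Gene signatures and pathway collections are held as :class:`GeneSet` /
:class:`GeneSetCollection` (GMT-backed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns. Values are log2 intensities/abundances unless the object is a
        :class:`CountMatrix`.
    sample_info
        Optional per-sample annotation table indexed by sample identifier.
        Recognized columns are ``dataset`` and ``class_label``; extra columns
        are carried along untouched.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.sample_info is not None:
            missing = self.values.columns.difference(self.sample_info.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from sample_info: {list(missing[:5])}"
                )
            self.sample_info = self.sample_info.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_labels(self) -> pd.Series:
        if self.sample_info is None or "class_label" not in self.sample_info:
            raise ValueError("matrix has no class_label annotation")
        return self.sample_info["class_label"]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(self.values.loc[genes], self.sample_info)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        info = None if self.sample_info is None else self.sample_info.loc[samples]
        return ExpressionMatrix(self.values.loc[:, samples], info)

    def copy(self) -> "ExpressionMatrix":
        info = None if self.sample_info is None else self.sample_info.copy()
        return ExpressionMatrix(self.values.copy(), info)


@dataclass
class CountMatrix(ExpressionMatrix):
    """Non-negative integer count matrix with library sizes and TMM factors.

    ``norm_factors`` default to 1 for every sample; :func:`cdcsig.io_prep.tmm_factors`
    fills them in. ``gene_lengths`` (kilobases) are only needed for FPKM.
    """

    norm_factors: pd.Series | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.samples)
        else:
            self.norm_factors = self.norm_factors.reindex(self.samples)
            if self.norm_factors.isna().any():
                raise ValueError("norm_factors missing for some samples")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.genes)

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class GeneSet:
    """A named gene list, optionally directional (up/down)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    direction: str | None = None  # "up" | "down" | None

    def __post_init__(self) -> None:
        # silently deduplicate, preserving order; callers that need to count
        # duplicates (the GMT reader) do so before construction
        seen: dict[str, None] = dict.fromkeys(self.genes)
        object.__setattr__(self, "genes", tuple(seen))
        if self.direction not in (None, "up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        uni = set(universe)
        return GeneSet(
            self.name,
            tuple(g for g in self.genes if g in uni),
            self.description,
            self.direction,
        )


class GeneSetCollection:
    """Ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out.update(s.genes)
        return out

    def filter_by_size(
        self, universe: Iterable[str], min_size: int, max_size: int
    ) -> "GeneSetCollection":
        uni = set(universe)
        kept = []
        for s in self:
            inter = s.intersect(uni)
            if min_size <= len(inter) <= max_size:
                kept.append(inter)
        return GeneSetCollection(kept)
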