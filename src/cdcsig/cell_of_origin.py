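"""Mapping bulk tumor profiles onto single-cell reference cell types.

For each bulk sample, expression is z-scored per gene across bulk samples and
Pearson-correlated with every cell of a labeled single-cell reference over the
most variable single-cell genes. Summarizing each cell type by the median
correlation across its cells gives a sample-by-type similarity matrix; the
argmax per sample is the putative cell of origin. Single-cell values are used
as provided (log-normalized); only the bulk side is standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeCorrelation",
    "select_variable_genes",
    "bulk_cell_correlation",
    "assign_origin",
]


@dataclass
class CellTypeCorrelation:
    """Bulk-sample by cell-type matrix of median Pearson correlations."""

    median_r: pd.DataFrame  # samples x cell types
    genes_used: pd.Index
    n_cells_excluded: int = 0
    tie_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        r = self.median_r.to_numpy()
        finite = r[np.isfinite(r)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise AssertionError("correlation outside [-1, 1]")


def select_variable_genes(cell_matrix: ExpressionMatrix, n_top: int = 5000) -> list[str]:
    """Top ``n_top`` genes by variance across all cells (pooled over types).

    Ties are broken deterministically by gene identifier; a fully constant
    matrix is allowed but logged.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > cell_matrix.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    var = cell_matrix.values.var(axis=1, ddof=1)
    if (var == 0).all():
        logger.warning("select_variable_genes: all genes constant; order is by identifier")
    order = sorted(cell_matrix.genes, key=lambda g: (-var[g], g))
    return order[:n_top]


def bulk_cell_correlation(
    bulk_matrix: ExpressionMatrix,
    cell_matrix: ExpressionMatrix,
    cell_labels: pd.Series,
    genes: Sequence[str] | None = None,
    n_top: int = 5000,
    min_genes_warn: int = 100,
) -> CellTypeCorrelation:
    """Median Pearson correlation of each bulk sample with each cell type.

    ``genes`` defaults to :func:`select_variable_genes` on the single-cell
    matrix. Bulk values are z-scored per gene across bulk samples first.
    Cells with zero variance over the used genes are excluded (counted);
    fewer than 3 informative genes makes a correlation undefined (NaN,
    excluded from the median).
    """
    if genes is None:
        genes = select_variable_genes(
            cell_matrix, min(n_top, cell_matrix.n_genes)
        )
    common = pd.Index(genes).intersection(bulk_matrix.genes).intersection(
        cell_matrix.genes
    )
    if len(common) == 0:
        raise ValueError("empty gene intersection between bulk and single-cell data")
    if len(common) < min_genes_warn:
        logger.warning("bulk_cell_correlation: only %d shared genes", len(common))
    if len(common) < 3:
        raise ValueError("need >= 3 shared genes for correlation")

    cell_labels = cell_labels.reindex(cell_matrix.samples)
    types = sorted(pd.unique(cell_labels.dropna()))
    if not types:
        raise ValueError("no labeled cells")
    for t in types:
        if (cell_labels == t).sum() == 0:
            raise ValueError(f"cell type {t!r} has no cells")

    b = bulk_matrix.values.loc[common].to_numpy(dtype=float)
    # z-score per gene across bulk samples (sample sd)
    mu = b.mean(axis=1, keepdims=True)
    sd = b.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    bz = (b - mu) / sd

    c = cell_matrix.values.loc[common].to_numpy(dtype=float)
    g = len(common)

    # Pearson over genes: standardize both sides over the gene axis
    def _std_cols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = x.mean(axis=0, keepdims=True)
        s = x.std(axis=0, ddof=1, keepdims=True)
        ok = s[0] > 0
        s = np.where(s == 0, 1.0, s)
        return (x - m) / s, ok

    bz_s, bulk_ok = _std_cols(bz)
    c_s, cell_ok = _std_cols(c)
    n_excluded = int((~cell_ok).sum())
    if n_excluded:
        logger.warning("bulk_cell_correlation: %d zero-variance cells excluded", n_excluded)
    r = (bz_s.T @ c_s) / (g - 1)  # samples x cells
    r[~bulk_ok, :] = np.nan
    r[:, ~cell_ok] = np.nan

    med = pd.DataFrame(index=bulk_matrix.samples, columns=types, dtype=float)
    for t in types:
        cols = (cell_labels == t).to_numpy()
        med[t] = np.nanmedian(np.where(r[:, cols] == r[:, cols], r[:, cols], np.nan), axis=1)
    return CellTypeCorrelation(med, common, n_excluded)


def assign_origin(corr: CellTypeCorrelation) -> pd.Series:
    """Top cell type per bulk sample (row argmax; ties to the first type name,
    flagged in ``corr.tie_flags``)."""
    med = corr.median_r
    if med.isna().all(axis=1).any():
        raise ValueError("a sample has no defined correlation with any type")
    # idxmax on column-name-sorted frame breaks ties by type name order
    ordered = med[sorted(med.columns)]
    top = ordered.idxmax(axis=1)
    row_max = ordered.max(axis=1)
    ties = (ordered.eq(row_max, axis=0)).sum(axis=1) > 1
    corr.tie_flags = ties
    if ties.any():
        logger.warning("assign_origin: %d samples had tied top types", int(ties.sum()))
    return top.rename("cell_of_origin")
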