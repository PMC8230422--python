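"""Rank-based single-sample signature scoring and per-cell recovery-curve AUC.

The single-sample score ranks all measured genes within one sample (average
ranks for ties) and takes the mean rank of the signature genes, normalized by
its attainable range and centered at zero:

    raw        = mean(set ranks) / n
    normalized = (raw - (m+1)/(2n)) / ((2n-m+1)/(2n) - (m+1)/(2n))
    score      = normalized - 0.5            in [-0.5, +0.5]

where n is the number of measured genes and m the number of signature genes
present. A down-set is scored the same way on descending ranks; the
bidirectional total (up + down) lies in [-1, +1]. Because only ranks enter,
the score is invariant to any strictly increasing transform of a sample's
values — the property that makes it stable across heterogeneous datasets.

The per-cell activity score is a recovery-curve AUC: genes are ranked by
expression within each cell and the cumulative count of signature genes among
the top-ranked fraction is integrated and normalized by its maximum. Empirical
significance comes from random gene sets of the same size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection
from .diffexpr import DEResult, fit_linear_de

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "RecoveryAUCResult",
    "NullDistribution",
    "singscore",
    "score_collection",
    "select_all_pairs_sets",
    "recovery_auc",
    "random_set_null",
    "compare_score_groups",
]


@dataclass
class ScoreResult:
    """Per-sample signature scores with their theoretical bounds."""

    scores: pd.Series
    set_name: str
    mode: str  # "up" | "bidirectional"
    bounds: tuple[float, float]
    n_genes_used: pd.Series | None = None
    n_missing: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        s = self.scores.to_numpy()
        if (s < lo - 1e-12).any() or (s > hi + 1e-12).any():
            raise AssertionError("score outside theoretical bounds")


@dataclass
class RecoveryAUCResult:
    """Per-cell recovery-curve AUC in [0, 1]."""

    auc: pd.Series
    top_fraction: float
    set_name: str

    def __post_init__(self) -> None:
        a = self.auc.to_numpy()
        if (a < -1e-12).any() or (a > 1 + 1e-12).any():
            raise AssertionError("recovery AUC outside [0, 1]")


@dataclass
class NullDistribution:
    """Recovery-AUC values of random same-size gene sets (sets x cells)."""

    auc: pd.DataFrame  # one row per random set
    set_size: int
    n_sets: int
    seed: int

    def percentile(self, q: float, per_cell: bool = True) -> pd.Series | float:
        if per_cell:
            return self.auc.quantile(q / 100.0)
        return float(np.quantile(self.auc.to_numpy().ravel(), q / 100.0))


# ---------------------------------------------------------------------------
# singscore
# ---------------------------------------------------------------------------

def _directional_score(ranks: np.ndarray, set_rows: np.ndarray, n: int) -> np.ndarray:
    """Centered mean-normalized-rank score for one direction; ranks are n x samples."""
    m = set_rows.size
    raw = ranks[set_rows].mean(axis=0) / n
    lo = (m + 1) / (2.0 * n)
    hi = (2.0 * n - m + 1) / (2.0 * n)
    return (raw - lo) / (hi - lo) - 0.5


def singscore(
    matrix: ExpressionMatrix,
    up_set: GeneSet | Sequence[str],
    down_set: GeneSet | Sequence[str] | None = None,
) -> ScoreResult:
    """Rank-based single-sample score of a signature.

    Up-only scores lie in [-0.5, 0.5]; with a down-set the total (up-score on
    ascending ranks plus down-score on descending ranks) lies in [-1, 1].
    Signature genes absent from the matrix are dropped with a logged warning.
    """
    up_genes = tuple(up_set.genes if isinstance(up_set, GeneSet) else up_set)
    name = up_set.name if isinstance(up_set, GeneSet) else "signature"
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    up_rows = np.array([gene_pos[g] for g in up_genes if g in gene_pos], dtype=int)
    n_missing = len(up_genes) - up_rows.size
    if up_rows.size == 0:
        raise ValueError("no up-set gene present in the matrix")
    n = matrix.n_genes
    if up_rows.size == n:
        raise ValueError("signature covers the entire matrix")
    if n_missing:
        logger.warning("singscore: %d signature genes absent from the matrix", n_missing)

    vals = matrix.values.to_numpy(dtype=float)
    asc_ranks = rankdata(vals, axis=0)  # average ranks, ascending
    score = _directional_score(asc_ranks, up_rows, n)
    mode, bounds = "up", (-0.5, 0.5)
    used = pd.Series(up_rows.size, index=matrix.samples)

    if down_set is not None:
        down_genes = tuple(
            down_set.genes if isinstance(down_set, GeneSet) else down_set
        )
        down_rows = np.array(
            [gene_pos[g] for g in down_genes if g in gene_pos], dtype=int
        )
        n_missing += len(down_genes) - down_rows.size
        if down_rows.size == 0:
            raise ValueError("no down-set gene present in the matrix")
        desc_ranks = n + 1 - asc_ranks
        score = score + _directional_score(desc_ranks, down_rows, n)
        mode, bounds = "bidirectional", (-1.0, 1.0)

    return ScoreResult(
        pd.Series(score, index=matrix.samples, name=name),
        name, mode, bounds, used, n_missing,
    )


def score_collection(
    matrix: ExpressionMatrix, collection: GeneSetCollection
) -> pd.DataFrame:
    """Score every set of a collection; returns a set-by-sample matrix."""
    if len(collection) == 0:
        raise ValueError("empty collection")
    rows, names = [], []
    n_skipped = 0
    for s in collection:
        try:
            rows.append(singscore(matrix, s).scores)
            names.append(s.name)
        except ValueError:
            n_skipped += 1
    if not rows:
        raise ValueError("no set overlaps the matrix genes")
    if n_skipped:
        logger.warning("score_collection: %d sets had no overlap and were skipped", n_skipped)
    return pd.DataFrame(rows, index=pd.Index(names, name="set"))


def select_all_pairs_sets(
    score_matrix: pd.DataFrame,
    labels: pd.Series,
    target_class: str,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Sets consistently up- or downregulated in the target class versus every
    other class (moderated-t on the score matrix, one contrast per other class).

    Returns a table with one row per selected set and its direction.
    """
    labels = labels.reindex(score_matrix.columns)
    others = [c for c in pd.unique(labels) if c != target_class]
    if not others:
        raise ValueError("target class is the only class")
    score_em = ExpressionMatrix(score_matrix)
    keep_up = pd.Series(True, index=score_matrix.index)
    keep_down = pd.Series(True, index=score_matrix.index)
    for other in others:
        res: DEResult = fit_linear_de(score_em, labels, (target_class, other))
        sig = res.table["fdr"] < fdr_threshold
        keep_up &= sig & (res.table["log_fc"] > 0)
        keep_down &= sig & (res.table["log_fc"] < 0)
    out = pd.DataFrame(index=score_matrix.index)
    out["direction"] = np.where(keep_up, "up", np.where(keep_down, "down", "ns"))
    return out[out["direction"] != "ns"]


# ---------------------------------------------------------------------------
# Recovery-curve AUC
# ---------------------------------------------------------------------------

def _auc_for_positions(positions: np.ndarray, m: int, top: int) -> float:
    """AUC from 0-based ranked positions of the set genes within one cell."""
    pos = positions[positions < top]
    # hits(k) summed over k = 1..top: each hit at 0-based position p contributes
    # to hits(k) for all k >= p+1, i.e. (top - p) times.
    numer = float(np.sum(top - pos))
    denom = float(sum(min(k, m) for k in range(1, top + 1)))
    return numer / denom


def recovery_auc(
    cell_matrix: ExpressionMatrix,
    gene_set: GeneSet | Sequence[str],
    top_fraction: float = 0.05,
) -> RecoveryAUCResult:
    """Per-cell gene-set activity as the normalized recovery-curve area.

    Genes are ranked by expression descending within each cell; ties are
    resolved deterministically by gene-identifier order at the cut. With
    T = ceil(top_fraction * n) genes inspected and m set genes present,

        AUC = sum_{k=1..T} hits(k) / sum_{k=1..T} min(k, m).
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    genes = tuple(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "set"
    present = np.array([g in set(genes) for g in cell_matrix.genes])
    m = int(present.sum())
    if m == 0:
        raise ValueError("no set gene present in the matrix")
    n = cell_matrix.n_genes
    top = math.ceil(top_fraction * n)

    # deterministic ordering: expression descending, then identifier ascending
    id_rank = np.argsort(np.argsort(cell_matrix.genes.to_numpy()))
    vals = cell_matrix.values.to_numpy(dtype=float)
    aucs = np.empty(cell_matrix.n_samples)
    for j in range(cell_matrix.n_samples):
        order = np.lexsort((id_rank, -vals[:, j]))
        positions = np.flatnonzero(present[order])
        aucs[j] = _auc_for_positions(positions, m, top)
    return RecoveryAUCResult(
        pd.Series(aucs, index=cell_matrix.samples, name=name), top_fraction, name
    )


def random_set_null(
    cell_matrix: ExpressionMatrix,
    set_size: int,
    n_sets: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> NullDistribution:
    """Recovery-AUC null from uniformly random gene sets of a fixed size."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    n = cell_matrix.n_genes
    if set_size >= n:
        raise ValueError("set_size must be smaller than the gene universe")
    rng = np.random.default_rng(seed)
    genes = cell_matrix.genes.to_numpy()
    rows = []
    for _ in range(n_sets):
        pick = genes[rng.choice(n, size=set_size, replace=False)]
        rows.append(recovery_auc(cell_matrix, tuple(pick), top_fraction).auc)
    return NullDistribution(
        pd.DataFrame(rows, index=pd.RangeIndex(n_sets, name="null_set")),
        set_size, n_sets, seed,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_score_groups(
    scores: pd.Series,
    group_labels: pd.Series,
    reference_group: str,
) -> pd.DataFrame:
    """Two-sided rank-sum of the reference group versus every other group."""
    group_labels = group_labels.reindex(scores.index)
    ref = scores[group_labels == reference_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    rows = []
    for grp in pd.unique(group_labels):
        if grp == reference_group:
            continue
        other = scores[group_labels == grp]
        if len(other) < 2 or len(ref) < 2:
            raise ValueError(f"group {grp!r} or reference has < 2 members")
        stat, p = mannwhitneyu(
            ref, other, alternative="two-sided", method="asymptotic"
        )
        rows.append({"group": grp, "stat": stat, "p_value": p,
                     "median_diff": float(ref.median() - other.median())})
    if not rows:
        raise ValueError("no group other than the reference")
    return pd.DataFrame(rows).set_index("group")
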