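"""Multi-method consensus clustering of tumor samples, subtype markers, and a
permutation-based subtype-correspondence test.

The consensus scheme clusters the samples once per combination of (number of
top-variable genes, gene-variability metric, base clustering algorithm) and
records, for every sample pair, the fraction of combinations that co-cluster
them (the consensus matrix). The final partition at each k cuts the
average-linkage dendrogram of (1 - consensus); k is chosen by the mean
silhouette width on consensus distances, with ties going to the smaller k.

Correspondence between subtypes of two cohorts is tested by scoring cohort B
samples with cohort A's subtype marker sets (rank-based single-sample score)
and comparing the mean score of each B subtype against the rest, with a label
permutation null and Bonferroni adjustment over all subtype pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection
from .diffexpr import fit_linear_de
from .scoring import singscore

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusConfig",
    "ConsensusResult",
    "CorrespondenceResult",
    "consensus_cluster",
    "subtype_markers",
    "subtype_correspondence",
]


@dataclass
class ConsensusConfig:
    """Grid of feature counts, variability metrics and base algorithms.

    Defaults follow common practice for small cohorts: the top 1000-5000 most
    variable genes (step 1000, capped at the matrix size), four variability
    metrics (sd, median absolute deviation, coefficient of variation and the
    mean-absolute-correlation "ability to correlate" measure) and three base
    algorithms (Ward hierarchical, k-means, partitioning around medoids), with
    k from 2 to 4.
    """

    top_n_grid: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000)
    metrics: tuple[str, ...] = ("sd", "mad", "cv", "atc")
    algorithms: tuple[str, ...] = ("ward", "kmeans", "pam")
    k_range: tuple[int, ...] = (2, 3, 4)
    kmeans_restarts: int = 25
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if not self.top_n_grid or not self.metrics or not self.algorithms:
            raise ValueError("grids must be non-empty")
        if min(self.k_range) < 2 or max(self.k_range) > n_samples - 1:
            raise ValueError("k range must lie within [2, n_samples - 1]")


@dataclass
class ConsensusResult:
    """Consensus matrices, partitions and stability metrics per k."""

    consensus: dict[int, pd.DataFrame]
    partitions: dict[int, pd.Series]
    silhouette: dict[int, float]
    ambiguous_fraction: dict[int, float]  # proportion of pairs in (0.1, 0.9)
    chosen_k: int

    @property
    def partition(self) -> pd.Series:
        return self.partitions[self.chosen_k]


# ---------------------------------------------------------------------------
# Gene variability metrics
# ---------------------------------------------------------------------------

def _metric_scores(vals: np.ndarray, metric: str) -> np.ndarray:
    if metric == "sd":
        return vals.std(axis=1, ddof=1)
    if metric == "mad":
        med = np.median(vals, axis=1, keepdims=True)
        return np.median(np.abs(vals - med), axis=1)
    if metric == "cv":
        mean = vals.mean(axis=1)
        s0 = max(float(np.quantile(mean, 0.10)), 0.0)
        denom = mean + s0
        score = np.where(denom > 1e-8, vals.std(axis=1, ddof=1) / denom, -np.inf)
        return score
    if metric == "atc":
        return _atc_scores(vals)
    raise ValueError(f"unknown variability metric {metric!r}")


def _atc_scores(vals: np.ndarray, max_partners: int = 1000) -> np.ndarray:
    """"Ability to correlate": mean absolute Pearson correlation of each gene
    to the other genes (area above the sorted-|r| curve). Correlations are
    computed against an evenly spaced gene subsample when the matrix is large.
    """
    n_genes = vals.shape[0]
    sd = vals.std(axis=1, ddof=1)
    ok = sd > 0
    z = np.zeros_like(vals)
    z[ok] = (vals[ok] - vals[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    if n_genes > max_partners:
        partners = np.linspace(0, n_genes - 1, max_partners).astype(int)
    else:
        partners = np.arange(n_genes)
    corr = np.abs(z @ z[partners].T) / (vals.shape[1] - 1)
    # remove self-correlation contribution where the gene is its own partner
    self_mask = partners[None, :] == np.arange(n_genes)[:, None]
    counts = (~self_mask).sum(axis=1)
    corr[self_mask] = 0.0
    return corr.sum(axis=1) / np.maximum(counts, 1)


# ---------------------------------------------------------------------------
# Base clustering algorithms
# ---------------------------------------------------------------------------

def _pam(x: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Deterministic partitioning around medoids (BUILD + greedy SWAP)."""
    d = squareform(pdist(x))
    n = x.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dmin = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(dmin - d[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    cost = d[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                trial_cost = d[:, trial].min(axis=1).sum()
                if trial_cost < cost - 1e-12:
                    medoids, cost, improved = trial, trial_cost, True
        if not improved:
            break
    return np.argmin(d[:, medoids], axis=1)


def _cluster(x: np.ndarray, k: int, algorithm: str, seed: int, restarts: int) -> np.ndarray:
    if algorithm == "ward":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    if algorithm == "kmeans":
        return KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit_predict(x)
    if algorithm == "pam":
        return _pam(x, k)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

def consensus_cluster(
    matrix: ExpressionMatrix, config: ConsensusConfig | None = None
) -> ConsensusResult:
    """Consensus partitioning of samples over a grid of feature selections and
    base algorithms.

    The consensus entry (i, j) at each k is the fraction of grid combinations
    placing samples i and j in the same cluster. The reported partition cuts
    the average-linkage tree of (1 - consensus) at k clusters.
    """
    config = config or ConsensusConfig()
    n = matrix.n_samples
    config.validate(n)
    if n < 2 * max(config.k_range):
        raise ValueError("need n_samples >= 2 * max(k)")
    vals = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("matrix must be finite")
    if np.allclose(vals, vals[:, [0]]):
        raise ValueError("degenerate input: all samples identical")

    scores = {m: _metric_scores(vals, m) for m in config.metrics}
    gene_order = {
        m: np.lexsort((matrix.genes.to_numpy(), -s)) for m, s in scores.items()
    }
    combos = list(
        itertools.product(config.top_n_grid, config.metrics, config.algorithms)
    )

    consensus, partitions, silh, pac = {}, {}, {}, {}
    for k in config.k_range:
        co = np.zeros((n, n))
        for top_n, metric, algo in combos:
            sel = gene_order[metric][: min(top_n, matrix.n_genes)]
            x = vals[sel].T  # samples as points
            labels = _cluster(x, k, algo, config.seed, config.kmeans_restarts)
            co += labels[:, None] == labels[None, :]
        co /= len(combos)
        cons = pd.DataFrame(co, index=matrix.samples, columns=matrix.samples)
        dist = 1.0 - co
        np.fill_diagonal(dist, 0.0)
        part = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        ).fit_predict(dist)
        consensus[k] = cons
        partitions[k] = pd.Series(part, index=matrix.samples, name=f"k{k}")
        if len(np.unique(part)) > 1:
            silh[k] = float(silhouette_score(dist, part, metric="precomputed"))
        else:
            silh[k] = -1.0
        triu = co[np.triu_indices(n, k=1)]
        pac[k] = float(np.mean((triu > 0.1) & (triu < 0.9)))

    chosen = min(silh, key=lambda k: (-silh[k], k))
    return ConsensusResult(consensus, partitions, silh, pac, chosen)


# ---------------------------------------------------------------------------
# Subtype markers
# ---------------------------------------------------------------------------

def subtype_markers(
    matrix: ExpressionMatrix,
    partition: pd.Series,
    n_top: int = 150,
) -> dict[str, GeneSet]:
    """Top upregulated genes of each subtype versus the rest (moderated t)."""
    partition = partition.reindex(matrix.samples)
    out: dict[str, GeneSet] = {}
    for subtype in sorted(pd.unique(partition)):
        in_sub = partition == subtype
        if in_sub.sum() < 2:
            raise ValueError(f"subtype {subtype!r} has a single sample")
        labels = pd.Series(
            np.where(in_sub, "in", "rest"), index=matrix.samples
        )
        res = fit_linear_de(matrix, labels, ("in", "rest"))
        up = res.table[res.table["log_fc"] > 0].sort_values(
            "stat", ascending=False, kind="stable"
        )
        if len(up) < n_top:
            logger.warning(
                "subtype_markers: subtype %s has only %d upregulated genes",
                subtype, len(up),
            )
        name = f"subtype_{subtype}_markers"
        out[str(subtype)] = GeneSet(name, tuple(up.index[:n_top]), direction="up")
    return out


# ---------------------------------------------------------------------------
# Subtype correspondence
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceResult:
    """Permutation p-values for cohort-A markers enriched in cohort-B subtypes."""

    p_values: pd.DataFrame  # A subtype x B subtype, raw one-sided p
    adjusted: pd.DataFrame  # Bonferroni over all tested pairs
    statistic: pd.DataFrame  # mean score shift of each B subtype
    n_perm: int
    seed: int


def subtype_correspondence(
    markers_a: Mapping[str, GeneSet] | GeneSetCollection,
    cohort_b: ExpressionMatrix,
    labels_b: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrespondenceResult:
    """Test each (A-subtype marker set, B-subtype) pair for correspondence.

    The statistic is the mean single-sample marker score of the B-subtype
    samples minus the mean of the remaining B samples; the null shuffles the
    B labels ``n_perm`` times. One-sided p-values are Bonferroni-adjusted over
    all tested pairs.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(markers_a, GeneSetCollection):
        markers = {s.name: s for s in markers_a}
    else:
        markers = dict(markers_a)
    labels_b = labels_b.reindex(cohort_b.samples)
    b_types = sorted(pd.unique(labels_b.dropna()))
    if len(b_types) < 2:
        raise ValueError("cohort B needs >= 2 subtype labels")

    rng = np.random.default_rng(seed)
    lab_arr = labels_b.to_numpy()
    masks = {t: lab_arr == t for t in b_types}
    perms = [rng.permutation(lab_arr) for _ in range(n_perm)]

    stat = pd.DataFrame(index=list(markers), columns=b_types, dtype=float)
    pvals = pd.DataFrame(index=list(markers), columns=b_types, dtype=float)
    for a_name, gene_set in markers.items():
        sc = singscore(cohort_b, gene_set).scores.to_numpy()
        for t in b_types:
            mask = masks[t]
            obs = sc[mask].mean() - sc[~mask].mean()
            null = np.empty(n_perm)
            for i, perm in enumerate(perms):
                pm = perm == t
                null[i] = sc[pm].mean() - sc[~pm].mean()
            stat.loc[a_name, t] = obs
            pvals.loc[a_name, t] = (1 + np.sum(null >= obs)) / (1 + n_perm)
    n_pairs = pvals.size
    adjusted = (pvals * n_pairs).clip(upper=1.0)
    return CorrespondenceResult(pvals, adjusted, stat, n_perm, seed)
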