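"""Moderated differential expression and signature derivation.

The workhorse is a group-means linear model per gene with empirical-Bayes
variance moderation: residual variances are shrunk toward a common prior
s0^2 with prior degrees of freedom d0, both estimated by moment matching on
the log residual variances (digamma/trigamma matching). The moderated t
statistic uses the posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

on d0 + d degrees of freedom. As d0 -> 0 the moderated t reduces to the
ordinary t; as d0 -> infinity all variances collapse to s0^2.

On top of the per-gene fits the module implements:

* the tumor-specific signature rule — upregulated at least ``fc``-fold in the
  target tumor versus both the contrast tumor and normal tissue, below a
  smaller fold-change in the contrast-tumor-versus-normal comparison, and
  passing an overall ANOVA FDR gate;
* cross-dataset consensus gene calling (significant with a consistent sign in
  at least ``min_datasets`` of the supplied results);
* the single-cell Wilcoxon rank-sum marker test (one type versus the rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import f as f_dist
from scipy.stats import mannwhitneyu
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "DEResult",
    "PrecisionWeights",
    "bh_adjust",
    "fit_linear_de",
    "voom_weights",
    "derive_specific_signature",
    "core_consensus_genes",
    "rank_sum_markers",
]


@dataclass(frozen=True)
class DesignSpec:
    """Per-sample class labels plus the contrasts to fit.

    A contrast is a ``(treatment, reference)`` label pair; ``"anova"`` requests
    the overall F test across all labels.
    """

    labels: pd.Series
    contrasts: tuple = ()

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        for c in self.contrasts:
            if c == "anova":
                continue
            for lab in c:
                if counts.get(lab, 0) < 2:
                    raise ValueError(f"contrasted label {lab!r} has < 2 samples")


@dataclass
class DEResult:
    """Per-gene statistics for a single contrast (or overall ANOVA).

    ``table`` columns: ``log_fc`` (signed log2 difference of class means, NaN
    for ANOVA), ``stat`` (moderated t, or F for ANOVA), ``p_value``, ``fdr``.
    """

    table: pd.DataFrame
    contrast: str
    kind: str = "contrast"  # "contrast" | "anova"
    prior_df: float = np.nan
    prior_var: float = np.nan

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, fdr: float = 0.05, min_abs_log_fc: float = 0.0) -> pd.Index:
        t = self.table
        mask = t["fdr"] < fdr
        if min_abs_log_fc > 0:
            mask &= t["log_fc"].abs() >= min_abs_log_fc
        return t.index[mask]


@dataclass
class PrecisionWeights:
    """Per-(gene, sample) positive precision weights from a mean-variance trend."""

    weights: pd.DataFrame
    trend_x: np.ndarray = field(default_factory=lambda: np.array([]))
    trend_y: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be positive and finite")


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances.

    Zero variances are excluded from estimation. An infinite d0 estimate is
    truncated to 10x the median residual df so the posterior stays a proper
    mixture.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return 0.0, float(np.median(pos)) if pos.size else 0.0
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
    else:
        d0 = np.inf
    cap = 10.0 * df
    if not np.isfinite(d0) or d0 > cap:
        d0 = cap
    s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


# ---------------------------------------------------------------------------
# Linear model fit
# ---------------------------------------------------------------------------

def _group_fit(
    vals: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    weights: np.ndarray | None,
):
    """Weighted group-means fit. Returns (means, group weight sums, s2, df)."""
    n_genes, n_samples = vals.shape
    g = len(groups)
    w = np.ones_like(vals) if weights is None else weights
    means = np.empty((n_genes, g))
    wsums = np.empty((n_genes, g))
    fitted = np.empty_like(vals)
    for i, grp in enumerate(groups):
        cols = labels == grp
        wi = w[:, cols]
        wsum = wi.sum(axis=1)
        means[:, i] = (wi * vals[:, cols]).sum(axis=1) / wsum
        wsums[:, i] = wsum
        fitted[:, cols] = means[:, [i]]
    df = n_samples - g
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    rss = (w * (vals - fitted) ** 2).sum(axis=1)
    s2 = rss / df
    return means, wsums, s2, df


def fit_linear_de(
    matrix: ExpressionMatrix,
    labels: pd.Series | None = None,
    contrast: tuple[str, str] | str = "anova",
    weights: PrecisionWeights | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Per-gene (weighted) least squares with empirical-Bayes moderation.

    ``contrast=(a, b)`` tests a - b and reports the signed log2 fold change;
    ``contrast="anova"`` reports the overall moderated F across all labels.
    ``prior_df`` overrides the estimated prior degrees of freedom (0 recovers
    the ordinary t exactly; ``np.inf`` collapses all variances to s0^2, which
    is internally truncated to a large finite value).
    """
    if labels is None:
        labels = matrix.class_labels()
    labels = labels.reindex(matrix.samples)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    lab_arr = labels.to_numpy()
    groups = np.array(sorted(pd.unique(lab_arr)))
    counts = pd.Series(lab_arr).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples")

    vals = matrix.values.to_numpy(dtype=float)
    w = None
    if weights is not None:
        w = weights.weights.reindex(index=matrix.genes, columns=matrix.samples).to_numpy()
        if np.isnan(w).any():
            raise ValueError("weights not conformable with the matrix")

    means, wsums, s2, df = _group_fit(vals, lab_arr, groups, w)

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)  # infinite estimates already truncated
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    else:
        _, s02 = estimate_prior(s2, df)
        d0 = float(prior_df)  # explicit override is honored, including inf
    denom_df = d0 + df
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    elif d0 > 0:
        s2_post = (d0 * s02 + df * s2) / denom_df
    else:
        s2_post = s2.copy()

    if contrast == "anova":
        if len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 classes")
        grand = (wsums * means).sum(axis=1) / wsums.sum(axis=1)
        ss_between = (wsums * (means - grand[:, None]) ** 2).sum(axis=1)
        df1 = len(groups) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = (ss_between / df1) / s2_post
        fstat = np.where(s2_post == 0, np.where(ss_between > 0, np.inf, 0.0), fstat)
        p = f_dist.sf(fstat, df1, denom_df)
        p = np.where(np.isinf(fstat), 0.0, p)
        table = pd.DataFrame(
            {"log_fc": np.nan, "stat": fstat, "p_value": p, "fdr": bh_adjust(p)},
            index=matrix.genes,
        )
        return DEResult(table, "anova", "anova", d0, s02)

    a, b = contrast
    for lab in (a, b):
        if lab not in groups:
            raise ValueError(f"label {lab!r} not present")
    ia = int(np.where(groups == a)[0][0])
    ib = int(np.where(groups == b)[0][0])
    diff = means[:, ia] - means[:, ib]
    var_coef = 1.0 / wsums[:, ia] + 1.0 / wsums[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / np.sqrt(s2_post * var_coef)
    tstat = np.where(
        s2_post == 0, np.sign(diff) * np.where(diff != 0, np.inf, 0.0), tstat
    )
    p = 2.0 * t_dist.sf(np.abs(tstat), denom_df)
    p = np.where(np.isinf(tstat), 0.0, p)
    table = pd.DataFrame(
        {"log_fc": diff, "stat": tstat, "p_value": p, "fdr": bh_adjust(p)},
        index=matrix.genes,
    )
    return DEResult(table, f"{a}_vs_{b}", "contrast", d0, s02)


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------

def voom_weights(
    counts: CountMatrix,
    labels: pd.Series,
    span: float = 0.5,
    prior_count: float = 0.5,
    lib_offset: float = 1.0,
    min_genes: int = 10,
) -> PrecisionWeights:
    """Precision weights from the fitted mean-variance trend of log-CPM counts.

    Per gene a group-means fit yields residual standard deviations; their
    square roots are smoothed (lowess) against average log2 count, and each
    observation's weight is the inverse fourth power of the trend evaluated at
    its fitted log2 count.
    """
    if counts.n_genes < min_genes:
        raise ValueError(f"mean-variance trend needs >= {min_genes} genes")
    labels = labels.reindex(counts.samples)
    lab_arr = labels.to_numpy()
    groups = np.array(sorted(pd.unique(lab_arr)))
    if counts.n_samples <= len(groups):
        raise ValueError("fewer samples than design parameters")

    eff = counts.library_sizes.to_numpy(dtype=float) * counts.norm_factors.to_numpy()
    lcpm = np.log2(
        (counts.values.to_numpy(dtype=float) + prior_count) / (eff + lib_offset) * 1e6
    )
    means, _, s2, _df = _group_fit(lcpm, lab_arr, groups, None)
    fitted_lcpm = np.empty_like(lcpm)
    for i, grp in enumerate(groups):
        fitted_lcpm[:, lab_arr == grp] = means[:, [i]]

    log_lib = np.log2(eff + lib_offset)
    sx = lcpm.mean(axis=1) + np.mean(log_lib) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(s2))  # quarter-root variance = sqrt residual sd
    smooth = lowess(sy, sx, frac=span, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]

    fitted_count = fitted_lcpm + log_lib[None, :] - np.log2(1e6)
    pred = np.interp(fitted_count, xs, ys)  # constant beyond the range
    floor = max(np.min(ys[ys > 0], initial=1e-4), 1e-4)
    pred = np.clip(pred, floor, None)
    w = pred ** -4
    return PrecisionWeights(
        pd.DataFrame(w, index=counts.genes, columns=counts.samples), xs, ys
    )


# ---------------------------------------------------------------------------
# Signature derivation and consensus calling
# ---------------------------------------------------------------------------

def derive_specific_signature(
    de_tumor_vs_normal: DEResult,
    de_tumor_vs_other: DEResult,
    de_other_vs_normal: DEResult,
    anova: DEResult | None = None,
    fc_threshold: float = 2.0,
    other_fc_threshold: float = 1.5,
    anova_fdr: float = 0.25,
    name: str = "specific_signature",
) -> GeneSet:
    """Genes upregulated specifically in the target tumor class.

    A gene enters the signature when (i) the overall ANOVA FDR is below
    ``anova_fdr`` (gate skipped when no ANOVA result is supplied), (ii) its
    linear fold change is at least ``fc_threshold`` in both target-tumor
    contrasts, and (iii) its fold change in the other-tumor-versus-normal
    contrast stays below ``other_fc_threshold``. Thresholds are given on the
    linear scale as conventionally printed and converted to log2 internally.
    """
    gene_space = de_tumor_vs_normal.genes
    for other in (de_tumor_vs_other, de_other_vs_normal):
        if not gene_space.equals(other.genes):
            raise ValueError("DE results have mismatched gene spaces")
    if anova is not None and not gene_space.equals(anova.genes):
        raise ValueError("ANOVA result has a mismatched gene space")

    lfc = np.log2(fc_threshold)
    lfc_other = np.log2(other_fc_threshold)
    mask = (
        (de_tumor_vs_normal.table["log_fc"] >= lfc)
        & (de_tumor_vs_other.table["log_fc"] >= lfc)
        & (de_other_vs_normal.table["log_fc"] < lfc_other)
    )
    if anova is not None:
        mask &= anova.table["fdr"] < anova_fdr
    return GeneSet(name, tuple(gene_space[mask]), direction="up")


def core_consensus_genes(
    de_results: Sequence[DEResult],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    min_datasets: int = 3,
) -> tuple[GeneSet, GeneSet]:
    """Cross-dataset consensus up/down gene cores.

    A gene enters the up (down) core when it passes |FC| >= ``fc_threshold``
    and FDR < ``fdr_threshold`` with the same sign in at least
    ``min_datasets`` of the supplied results.
    """
    if len(de_results) < 2:
        raise ValueError("need >= 2 DE results")
    if min_datasets > len(de_results):
        raise ValueError("min_datasets exceeds the number of results")
    lfc = np.log2(fc_threshold)
    union = de_results[0].genes
    for r in de_results[1:]:
        union = union.union(r.genes)
    up_counts = pd.Series(0, index=union)
    down_counts = pd.Series(0, index=union)
    for r in de_results:
        t = r.table
        sig = t["fdr"] < fdr_threshold
        up = t.index[sig & (t["log_fc"] >= lfc)]
        down = t.index[sig & (t["log_fc"] <= -lfc)]
        up_counts.loc[up] += 1
        down_counts.loc[down] += 1
    up_core = union[(up_counts >= min_datasets).to_numpy()]
    down_core = union[(down_counts >= min_datasets).to_numpy()]
    return (
        GeneSet("consensus_up", tuple(up_core), direction="up"),
        GeneSet("consensus_down", tuple(down_core), direction="down"),
    )


# ---------------------------------------------------------------------------
# Single-cell rank-sum marker test
# ---------------------------------------------------------------------------

def rank_sum_markers(
    cell_matrix: ExpressionMatrix,
    cell_labels: pd.Series,
    target_type: str,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene: target cells vs all others.

    Uses the normal approximation with tie correction and continuity
    correction. Returns a table with columns ``log_fc`` (difference of means),
    ``stat`` (U), ``p_value`` and ``fdr``, sorted by p. A gene constant across
    all cells gets p = 1.
    """
    cell_labels = cell_labels.reindex(cell_matrix.samples)
    in_target = (cell_labels == target_type).to_numpy()
    if in_target.sum() < 3:
        raise ValueError(f"target type {target_type!r} has < 3 cells")
    if (~in_target).sum() < 1:
        raise ValueError("only one cell type present")

    vals = cell_matrix.values.to_numpy(dtype=float)
    x = vals[:, in_target]
    y = vals[:, ~in_target]
    n_genes = vals.shape[0]
    stat = np.empty(n_genes)
    p = np.empty(n_genes)
    for g in range(n_genes):
        row = vals[g]
        if np.ptp(row) == 0.0:  # all ties: no information
            stat[g] = x.shape[1] * y.shape[1] / 2.0
            p[g] = 1.0
            continue
        res = mannwhitneyu(
            x[g], y[g], alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        stat[g], p[g] = res.statistic, res.pvalue
    table = pd.DataFrame(
        {
            "log_fc": x.mean(axis=1) - y.mean(axis=1),
            "stat": stat,
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=cell_matrix.genes,
    )
    return table.sort_values("p_value", kind="stable")
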