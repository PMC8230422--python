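"""Pharmacotranscriptomic screening: correlate a signature score with drug AUC.

Each compound's area-under-dose-response-curve vector across cell lines (lower
AUC = more sensitive) is Spearman-correlated with the per-line single-sample
signature score. Compounds with a significantly negative correlation (BH FDR)
are candidate actives: lines expressing the signature more strongly are more
sensitive to them. Screens from independent panels can be intersected and
their correlation profiles compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from scipy.stats import permutation_test

from .containers import GeneSet
from .diffexpr import DEResult, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenResult",
    "screen",
    "cross_panel_concordance",
    "target_modulation",
]


@dataclass
class ScreenResult:
    """Per-compound Spearman screen results.

    ``table`` columns: ``rho``, ``p_value``, ``fdr``, ``n`` (cell lines used)
    and ``label`` (active: rho < 0 & FDR < threshold; inactive: rho > 0 &
    FDR < threshold; otherwise unlabeled).
    """

    table: pd.DataFrame
    fdr_threshold: float
    skipped: list[str] = field(default_factory=list)

    @property
    def active(self) -> pd.Index:
        return self.table.index[self.table["label"] == "active"]

    @property
    def inactive(self) -> pd.Index:
        return self.table.index[self.table["label"] == "inactive"]


def _spearman(score: np.ndarray, auc: np.ndarray, method: str) -> tuple[float, float]:
    rho, p = spearmanr(score, auc)
    if method == "exact" or (method == "auto" and score.size < 12):
        # exact permutation p for tiny n where the t-approximation is rough
        res = permutation_test(
            (score,),
            lambda x: spearmanr(x, auc).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        p = float(res.pvalue)
    return float(rho), float(p)


def screen(
    scores: pd.Series,
    responses: pd.DataFrame,
    min_lines: int = 20,
    fdr_threshold: float = 0.05,
    method: str = "asymptotic",
) -> ScreenResult:
    """Spearman correlation of signature score vs AUC, per compound.

    ``responses`` is compound-by-cell-line; missing entries are allowed and
    handled pairwise-complete. Compounds observed in fewer than ``min_lines``
    shared lines are skipped and reported. ``method`` selects the p-value
    computation: ``asymptotic`` (t-approximation, default), ``exact``
    (permutation) or ``auto`` (exact below n = 12).
    """
    shared = responses.columns.intersection(scores.index)
    if len(shared) == 0:
        raise ValueError("no shared cell lines between scores and responses")
    s_all = scores.loc[shared]
    if s_all.nunique() <= 1:
        raise ValueError("constant score vector")

    rows, skipped = [], []
    for compound, auc in responses.loc[:, shared].iterrows():
        mask = auc.notna() & s_all.notna()
        n = int(mask.sum())
        if n < min_lines:
            skipped.append(compound)
            continue
        rho, p = _spearman(
            s_all[mask].to_numpy(), auc[mask].to_numpy(dtype=float), method
        )
        rows.append({"compound": compound, "rho": rho, "p_value": p, "n": n})
    if not rows:
        raise ValueError("no compound passed the min_lines filter")
    table = pd.DataFrame(rows).set_index("compound")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["label"] = "unlabeled"
    table.loc[(table["rho"] < 0) & (table["fdr"] < fdr_threshold), "label"] = "active"
    table.loc[(table["rho"] > 0) & (table["fdr"] < fdr_threshold), "label"] = "inactive"
    if skipped:
        logger.warning("screen: %d compounds below min_lines skipped", len(skipped))
    return ScreenResult(table, fdr_threshold, skipped)


@dataclass
class ConcordanceResult:
    """Shared actives and correlation-profile agreement of two screens."""

    shared_compounds: pd.Index
    shared_active: pd.Index
    rho_concordance: float
    rho_concordance_p: float
    table: pd.DataFrame  # per shared compound: rho_a, rho_b, label_a, label_b


def cross_panel_concordance(
    a: ScreenResult,
    b: ScreenResult,
    name_map: Mapping[str, str] | None = None,
) -> ConcordanceResult:
    """Intersect two screens' active calls and correlate their rho profiles.

    Compound names are matched by exact lowercase comparison unless an
    explicit ``name_map`` (a-name -> b-name) is given.
    """
    ta, tb = a.table, b.table
    if name_map is None:
        b_by_lower = {str(c).lower(): c for c in tb.index}
        name_map = {
            c: b_by_lower[str(c).lower()]
            for c in ta.index
            if str(c).lower() in b_by_lower
        }
    pairs = [(ca, cb) for ca, cb in name_map.items() if ca in ta.index and cb in tb.index]
    if not pairs:
        raise ValueError("empty shared compound space")
    a_names = pd.Index([p[0] for p in pairs])
    b_names = pd.Index([p[1] for p in pairs])
    table = pd.DataFrame(
        {
            "rho_a": ta.loc[a_names, "rho"].to_numpy(),
            "rho_b": tb.loc[b_names, "rho"].to_numpy(),
            "label_a": ta.loc[a_names, "label"].to_numpy(),
            "label_b": tb.loc[b_names, "label"].to_numpy(),
        },
        index=a_names,
    )
    shared_active = table.index[
        (table["label_a"] == "active") & (table["label_b"] == "active")
    ]
    if len(table) >= 3:
        rho, p = spearmanr(table["rho_a"], table["rho_b"])
    else:
        rho, p = np.nan, np.nan
    return ConcordanceResult(a_names, shared_active, float(rho), float(p), table)


def target_modulation(
    de: DEResult,
    compound_targets: Mapping[str, Sequence[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Tumor-vs-normal modulation status of each compound's nominal targets.

    Status is ``up`` (logFC > 0, FDR < threshold), ``down`` (logFC < 0,
    FDR < threshold), ``ns`` otherwise, or ``missing`` when the target gene is
    absent from the DE table.
    """
    rows = []
    t = de.table
    for compound, targets in compound_targets.items():
        for gene in targets:
            if gene not in t.index:
                status, lfc, fdr = "missing", np.nan, np.nan
            else:
                lfc = float(t.loc[gene, "log_fc"])
                fdr = float(t.loc[gene, "fdr"])
                if fdr < fdr_threshold and lfc > 0:
                    status = "up"
                elif fdr < fdr_threshold and lfc < 0:
                    status = "down"
                else:
                    status = "ns"
            rows.append(
                {"compound": compound, "target": gene, "log_fc": lfc,
                 "fdr": fdr, "status": status}
            )
    return pd.DataFrame(rows).set_index(["compound", "target"])
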