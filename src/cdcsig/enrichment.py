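"""Over-representation analysis, preranked gene-set enrichment, and
kappa-similarity term networks.

Preranked enrichment uses the weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranked gene list, hitting a set gene adds
|r|^p / sum_set |r|^p and missing one subtracts 1/(n - m); the enrichment
score ES is the signed maximum excursion (positive = enrichment at the top of
the ranking). Significance comes from random same-size gene sets: NES is ES
divided by the mean |null ES| of matching sign, with p-values and FDR computed
within the sign-matched null pools.

Term grouping follows the enrichment-map idea: pairwise Cohen's kappa over
the binary gene-membership vectors, edges where kappa passes a threshold, and
communities by greedy modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSet, GeneSetCollection
from .diffexpr import bh_adjust

__all__ = [
    "ORAResult",
    "GSEAResult",
    "TermNetwork",
    "hypergeom_ora",
    "enrichment_score",
    "gsea_preranked",
    "kappa_matrix",
    "build_term_network",
]


@dataclass
class ORAResult:
    """Hypergeometric over-representation results, one row per term."""

    table: pd.DataFrame  # columns: k, n, K, N, p_value, fdr
    universe_size: int
    query_size: int


@dataclass
class GSEAResult:
    """Preranked enrichment results, one row per set."""

    table: pd.DataFrame  # columns: es, nes, p_value, fdr, size, leading_edge
    n_perm: int
    seed: int


@dataclass
class TermNetwork:
    """Kappa-similarity graph over enriched terms with community labels."""

    graph: nx.Graph
    clusters: pd.Series  # term -> cluster id
    threshold: float


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def hypergeom_ora(
    query: GeneSet | Sequence[str],
    annotation: GeneSetCollection,
    universe: Iterable[str],
) -> ORAResult:
    """Upper-tail hypergeometric test of each term against a query list.

    Terms are intersected with the universe; the query must be a subset of it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query.genes if isinstance(query, GeneSet) else query)
    if not q:
        raise ValueError("empty query")
    outside = q - uni
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    N, n = len(uni), len(q)
    rows = []
    for term in annotation:
        term_genes = set(term.genes) & uni
        K = len(term_genes)
        k = len(term_genes & q)
        # P(X >= k) under sampling n genes from N with K successes
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term.name, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    table = pd.DataFrame(rows).set_index("term")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    return ORAResult(table.sort_values("p_value", kind="stable"), N, n)


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked_abs_w: np.ndarray, hit_positions: np.ndarray, n: int
) -> float:
    """Signed maximum excursion of the weighted KS running sum.

    ``ranked_abs_w`` are |r|^p for the genes at ``hit_positions`` (0-based
    positions in the ranked list, sorted ascending). Extrema can only occur
    immediately before or after a hit, which is what is evaluated.
    """
    m = hit_positions.size
    if m == 0 or m == n:
        raise ValueError("set empty or covering the whole list")
    w = ranked_abs_w[hit_positions]
    total = w.sum()
    if total == 0:  # all-zero weights: fall back to unweighted steps
        w = np.ones(m)
        total = float(m)
    hit_cum = np.cumsum(w) / total
    miss_step = 1.0 / (n - m)
    j = np.arange(m)
    after = hit_cum - (hit_positions - j) * miss_step
    before = np.concatenate(([0.0], hit_cum[:-1])) - (hit_positions - j) * miss_step
    candidates = np.concatenate((after, before))
    # largest |excursion|; an exact tie between signs resolves to the positive one
    best = np.lexsort((candidates, np.abs(candidates)))[-1]
    return float(candidates[best])


def _leading_edge_size(
    ranked_abs_w: np.ndarray, hit_positions: np.ndarray, n: int, es: float
) -> int:
    """Number of set genes at or before the running-sum extremum."""
    m = hit_positions.size
    w = ranked_abs_w[hit_positions]
    total = w.sum() or float(m)
    hit_cum = np.cumsum(w) / total
    miss_step = 1.0 / (n - m)
    j = np.arange(m)
    after = hit_cum - (hit_positions - j) * miss_step
    if es >= 0:
        peak = int(np.argmax(after))
        return peak + 1
    before = np.concatenate(([0.0], hit_cum[:-1])) - (hit_positions - j) * miss_step
    trough = int(np.argmin(before))
    return m - trough


def gsea_preranked(
    ranked_stats: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    weight_p: float = 1.0,
    seed: int = 0,
) -> GSEAResult:
    """Preranked gene-set enrichment with a random-set permutation null.

    ``ranked_stats`` maps genes to a ranking statistic (e.g. a moderated t);
    genes are sorted descending (ties broken by identifier for determinism).
    Sets are intersected with the ranked genes and filtered to
    [``min_size``, ``max_size``].
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    stats = ranked_stats.astype(float)
    if not np.all(np.isfinite(stats.to_numpy())):
        raise ValueError("ranking statistics must be finite")
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    ranked_genes = pd.Index(order)
    n = len(ranked_genes)
    abs_w = np.abs(stats.loc[ranked_genes].to_numpy()) ** weight_p
    pos_of = {g: i for i, g in enumerate(ranked_genes)}

    sets = []
    for s in collection:
        hit = np.array(sorted(pos_of[g] for g in s.genes if g in pos_of), dtype=int)
        if hit.size == n and hit.size > 0:
            raise ValueError(f"set {s.name!r} covers the entire ranked list")
        if min_size <= hit.size <= max_size:
            sets.append((s.name, hit))
    if not sets:
        raise ValueError("no set within the size window overlaps the ranking")

    rng = np.random.default_rng(seed)
    rows = []
    null_by_name: dict[str, np.ndarray] = {}
    for name, hit in sets:
        es = enrichment_score(abs_w, hit, n)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = np.sort(rng.choice(n, size=hit.size, replace=False))
            null[b] = enrichment_score(abs_w, rand, n)
        null_by_name[name] = null
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "size": hit.size,
                "leading_edge": _leading_edge_size(abs_w, hit, n, es),
            }
        )
    table = pd.DataFrame(rows).set_index("set")

    # FDR from the sign-matched pools of null and observed NES
    null_nes = []
    for name, null in null_by_name.items():
        pos, neg = null[null >= 0], null[null < 0]
        nn = np.full_like(null, np.nan)
        if pos.size:
            nn[null >= 0] = pos / np.mean(np.abs(pos))
        if neg.size:
            nn[null < 0] = neg / np.mean(np.abs(neg))
        null_nes.append(nn)
    null_nes = np.concatenate(null_nes)
    null_nes = null_nes[np.isfinite(null_nes)]
    obs_nes = table["nes"].to_numpy()
    fdr = np.empty(len(table))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            fdr[i] = 1.0
            continue
        if nes >= 0:
            null_frac = np.mean(null_nes[null_nes >= 0] >= nes) if (null_nes >= 0).any() else 0.0
            obs_frac = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_frac = np.mean(null_nes[null_nes < 0] <= nes) if (null_nes < 0).any() else 0.0
            obs_frac = np.mean(obs_nes[obs_nes < 0] <= nes)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    table["fdr"] = fdr
    return GSEAResult(table.sort_values("p_value", kind="stable"), n_perm, seed)


# ---------------------------------------------------------------------------
# Kappa term network
# ---------------------------------------------------------------------------

def kappa_matrix(
    terms: GeneSetCollection, universe: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pairwise Cohen's kappa of term gene memberships over a universe.

    The universe defaults to the union of genes across the supplied terms.
    For terms A and B with joint membership counts n11, n10, n01, n00 over a
    universe of size N:

        po = (n11 + n00) / N
        pe = [(n11+n10)(n11+n01) + (n01+n00)(n10+n00)] / N^2
        kappa = (po - pe) / (1 - pe),  with kappa = 1 when pe = 1.
    """
    if len(terms) < 2:
        raise ValueError("need >= 2 terms")
    uni = sorted(universe) if universe is not None else sorted(terms.gene_universe())
    uni_pos = {g: i for i, g in enumerate(uni)}
    N = len(uni)
    names = terms.names
    M = np.zeros((len(names), N), dtype=bool)
    for i, s in enumerate(terms):
        for g in s.genes:
            if g not in uni_pos:
                raise ValueError(f"term {s.name!r} has gene {g!r} outside the universe")
            M[i, uni_pos[g]] = True

    Mf = M.astype(float)
    n11 = Mf @ Mf.T
    sizes = Mf.sum(axis=1)
    n10 = sizes[:, None] - n11
    n01 = sizes[None, :] - n11
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / N ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    kappa[pe >= 1.0 - 1e-15] = 1.0
    np.fill_diagonal(kappa, 1.0)
    return pd.DataFrame(kappa, index=names, columns=names)


def build_term_network(kappa: pd.DataFrame, threshold: float = 0.5) -> TermNetwork:
    """Graph over terms with edges at kappa >= threshold; greedy-modularity
    communities with deterministic ordering. Singleton terms keep their own
    cluster."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    terms = sorted(kappa.index)
    g.add_nodes_from(terms)
    k = kappa.to_numpy()
    names = list(kappa.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if k[i, j] >= threshold:
                g.add_edge(names[i], names[j], weight=float(k[i, j]))

    clusters = pd.Series(-1, index=pd.Index(terms, name="term"), dtype=int)
    next_id = 0
    # connected components with >1 node get community detection; isolates are singletons
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        if len(comp) == 1:
            clusters[next(iter(comp))] = next_id
            next_id += 1
            continue
        sub = g.subgraph(sorted(comp))
        comms = nx.community.greedy_modularity_communities(sub, weight="weight")
        for comm in sorted(comms, key=lambda c: sorted(c)[0]):
            for node in comm:
                clusters[node] = next_id
            next_id += 1
    return TermNetwork(g, clusters, threshold)
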