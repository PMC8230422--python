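"""ORA, preranked enrichment and kappa term networks against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdcsig import (
    GeneSet,
    GeneSetCollection,
    build_term_network,
    gsea_preranked,
    hypergeom_ora,
    kappa_matrix,
)
from cdcsig.enrichment import enrichment_score


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def _hyper_oracle(N, K, n, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestORA:
    def test_perfect_overlap_exact(self):
        uni = [f"u{i}" for i in range(10)]
        ann = GeneSetCollection([GeneSet("T", tuple(uni[:5]))])
        res = hypergeom_ora(tuple(uni[:5]), ann, uni)
        assert res.table["p_value"].iloc[0] == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_p_one(self):
        uni = [f"u{i}" for i in range(10)]
        ann = GeneSetCollection([GeneSet("T", tuple(uni[:5]))])
        res = hypergeom_ora(tuple(uni[5:]), ann, uni)
        assert res.table["k"].iloc[0] == 0
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_small_universe(self):
        # all (K, n, k) on universes N <= 12 against the combinatorial oracle
        for N in (6, 9, 12):
            uni = [f"u{i}" for i in range(N)]
            for K in (2, N // 2):
                for n in (2, N // 2):
                    for k in range(min(K, n) + 1):
                        query = uni[:k] + uni[K:K + (n - k)]
                        ann = GeneSetCollection([GeneSet("T", tuple(uni[:K]))])
                        res = hypergeom_ora(tuple(query), ann, uni)
                        assert res.table["p_value"].iloc[0] == pytest.approx(
                            _hyper_oracle(N, K, n, k), rel=1e-10), (N, K, n, k)

    def test_p_monotone_in_overlap(self):
        N, K, n = 20, 8, 8
        uni = [f"u{i}" for i in range(N)]
        ps = [_hyper_oracle(N, K, n, k) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_query_outside_universe_errors(self):
        ann = GeneSetCollection([GeneSet("T", ("a",))])
        with pytest.raises(ValueError):
            hypergeom_ora(("zz",), ann, ["a", "b"])


# ---------------------------------------------------------------------------
# Preranked enrichment
# ---------------------------------------------------------------------------

def _brute_es(weights, hit_mask):
    """Literal running-sum evaluation; extremum over every list position."""
    n = len(hit_mask)
    m = int(np.sum(hit_mask))
    nr = float(np.sum(weights[hit_mask]))
    if nr == 0:
        weights = np.ones(n)
        nr = float(m)
    run, candidates = 0.0, []
    for i in range(n):
        if hit_mask[i]:
            run += weights[i] / nr
        else:
            run -= 1.0 / (n - m)
        candidates.append(run)
    arr = np.array(candidates)
    order = np.lexsort((arr, np.abs(arr)))
    return float(arr[order[-1]])


class TestEnrichmentScore:
    def test_hand_worked_example(self):
        # stats (2, 1, -1), set = top gene: running sum (+1, +0.5, 0)
        es = enrichment_score(np.array([2.0, 1.0, 1.0]), np.array([0]), 3)
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_small_lists_match_brute_force(self):
        rng = np.random.default_rng(0)
        for n in range(3, 9):
            weights = np.abs(rng.normal(1, 0.5, n)) + 0.05
            for size in (1, 2, 3):
                for hits in itertools.combinations(range(n), size):
                    if size == n:
                        continue
                    mask = np.zeros(n, dtype=bool)
                    mask[list(hits)] = True
                    es = enrichment_score(weights, np.array(hits), n)
                    brute = _brute_es(weights, mask)
                    # on an exact tie between the positive and negative
                    # excursion the sign is decided within float noise, so
                    # compare signed values or magnitudes
                    assert (
                        es == pytest.approx(brute, abs=1e-9)
                        or abs(es) == pytest.approx(abs(brute), abs=1e-9)
                    ), (n, hits)

    def test_all_genes_set_errors(self):
        with pytest.raises(ValueError):
            enrichment_score(np.ones(4), np.arange(4), 4)


class TestGseaPreranked:
    def _ranked(self, seed=1, n=200):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(0, 1, n),
                         index=[f"g{i:03d}" for i in range(n)])

    def test_matches_external_reference_es(self):
        # cross-check ES against an independent implementation (gseapy)
        gseapy = pytest.importorskip("gseapy")
        stats_ = self._ranked(seed=2, n=80)
        genes = list(stats_.sort_values(ascending=False).index)
        sets = {"S1": genes[3:40:4], "S2": genes[10:70:3]}
        ref = gseapy.prerank(
            rnk=stats_.reset_index(), gene_sets=sets, permutation_num=10,
            min_size=3, max_size=80, seed=1, outdir=None, no_plot=True,
            threads=1,
        ).res2d.set_index("Term")
        col = GeneSetCollection(
            [GeneSet(k, tuple(v)) for k, v in sets.items()])
        mine = gsea_preranked(stats_, col, n_perm=10, min_size=3, max_size=80)
        for name in sets:
            assert mine.table.loc[name, "es"] == pytest.approx(
                float(ref.loc[name, "ES"]), abs=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        stats_ = self._ranked(seed=4, n=300)
        sets = [GeneSet(f"S{i}", tuple(rng.choice(stats_.index, 20,
                                                  replace=False)))
                for i in range(100)]
        res = gsea_preranked(stats_, GeneSetCollection(sets), n_perm=200,
                             min_size=15, max_size=500, seed=5)
        ks = stats.kstest(res.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_set_enriched(self):
        stats_ = self._ranked(seed=6, n=300).sort_values(ascending=False)
        planted = GeneSet("P", tuple(stats_.index[:20]))
        rng = np.random.default_rng(7)
        rand = GeneSet("R", tuple(rng.choice(stats_.index, 20, replace=False)))
        res = gsea_preranked(stats_, GeneSetCollection([planted, rand]),
                             n_perm=500, seed=8)
        assert res.table.loc["P", "es"] > 0.8
        assert res.table.loc["P", "p_value"] < 0.01
        assert np.sign(res.table.loc["P", "nes"]) == np.sign(
            res.table.loc["P", "es"])

    def test_size_window_and_n_perm_validation(self):
        stats_ = self._ranked()
        tiny = GeneSetCollection([GeneSet("T", ("g000", "g001"))])
        with pytest.raises(ValueError):
            gsea_preranked(stats_, tiny, min_size=15)  # nothing in window
        big = GeneSetCollection([GeneSet("B", tuple(stats_.index[:20]))])
        with pytest.raises(ValueError):
            gsea_preranked(stats_, big, n_perm=5)


# ---------------------------------------------------------------------------
# Kappa term network
# ---------------------------------------------------------------------------

class TestKappa:
    def test_analytic_cases(self):
        uni = [str(i) for i in range(1, 11)]
        identical = GeneSetCollection([
            GeneSet("A", tuple(uni[:5])), GeneSet("B", tuple(uni[:5]))])
        assert kappa_matrix(identical, uni).iloc[0, 1] == pytest.approx(1.0)
        disjoint = GeneSetCollection([
            GeneSet("A", tuple(uni[:5])), GeneSet("B", tuple(uni[5:]))])
        assert kappa_matrix(disjoint, uni).iloc[0, 1] == pytest.approx(-1.0)
        uni8 = [str(i) for i in range(1, 9)]
        half = GeneSetCollection([
            GeneSet("A", tuple(uni8[:4])), GeneSet("B", tuple(uni8[2:6]))])
        assert kappa_matrix(half, uni8).iloc[0, 1] == pytest.approx(0.0)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(9)
        uni = [f"x{i}" for i in range(30)]
        col = GeneSetCollection([
            GeneSet(f"T{i}", tuple(rng.choice(uni, 10, replace=False)))
            for i in range(5)])
        k = kappa_matrix(col, uni)
        assert np.allclose(k, k.T)
        assert np.allclose(np.diag(k), 1.0)
        relabel = {g: f"y{i}" for i, g in enumerate(uni)}
        col2 = GeneSetCollection([
            GeneSet(s.name, tuple(relabel[g] for g in s.genes)) for s in col])
        k2 = kappa_matrix(col2, [relabel[g] for g in uni])
        assert np.allclose(k, k2)

    def test_term_outside_universe_errors(self):
        col = GeneSetCollection([GeneSet("A", ("a",)), GeneSet("B", ("zz",))])
        with pytest.raises(ValueError):
            kappa_matrix(col, ["a", "b"])


class TestTermNetwork:
    def test_two_cliques_two_clusters(self):
        poolA = tuple(f"a{i}" for i in range(10))
        poolB = tuple(f"b{i}" for i in range(10))
        col = GeneSetCollection(
            [GeneSet(f"A{i}", poolA) for i in range(3)]
            + [GeneSet(f"B{i}", poolB) for i in range(3)])
        k = kappa_matrix(col)
        net = build_term_network(k, threshold=0.5)
        assert net.clusters.nunique() == 2
        assert net.clusters[["A0", "A1", "A2"]].nunique() == 1
        assert net.clusters[["B0", "B1", "B2"]].nunique() == 1

    def test_threshold_one_keeps_identical_terms_only(self):
        col = GeneSetCollection([
            GeneSet("A", ("x", "y")), GeneSet("B", ("x", "y")),
            GeneSet("C", ("x", "z"))])
        net = build_term_network(kappa_matrix(col), threshold=1.0)
        assert net.graph.has_edge("A", "B")
        assert not net.graph.has_edge("A", "C")

    def test_planted_block_structure_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(10)
        pools = [
            tuple(f"p{b}_{i}" for i in range(40)) for b in range(3)
        ]
        terms, truth = [], []
        for b, pool in enumerate(pools):
            for t in range(8):
                genes = tuple(rng.choice(pool, 25, replace=False))
                terms.append(GeneSet(f"blk{b}_t{t}", genes))
                truth.append(b)
        col = GeneSetCollection(terms)
        net = build_term_network(kappa_matrix(col), threshold=0.35)
        labels = net.clusters[[s.name for s in col]].to_numpy()
        assert adjusted_rand_score(truth, labels) >= 0.9
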