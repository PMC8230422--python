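"""Moderated differential expression, signature rules and marker tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdcsig import (
    CountMatrix,
    ExpressionMatrix,
    bh_adjust,
    core_consensus_genes,
    derive_specific_signature,
    fit_linear_de,
    rank_sum_markers,
    voom_weights,
)
from cdcsig.diffexpr import DEResult


def _two_group_matrix(n_genes=200, n_per=10, lfc=2.0, sd=0.5, n_de=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(7.0, sd, size=(n_genes, 2 * n_per))
    vals[:n_de, n_per:] += lfc
    genes = [f"g{i:04d}" for i in range(n_genes)]
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    m = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols))
    labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=cols)
    return m, labels, set(genes[:n_de])


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        perm = rng.permutation(100)
        direct = bh_adjust(p)
        via_perm = np.empty(100)
        via_perm[perm] = bh_adjust(p[perm])
        assert np.allclose(direct, via_perm)

    def test_null_calibration_mean_marked_fraction(self):
        rng = np.random.default_rng(2)
        fractions = []
        for _ in range(500):
            p = rng.random(1000)
            fractions.append(np.mean(bh_adjust(p) < 0.05))
        mean = np.mean(fractions)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert mean <= 0.05 + 3 * se

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFitLinearDE:
    def test_zero_noise_identical_means_fc_zero(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 6))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)]))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=m.samples)
        res = fit_linear_de(m, labels, ("b", "a"))
        assert np.allclose(res.table["log_fc"], 0.0)

    def test_prior_df_zero_equals_ordinary_t(self):
        m, labels, _ = _two_group_matrix(seed=3)
        res = fit_linear_de(m, labels, ("b", "a"), prior_df=0)
        a = m.values.loc[:, labels == "a"].to_numpy()
        b = m.values.loc[:, labels == "b"].to_numpy()
        t_ref, p_ref = stats.ttest_ind(b, a, axis=1)  # pooled-variance t
        assert np.allclose(res.table["stat"], t_ref)
        assert np.allclose(res.table["p_value"], p_ref)

    def test_infinite_prior_df_collapses_variances(self):
        m, labels, _ = _two_group_matrix(seed=4)
        res = fit_linear_de(m, labels, ("b", "a"), prior_df=np.inf)
        # all genes share one variance: t proportional to the mean difference
        ratio = res.table["stat"] / res.table["log_fc"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_moderated_variance_between_ordinary_and_prior(self):
        m, labels, _ = _two_group_matrix(seed=5)
        res = fit_linear_de(m, labels, ("b", "a"))
        assert 0 < res.prior_df < np.inf
        assert res.prior_var > 0

    def test_planted_recovery_matches_welch_oracle(self):
        m, labels, truth = _two_group_matrix(n_genes=2000, n_de=200, seed=6)
        res = fit_linear_de(m, labels, ("b", "a"))
        called = set(res.significant(fdr=0.05))
        assert len(called & truth) / len(truth) >= 0.95
        false = called - truth
        assert len(false) <= 0.1 * max(len(called), 1)
        # cross-check against an independent Welch-t + BH oracle
        a = m.values.loc[:, labels == "a"].to_numpy()
        b = m.values.loc[:, labels == "b"].to_numpy()
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        oracle = set(m.genes[bh_adjust(p) < 0.05])
        overlap = len(called & oracle) / len(oracle | called)
        assert overlap >= 0.9

    def test_anova_flags_any_group_difference(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 0.5, size=(100, 15))
        vals[:10, 10:] += 2.0  # third group shifted
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(15)]))
        labels = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=m.samples)
        res = fit_linear_de(m, labels, "anova")
        assert res.kind == "anova"
        sig = set(res.significant(0.05))
        assert set(m.genes[:10]) <= sig

    def test_zero_residual_df_errors(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0]], index=["g"], columns=["s1", "s2"]))
        labels = pd.Series(["a", "b"], index=m.samples)
        with pytest.raises(ValueError):
            fit_linear_de(m, labels, ("a", "b"))


class TestVoom:
    def _counts(self, n_genes=500, n_per=5, seed=8, hetero=True):
        # small dispersion keeps the Poisson 1/mu term dominant, planting a
        # strong decreasing mean-variance trend on the log-cpm scale
        rng = np.random.default_rng(seed)
        mu = rng.uniform(2, 2000, n_genes)
        phi = 0.01 if hetero else 0.0
        lam = rng.gamma(1 / phi, mu[:, None] * phi, (n_genes, 2 * n_per)) if phi else \
            np.tile(mu[:, None], (1, 2 * n_per))
        counts = rng.poisson(lam)
        cm = CountMatrix(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(2 * n_per)]))
        labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=cm.samples)
        return cm, labels

    def test_weights_positive_finite(self):
        cm, labels = self._counts()
        w = voom_weights(cm, labels)
        arr = w.weights.to_numpy()
        assert np.isfinite(arr).all() and (arr > 0).all()

    def test_homoskedastic_gaussian_pseudocounts_near_constant_weights(self):
        rng = np.random.default_rng(9)
        # constant-variance pseudo-counts on a narrow abundance range
        base = rng.integers(900, 1100, 400)
        counts = base[:, None] + rng.integers(-30, 30, (400, 8))
        cm = CountMatrix(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(400)],
            columns=[f"s{i}" for i in range(8)]))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=cm.samples)
        w = voom_weights(cm, labels).weights.to_numpy()
        cv = w.std() / w.mean()
        assert cv < 0.2

    def test_weights_increase_with_expression_under_nb_noise(self):
        cm, labels = self._counts(hetero=True)
        w = voom_weights(cm, labels)
        mean_w = np.log(w.weights.mean(axis=1))
        mean_c = np.log1p(cm.values.mean(axis=1))
        rho = stats.spearmanr(mean_c, mean_w).statistic
        assert rho > 0.5  # higher counts -> smaller relative variance -> larger weight

    def test_single_gene_errors(self):
        cm = CountMatrix(pd.DataFrame(
            [[5, 6, 7, 8]], index=["g"], columns=["s1", "s2", "s3", "s4"]))
        labels = pd.Series(["a", "a", "b", "b"], index=cm.samples)
        with pytest.raises(ValueError):
            voom_weights(cm, labels)


def _mk_de(genes, log_fc, fdr, contrast="x"):
    lfc = pd.Series(log_fc, index=genes, dtype=float)
    q = pd.Series(fdr, index=genes, dtype=float)
    table = pd.DataFrame({"log_fc": lfc, "stat": lfc, "p_value": q, "fdr": q})
    return DEResult(table, contrast)


class TestSignatureRule:
    def test_rule_application(self):
        genes = ["g1", "g2"]
        # g1: FCs (3, 2.5, 1.2) linear, FDR 0.01 -> in
        # g2: FCs (3, 2.5, 1.6) -> excluded (shared-tumor gene)
        an = _mk_de(genes, np.log2([3.0, 3.0]), [0.01, 0.01])
        ab = _mk_de(genes, np.log2([2.5, 2.5]), [0.01, 0.01])
        bn = _mk_de(genes, np.log2([1.2, 1.6]), [0.5, 0.5])
        anova = _mk_de(genes, [np.nan, np.nan], [0.01, 0.01])
        sig = derive_specific_signature(an, ab, bn, anova)
        assert list(sig.genes) == ["g1"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        an = _mk_de(genes, rng.normal(1, 1, 200), rng.random(200))
        ab = _mk_de(genes, rng.normal(1, 1, 200), rng.random(200))
        bn = _mk_de(genes, rng.normal(0, 1, 200), rng.random(200))
        anova = _mk_de(genes, np.zeros(200), rng.random(200))
        tight = set(derive_specific_signature(an, ab, bn, anova,
                                              fc_threshold=2.0,
                                              other_fc_threshold=1.5,
                                              anova_fdr=0.25).genes)
        loose = set(derive_specific_signature(an, ab, bn, anova,
                                              fc_threshold=1.5,
                                              other_fc_threshold=2.0,
                                              anova_fdr=0.5).genes)
        assert tight <= loose

    def test_mismatched_gene_spaces_error(self):
        a = _mk_de(["g1"], [1.0], [0.01])
        b = _mk_de(["g2"], [1.0], [0.01])
        with pytest.raises(ValueError, match="mismatched"):
            derive_specific_signature(a, b, b)

    def test_planted_compendium_signature_exact(self, bulk_compendium):
        mats, truth = bulk_compendium
        m = mats[0]
        lab = m.class_labels()
        sig = derive_specific_signature(
            fit_linear_de(m, lab, ("tumorA", "normal")),
            fit_linear_de(m, lab, ("tumorA", "tumorB")),
            fit_linear_de(m, lab, ("tumorB", "normal")),
            fit_linear_de(m, lab, "anova"),
        )
        planted = set(truth.genes_of_class("specific_up"))
        shared = set(truth.genes_of_class("shared_up"))
        assert set(sig.genes) & shared == set()
        assert len(set(sig.genes) & planted) >= 0.9 * len(planted)


class TestConsensusCore:
    def test_three_of_four_up(self):
        genes = ["g"]
        hits = _mk_de(genes, [2.0], [0.01])
        miss = _mk_de(genes, [0.0], [0.9])
        up3, _ = core_consensus_genes([hits, hits, hits, miss])
        assert "g" in up3.genes
        up2, _ = core_consensus_genes([hits, hits, miss, miss])
        assert "g" not in up2.genes

    def test_sign_consistency_required(self):
        genes = ["g"]
        up = _mk_de(genes, [2.0], [0.01])
        down = _mk_de(genes, [-2.0], [0.01])
        u, d = core_consensus_genes([up, up, down, down])
        assert "g" not in u.genes and "g" not in d.genes

    def test_min_datasets_bound(self):
        de = _mk_de(["g"], [2.0], [0.01])
        with pytest.raises(ValueError):
            core_consensus_genes([de, de], min_datasets=3)

    def test_planted_core_recovery(self, bulk_compendium):
        mats, truth = bulk_compendium
        des = [fit_linear_de(m, m.class_labels(), ("tumorA", "normal"))
               for m in mats]
        up, down = core_consensus_genes(des)
        up_truth = set(truth.genes_of_class("specific_up")) | set(
            truth.genes_of_class("shared_up"))
        down_truth = set(truth.genes_of_class("down"))
        null = set(truth.genes_of_class("null"))
        assert len(set(up.genes) & up_truth) / len(up_truth) >= 0.9
        assert len(set(down.genes) & down_truth) / len(down_truth) >= 0.9
        assert set(up.genes) & null == set()
        assert set(down.genes) & null == set()


class TestRankSumMarkers:
    def test_constant_gene_p_one(self):
        vals = np.ones((1, 10))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=["g"], columns=[f"c{i}" for i in range(10)]))
        labels = pd.Series(["t"] * 5 + ["o"] * 5, index=m.samples)
        table = rank_sum_markers(m, labels, "t")
        assert table.loc["g", "p_value"] == 1.0

    def test_planted_marker_significant(self, single_cell):
        m, truth = single_cell
        table = rank_sum_markers(m, truth.cell_types, "typeA")
        planted = list(truth.marker_sets["typeA"])
        assert (table.loc[planted, "fdr"] < 0.05).mean() >= 0.9

    def test_single_type_errors(self):
        m = ExpressionMatrix(pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(6)]))
        labels = pd.Series(["t"] * 6, index=m.samples)
        with pytest.raises(ValueError):
            rank_sum_markers(m, labels, "t")
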