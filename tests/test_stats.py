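"""Enrichment and inference statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from sclc_caf import (
    ExpressionMatrix, GeneSet, RankedList, SignatureLibrary, bh_fdr,
    correlation_pvalue, group_tests, gsea_es, gsea_nes, gsva_like_scores,
    log_transform, moderated_t, pearson_correlation, rank_metric,
)


# --------------------------------------------------------------------------
# oracles

def gsea_es_oracle(genes, metrics, set_genes, p):
    """Literal running-sum evaluation, independent of the implementation."""
    n = len(genes)
    hits = [g in set_genes for g in genes]
    total = sum(abs(m) ** p for g, m, h in zip(genes, metrics, hits) if h)
    n_miss = n - sum(hits)
    run, best = 0.0, 0.0
    for g, m, h in zip(genes, metrics, hits):
        run += (abs(m) ** p / total) if h else (-1.0 / n_miss)
        if abs(run) > abs(best):
            best = run
    return best


def moderated_t_oracle(X, n1, n2):
    """Step-by-step transcription of the shrinkage equations with an
    independent root solver for the trigamma inversion."""
    high, low = X[:, :n1], X[:, n1:]
    effect = high.mean(axis=1) - low.mean(axis=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * high.var(axis=1, ddof=1) + (n2 - 1) * low.var(axis=1, ddof=1)) / d
    e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
    ebar = e.mean()
    G = e.size
    excess = ((e - ebar) ** 2).sum() / (G - 1) - polygamma(1, d / 2)
    if excess > 0:
        half_d0 = brentq(lambda y: polygamma(1, y) - excess, 1e-8, 1e8)
        d0 = 2 * half_d0
        s0_sq = np.exp(ebar + digamma(d0 / 2) - np.log(d0 / 2))
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        d0, s0_sq = np.inf, np.exp(ebar)
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    t = effect / np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    return t, d0, s0_sq, df_total


# --------------------------------------------------------------------------

class TestRankMetric:
    def _m(self, X, n1, n2):
        genes = [f"G{i:02d}" for i in range(X.shape[0])]
        cols = [f"H{j}" for j in range(n1)] + [f"L{j}" for j in range(n2)]
        m = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=cols), scale="log2p1")
        return m, ["high"] * n1 + ["low"] * n2

    def test_sign_of_elevated_gene(self, rng):
        X = rng.normal(5, 1, size=(5, 10))
        X[0, :5] += 4.0
        m, labels = self._m(X, 5, 5)
        ranked = rank_metric(m, labels)
        assert ranked.genes[0] == "G00"
        assert ranked.metric[0] > 0

    def test_hand_formula(self):
        X = np.array([
            [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0],
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            [9.0, 8.0, 7.0, 6.0, 1.0, 2.0, 3.0, 4.0],
        ])
        m, labels = self._m(X, 4, 4)
        ranked = rank_metric(m, labels)
        metrics = dict(zip(ranked.genes, ranked.metric))
        # gene 0: mu_h=2.5 mu_l=11.5 sd_h=sd_l=1.29; floors max(.2*mu,.2)
        sd = np.std([1, 2, 3, 4], ddof=1)
        sd_h = max(sd, 0.2 * 2.5, 0.2)
        sd_l = max(sd, 0.2 * 11.5, 0.2)
        assert metrics["G00"] == pytest.approx((2.5 - 11.5) / (sd_h + sd_l), abs=1e-12)
        # constant gene: sd floored at max(.2*5, .2) = 1 per group
        assert metrics["G01"] == pytest.approx(0.0, abs=1e-12)

    def test_tied_metrics_lexicographic(self):
        X = np.array([[1.0, 1, 1, 1, 2, 2, 2, 2]] * 2 + [[3.0, 3, 3, 3, 3, 3, 3, 3]])
        m, labels = self._m(X, 4, 4)
        ranked = rank_metric(m, labels)
        tied = [g for g, v in zip(ranked.genes, ranked.metric) if v == ranked.metric[0]]
        assert tied == sorted(tied)

    def test_small_group_rejected(self):
        X = np.zeros((3, 3))
        m, _ = self._m(X + 1.0, 2, 1)
        with pytest.raises(ValueError, match="2 samples"):
            rank_metric(m, ["high", "high", "low"])


class TestGseaEs:
    def _ranked(self, metrics, genes=None):
        genes = genes or [chr(65 + i) for i in range(len(metrics))]
        return RankedList(np.array(genes), np.array(metrics, dtype=float))

    def test_top_block_unit_score(self):
        ranked = self._ranked(sorted(range(10), reverse=True))
        assert gsea_es(ranked, GeneSet("s", ("A", "B", "C")), p_exponent=0) == pytest.approx(1.0)

    def test_bottom_block_mirror(self):
        ranked = self._ranked(sorted(range(10), reverse=True))
        assert gsea_es(ranked, GeneSet("s", ("H", "I", "J")), p_exponent=0) == pytest.approx(-1.0)

    def test_worked_example_two_thirds(self):
        # metrics (5,4,3,2,1) for A..E, set {A,C}: running max 5/8 - 1/3 + 3/8 = 2/3
        ranked = self._ranked([5, 4, 3, 2, 1])
        es = gsea_es(ranked, GeneSet("s", ("A", "C")), p_exponent=1)
        assert es == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_exhaustive_enumeration_oracle(self, rng):
        """All subsets of size <= 4 of a 10-gene list match the oracle."""
        metrics = np.sort(rng.normal(size=10))[::-1]
        genes = [f"G{i}" for i in range(10)]
        ranked = self._ranked(metrics, genes)
        for size in (1, 2, 3, 4):
            for combo in itertools.combinations(genes, size):
                got = gsea_es(ranked, GeneSet("s", combo), p_exponent=1)
                want = gsea_es_oracle(genes, metrics, set(combo), 1)
                assert got == pytest.approx(want, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = self._ranked([3, 2, 1])
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("s", ("X",)))
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("s", ("A", "B", "C")))
        with pytest.raises(ValueError, match="zero"):
            gsea_es(self._ranked([0.0, 0.0, 0.0]), GeneSet("s", ("A",)), p_exponent=1)


class TestGseaNes:
    def _data(self, seed, n_genes=30, n1=10, n2=10, effect=0.0, set_size=5):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(n_genes)]
        X = rng.normal(5, 1, size=(n_genes, n1 + n2))
        X[:set_size, :n1] += effect
        m = ExpressionMatrix(
            pd.DataFrame(X, index=genes, columns=[f"S{j}" for j in range(n1 + n2)]),
            scale="log2p1",
        )
        return m, ["high"] * n1 + ["low"] * n2, GeneSet("s", tuple(genes[:set_size]))

    def test_strong_effect_hits_p_floor(self):
        m, labels, s = self._data(seed=1, effect=8.0)
        res = gsea_nes(m, labels, s, n_perm=200, seed=4, mode="gene_set")
        assert res.nes > 0
        assert res.es == pytest.approx(1.0, abs=1e-6)  # set occupies the top ranks
        # no null ES as extreme as the observed one: p attains its floor
        # 1/(#same-sign nulls + 1), bounded below by 1/(n_perm + 1)
        assert res.p_value >= 1.0 / (res.n_permutations + 1)
        assert res.p_value < 0.05

    def test_seed_determinism(self):
        m, labels, s = self._data(seed=2, effect=1.0)
        a = gsea_nes(m, labels, s, n_perm=120, seed=11)
        b = gsea_nes(m, labels, s, n_perm=120, seed=11)
        assert (a.es, a.nes, a.p_value) == (b.es, b.nes, b.p_value)

    def test_seed_required(self):
        m, labels, s = self._data(seed=3)
        with pytest.raises(ValueError, match="seed"):
            gsea_nes(m, labels, s, n_perm=100)

    def test_small_group_falls_back_to_gene_set_mode(self):
        m, labels, s = self._data(seed=4, n1=4, n2=16)
        res = gsea_nes(m, labels, s, n_perm=100, seed=5, mode="phenotype")
        assert res.permutation_mode == "gene_set"

    def test_null_p_roughly_uniform(self):
        """Nominal p under permuted labels on homogeneous data is
        approximately uniform (KS test over 200 sets)."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            m, labels, _ = self._data(seed=int(rng.integers(2**31)), n_genes=30)
            lab = np.array(labels)
            rng.shuffle(lab)
            genes = np.array(m.gene_ids)
            s = GeneSet("s", tuple(rng.choice(genes, 6, replace=False)))
            res = gsea_nes(m, list(lab), s, n_perm=150, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestGsvaLike:
    def test_matches_bruteforce(self, rng):
        from .test_abundance import ssgsea_oracle
        genes = [f"G{i:02d}" for i in range(12)]
        df = pd.DataFrame(rng.uniform(1, 9, size=(12, 3)), index=genes,
                          columns=["S1", "S2", "S3"])
        m = ExpressionMatrix(df, scale="log2p1")
        lib = SignatureLibrary.from_sets([
            GeneSet("A", ("G00", "G03", "G07")),
            GeneSet("B", ("G01", "G02")),
            GeneSet("C", ("G10", "G11", "G05", "G06")),
        ])
        out = gsva_like_scores(m, lib)
        for name, gs in lib.sets.items():
            for s in m.sample_ids:
                want = ssgsea_oracle(dict(zip(genes, df[s])), set(gs.genes), 1.0, "max_dev")
                assert out.loc[name, s] == pytest.approx(want, abs=1e-12)

    def test_identical_samples_identical_columns(self):
        genes = [f"G{i}" for i in range(8)]
        col = np.arange(8, dtype=float) + 1
        m = ExpressionMatrix(
            pd.DataFrame({"S1": col, "S2": col}, index=genes), scale="log2p1"
        )
        lib = SignatureLibrary.from_sets([GeneSet("A", ("G0", "G5"))])
        out = gsva_like_scores(m, lib)
        assert out["S1"].equals(out["S2"])

    def test_concentrated_set_has_row_max(self, rng):
        genes = [f"G{i:02d}" for i in range(20)]
        X = rng.uniform(1, 5, size=(20, 4))
        X[:4, 0] += 50.0  # set genes top-ranked in sample 0 only
        m = ExpressionMatrix(
            pd.DataFrame(X, index=genes, columns=["S0", "S1", "S2", "S3"]), scale="log2p1"
        )
        lib = SignatureLibrary.from_sets([GeneSet("A", tuple(genes[:4]))])
        out = gsva_like_scores(m, lib)
        assert out.loc["A"].idxmax() == "S0"


class TestModeratedT:
    def test_matches_transcription_oracle(self, rng):
        X = rng.normal(size=(50, 16)) * rng.uniform(0.5, 2.0, size=(50, 1))
        X[:5, :8] += 1.5
        tab = pd.DataFrame(X)
        res = moderated_t(tab, ["high"] * 8 + ["low"] * 8)
        t, d0, s0_sq, df_total = moderated_t_oracle(X, 8, 8)
        np.testing.assert_allclose(res.table["t"].to_numpy(), t, rtol=1e-8)
        assert res.prior_df == pytest.approx(d0, rel=1e-6)
        assert res.prior_var == pytest.approx(s0_sq, rel=1e-8)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        X = rng.normal(size=(20, 12))
        tab = pd.DataFrame(X)
        labels = ["high"] * 6 + ["low"] * 6
        res = moderated_t(tab, labels, prior_df=0.0)
        for i in range(20):
            t_ref, _ = sps.ttest_ind(X[i, :6], X[i, 6:], equal_var=True)
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, abs=1e-10)

    def test_identical_variances_take_infinite_prior(self, rng):
        base = rng.normal(size=12)
        # every feature is a permutation-free shift of the same draws:
        # identical sample variances in both groups
        X = np.stack([base + k for k in range(6)])
        res = moderated_t(pd.DataFrame(X), ["high"] * 6 + ["low"] * 6)
        assert np.isinf(res.prior_df)
        assert np.isinf(res.table["df_total"]).all()
        assert res.prior_var > 0

    def test_zero_variance_feature_flagged(self, rng):
        X = rng.normal(size=(10, 8))
        X[0] = 3.0
        res = moderated_t(pd.DataFrame(X), ["high"] * 4 + ["low"] * 4)
        assert bool(res.table["zero_variance"].iloc[0])
        assert not res.table["zero_variance"].iloc[1:].any()

    def test_q_monotone_in_p(self, rng):
        X = rng.normal(size=(30, 10))
        res = moderated_t(pd.DataFrame(X), ["high"] * 5 + ["low"] * 5)
        srt = res.table.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        out = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert out.r == pytest.approx(-1.0)

    def test_published_pair_reproduced(self):
        # r = 0.3086 at n = 74 -> two-sided p = 0.0075
        assert correlation_pvalue(0.3086, 74) == pytest.approx(0.0075, abs=0.0005)

    def test_matches_t_formula_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        out = pearson_correlation(x, y)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt((10 - 2) / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), 8)
        assert out.r == pytest.approx(r, abs=1e-12)
        assert out.p_value == pytest.approx(p, rel=1e-9)

    def test_spearman_option_ranks_first(self, rng):
        x = rng.normal(size=20)
        y = np.exp(x)  # monotone, nonlinear
        out = pearson_correlation(x, y, method="spearman")
        assert out.r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestGroupTests:
    def test_identical_groups_mann_whitney_p_one(self):
        # mirror-image groups: U at its null mean -> two-sided p = 1
        # (ties force the tie-corrected approximation)
        stat, p = group_tests([1, 2, 3, 9, 1, 2, 3, 9], ["a"] * 4 + ["b"] * 4,
                              test="mann_whitney")
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        # oracle: all C(8,4) = 70 rank splits, the 2 extreme ones -> p = 2/70
        vals = [1, 2, 3, 4, 10, 11, 12, 13]
        stat, p = group_tests(vals, ["a"] * 4 + ["b"] * 4, test="mann_whitney")
        assert p == pytest.approx(2.0 / 70.0, abs=1e-12)

    def test_student_t_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        stat, p = group_tests(a + b, ["x"] * 3 + ["y"] * 3, test="student_t")
        sp = np.sqrt(((2) * 1.0 + (2) * 1.0) / 4)  # pooled sd, both var = 1
        t_ref = (2.0 - 3.0) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert stat == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), 4), rel=1e-9)

    def test_anova_needs_three_groups(self):
        with pytest.raises(ValueError, match="t-test"):
            group_tests([1, 2, 3, 4], ["a", "a", "b", "b"], test="anova")
        stat, p = group_tests(
            [1, 2, 5, 6, 9, 10], ["a", "a", "b", "b", "c", "c"], test="anova"
        )
        assert 0 <= p <= 1


class TestBhFdr:
    def test_manual_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_edge_cases(self):
        assert bh_fdr([0.4])[0] == pytest.approx(0.4)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, pvals):
        p = np.array(pvals)
        perm = np.random.default_rng(0).permutation(len(p))
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        np.testing.assert_allclose(q[perm], q_perm, atol=1e-12)
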