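import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import digamma

import nestvar as nv
from nestvar.variance_components import (
    alpha_counts,
    chi2_log_bias,
    shrunken_within_variance,
)

from conftest import make_study


class TestPooledScale:
    def test_single_gene_digamma_oracle(self):
        scale = nv.pooled_scale([1.0], nu=23)
        assert scale.sigma2_pool == pytest.approx(np.exp(np.log(11.5) - digamma(11.5)))
        assert scale.sigma2_pool == pytest.approx(1.0451, abs=1e-4)

    def test_large_nu_limit_is_geometric_mean(self):
        s2 = np.array([0.5, 2.0, 1.0])
        scale = nv.pooled_scale(s2, nu=10 ** 7)
        assert abs(scale.bias_correction) < 1e-6
        assert scale.sigma2_pool == pytest.approx(stats.gmean(s2), rel=1e-5)

    def test_outlier_influence_bounded(self):
        s2 = np.ones(100)
        outlier = 1000.0
        with_out = nv.pooled_scale(np.append(s2, outlier), nu=23)
        without = nv.pooled_scale(np.append(s2, 1.0), nu=23)
        ratio = with_out.sigma2_pool / without.sigma2_pool
        assert ratio <= outlier ** (1 / 101) + 1e-12

    def test_zero_variance_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            scale = nv.pooled_scale([1.0, 0.0], nu=23)
        assert scale.sigma2_pool == pytest.approx(nv.pooled_scale([1.0], 23).sigma2_pool)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            nv.pooled_scale([], nu=23)


class TestExcessVarianceTest:
    def test_stat_and_pvalue_at_pooled_scale(self):
        scale = nv.PooledScale(sigma2_pool=1.0, nu=23, bias_correction=0.0)
        res = nv.excess_variance_test([1.0], scale)
        assert res["chi2_stat"].iloc[0] == pytest.approx(23.0)
        assert res["chi2_p"].iloc[0] == pytest.approx(stats.chi2.sf(23, 23))
        assert res["chi2_p"].iloc[0] == pytest.approx(0.462, abs=5e-3)

    def test_variable_gene_ranking(self):
        s2 = pd.Series([1.0, 5.0, 3.0, 0.5, 4.0], index=list("abcde"))
        top = nv.variable_genes(s2, n=3)
        assert list(top) == ["b", "e", "c"]

    def test_ranking_restricted_to_eligible(self):
        s2 = pd.Series([9.0, 5.0, 3.0], index=list("abc"))
        top = nv.variable_genes(s2, n=2, eligible=["b", "c"])
        assert list(top) == ["b", "c"]

    def test_alpha_counts(self):
        counts = alpha_counts([0.001, 0.02, 0.2], alphas=(0.05, 0.01))
        assert counts == {0.05: 2, 0.01: 1}


class TestDecomposeVariance:
    def test_hand_anova(self, tiny_study):
        d = nv.decompose_variance(tiny_study)
        g = d.loc["g0001"]
        assert g["msw"] == pytest.approx(2.0)
        assert g["msb"] == pytest.approx(26 / 3, abs=1e-4)
        assert g["s2_within"] == pytest.approx(2.0)
        assert g["s2_between"] == pytest.approx(10 / 3, abs=1e-4)
        assert g["icc"] == pytest.approx(0.625)

    def test_equal_mouse_means_truncate(self, tiny_study):
        g = nv.decompose_variance(tiny_study).loc["g0002"]  # mouse means 5, 5, 5
        assert g["msb"] == pytest.approx(0.0)
        assert g["s2_between"] == 0.0
        assert g["icc"] == 0.0

    def test_icc_formula(self):
        # s_b2 = 1, s_w2 = 3 -> c = 0.25; construct via msb = k*s_b2 + msw
        d = pd.DataFrame({"s2_between": [1.0], "s2_within": [3.0]})
        assert (d["s2_between"] / (d["s2_between"] + d["s2_within"])).iloc[0] == 0.25

    def test_total_variance_matches_sample_variance(self, null_study):
        d = nv.decompose_variance(null_study)
        np.testing.assert_allclose(
            d["s2_total"], null_study.values.var(axis=1, ddof=1)
        )

    def test_unbalanced_falls_back_to_reml(self):
        rng = np.random.default_rng(3)
        study = make_study(rng.normal(size=(5, 12)), n_mice=6, reps=2)
        # drop one sample -> unbalanced
        vals = study.values.drop(columns=["m06_r2"])
        samples = study.samples.drop(index=["m06_r2"])
        with pytest.warns(UserWarning, match="unbalanced"):
            unb = nv.ExpressionStudy(vals, samples, study.probes)
        with pytest.warns(UserWarning, match="REML"):
            d = nv.decompose_variance(unb)
        assert (d["s2_within"] > 0).all()
        assert (d["s2_between"] >= 0).all()


class TestShrunkenF:
    def test_no_shrinkage_limit_is_classic_f(self):
        msb = np.array([4.0, 2.0, 1.0])
        msw = np.array([2.0, 2.0, 2.0])
        f = nv.shrunken_f(msb, msw, d=12, shrink=False)
        np.testing.assert_allclose(f, msb / msw)

    def test_identical_msw_gives_equal_denominators(self):
        msb = np.array([4.0, 2.0, 1.0, 8.0])
        msw = np.full(4, 2.0)
        sigma_tilde, B = shrunken_within_variance(msw, d=12)
        assert B == 1.0
        assert np.allclose(sigma_tilde, sigma_tilde[0])
        f = nv.shrunken_f(msb, msw, d=12)
        assert list(np.argsort(-f)) == list(np.argsort(-msb))

    def test_few_genes_no_shrinkage(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            sigma_tilde, B = shrunken_within_variance(np.array([1.0, 2.0]), d=12)
        assert B == 0.0

    def test_bias_correction_centres_log_msw(self):
        # chi2 sampling: mean of corrected z approximates log sigma2
        rng = np.random.default_rng(0)
        d = 12
        msw = stats.chi2.rvs(d, size=20000, random_state=rng) / d  # sigma2 = 1
        z = np.log(msw) - chi2_log_bias(d)
        assert abs(z.mean()) < 0.01


class TestPermutationPvalues:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.01, size=(5, 24))
        X[0] += np.repeat(np.linspace(-3, 3, 12), 2)  # enormous mouse effect
        study = make_study(X)
        p = nv.permutation_pvalues(study, n_perm=99, seed=0, pooling="per-gene")
        assert p.iloc[0] == pytest.approx(1 / 100)

    def test_seed_reproducibility(self, null_study):
        p1 = nv.permutation_pvalues(null_study, n_perm=50, seed=9)
        p2 = nv.permutation_pvalues(null_study, n_perm=50, seed=9)
        pd.testing.assert_series_equal(p1, p2)

    def test_constant_gene_reported_missing(self):
        X = np.vstack([np.full(24, 3.0), np.random.default_rng(0).normal(size=24)])
        study = make_study(X)
        p = nv.permutation_pvalues(study, n_perm=20, seed=0)
        assert np.isnan(p.iloc[0])
        assert np.isfinite(p.iloc[1])

    def test_invalid_n_perm(self, null_study):
        with pytest.raises(ValueError):
            nv.permutation_pvalues(null_study, n_perm=0)

    def test_null_f_matches_permutation_null(self, null_study):
        """Under the global null the observed shrunken-F distribution is
        indistinguishable from its own permutation null."""
        from nestvar.variance_components import _balanced_layout, _mean_squares

        order, n, k = _balanced_layout(null_study)
        X = null_study.values.to_numpy()[:, order]
        msb, msw = _mean_squares(X, n, k)
        obs = nv.shrunken_f(msb, msw, d=n * (k - 1))
        rng = np.random.default_rng(4)
        resid = X - X.mean(axis=1, keepdims=True)
        perm = resid[:, rng.permutation(X.shape[1])]
        msb_p, msw_p = _mean_squares(perm, n, k)
        null = nv.shrunken_f(msb_p, msw_p, d=n * (k - 1))
        assert stats.ks_2samp(obs, null).pvalue > 0.01


class TestAdjustPvalues:
    def test_sidak_stepdown_hand_example(self):
        res = nv.adjust_pvalues([0.01, 0.5], method="sidak_stepdown")
        np.testing.assert_allclose(res.adjusted, [1 - 0.99 ** 2, 0.5])

    def test_bh_hand_example(self):
        res = nv.adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(res.adjusted, [0.04] * 4)

    def test_single_zero(self):
        for method in ("sidak_stepdown", "bh", "qvalue"):
            assert nv.adjust_pvalues([0.0], method=method).adjusted.iloc[0] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nv.adjust_pvalues([0.5, 1.5], method="bh")

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.sampled_from(["sidak_stepdown", "bh", "qvalue"]),
    )
    def test_adjusted_in_unit_interval_and_no_smaller(self, pvals, method):
        res = nv.adjust_pvalues(pvals, method=method)
        adj = res.adjusted.to_numpy()
        assert ((adj >= -1e-12) & (adj <= 1 + 1e-12)).all()
        if method in ("sidak_stepdown", "bh"):
            assert (adj >= np.asarray(pvals) - 1e-12).all()


class TestPi0:
    def test_counting_example(self):
        assert nv.estimate_pi0([0.1, 0.2, 0.3, 0.8, 0.9, 1.0], lam=0.5) == 1.0

    def test_all_ones_capped(self):
        assert nv.estimate_pi0([1.0] * 10) == 1.0

    def test_uniform_p_estimates_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20000)
        assert nv.estimate_pi0(p) == pytest.approx(1.0, abs=0.02)
        assert nv.estimate_pi0(p, grid=True) == pytest.approx(1.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nv.estimate_pi0([])


class TestDecomposeCage:
    def test_equal_cage_means_truncate(self):
        # 2 cages x 2 mice x 2 reps; cage means both 3
        X = [[1, 3, 4, 4, 2, 4, 3, 3]]
        study = make_study(X, n_mice=4, reps=2)
        d = nv.decompose_cage(study)
        assert d["s2_cage"].iloc[0] == 0.0

    def test_cage_signal_detected_by_cage_test(self):
        cfg = nv.SimulationConfig(
            n_genes=400, n_negative_controls=0, sigma2_cage=1.0, sigma2_mouse=0.0,
            sigma2_within=1.0, frac_expressed=1.0, batch_effect_sd=0.0, seed=9,
        )
        d = nv.decompose_cage(nv.simulate_study(cfg).study)
        power_cage = (d["p_cage"] < 0.05).mean()
        power_mouse = (d["p_mouse_in_cage"] < 0.05).mean()
        assert power_cage > power_mouse

    def test_nested_components_sum_to_oneway_between(self):
        """Untruncated nested estimates (cage + mouse-in-cage) average to the
        one-way between-mouse estimate.  With no cage variance both are
        unbiased for sigma2_mouse; a cage component would enter the one-way
        between-mouse mean square with coefficient mpc(C-1)/(M-1) < 1, so the
        clean identity is checked at sigma2_cage = 0."""
        cfg = nv.SimulationConfig(
            n_genes=500, n_negative_controls=0, sigma2_cage=0.0, sigma2_mouse=0.6,
            sigma2_within=0.3, frac_expressed=1.0, batch_effect_sd=0.0, seed=4,
        )
        study = nv.simulate_study(cfg).study
        one = nv.decompose_variance(study)
        nest = nv.decompose_cage(study)
        k, mpc = 2, 2
        s2b_unt = (one["msb"] - one["msw"]) / k
        sum_unt = (nest["ms_cage"] - nest["ms_mouse_in_cage"]) / (mpc * k) + (
            nest["ms_mouse_in_cage"] - nest["ms_within"]
        ) / k
        assert abs(s2b_unt.mean() - sum_unt.mean()) < 0.02
        assert abs(s2b_unt.mean() - 0.6) < 0.05

    def test_single_cage_rejected(self):
        study = make_study(np.random.default_rng(0).normal(size=(2, 4)), n_mice=2, reps=2)
        study.samples["cage"] = "c1"
        with pytest.raises(ValueError, match="2 cages"):
            nv.decompose_cage(study)
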