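import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from csvdnet import stats
from csvdnet.errors import ParameterError


class TestOnewayAnova:
    def test_clear_separation_gives_tiny_p(self, rng):
        y = np.concatenate([rng.normal(0, 1e-3, 5), rng.normal(0, 1e-3, 5),
                            rng.normal(10, 1e-3, 5)])
        g = np.repeat(["a", "b", "c"], 5)
        _, p = stats.oneway_anova(y, g)
        assert p < 1e-6

    def test_identical_groups_give_f_zero(self):
        y = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        F, p = stats.oneway_anova(y, g)
        assert F == 0.0 and p == 1.0

    def test_matches_scipy_f_oneway(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        F, p = stats.oneway_anova(y, g)
        Fs, ps = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert F == pytest.approx(Fs) and p == pytest.approx(ps)

    def test_published_cognitive_screen_summaries(self):
        # MoCA rows of a 3-group cohort (n=67/133/89): published omnibus p = 0.003
        F, p = stats.oneway_anova_from_summary(
            [67, 133, 89], [24.03, 25.26, 26.04], [2.97, 3.58, 3.79]
        )
        assert p < 0.01


class TestChiSquare:
    def test_published_sex_table(self):
        chi2, p = stats.chi_square([[43, 24], [70, 63], [40, 49]])
        assert round(p, 2) == 0.06  # printed as 0.058
        assert p == pytest.approx(0.058, abs=5e-4)

    def test_proportional_table_is_null(self):
        chi2, p = stats.chi_square([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_formula_on_2x2(self, rng):
        t = rng.integers(5, 50, size=(2, 2)).astype(float)
        chi2, _ = stats.chi_square(t)
        tot = t.sum()
        expected = np.outer(t.sum(1), t.sum(0)) / tot
        assert chi2 == pytest.approx((((t - expected) ** 2) / expected).sum())

    def test_zero_marginal_rejected(self):
        with pytest.raises(ParameterError):
            stats.chi_square([[0, 0], [5, 3]])


class TestAncova:
    def test_reduces_to_anova_without_covariates(self, rng):
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        res = stats.ancova_f_test(y, g)
        F, p = stats.oneway_anova(y, g)
        assert res.omnibus_F == pytest.approx(F, abs=1e-8)
        assert res.omnibus_p == pytest.approx(p, abs=1e-8)

    def test_constructed_group_shift_detected(self, rng):
        age = rng.normal(60, 5, 90)
        shift = np.repeat([0.0, 0.0, 1.0], 30)
        y = 2 * age + shift
        g = np.repeat(["a", "b", "c"], 30)
        cov = pd.DataFrame({"age": age})
        res = stats.ancova_f_test(y, g, covariates=cov)
        assert res.omnibus_p < 1e-6

    def test_matches_nested_normal_equations_oracle(self, rng):
        y = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        cov = pd.DataFrame({"age": rng.normal(60, 5, 12), "edu": rng.normal(12, 3, 12)})
        res = stats.ancova_f_test(y, g, covariates=cov)
        # brute-force both nested fits via the normal equations
        d = pd.get_dummies(pd.Series(g), drop_first=True).to_numpy(float)
        Xf = np.column_stack([np.ones(12), d, cov.to_numpy()])
        Xr = np.column_stack([np.ones(12), cov.to_numpy()])

        def ssr(X):
            b = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ b
            return r @ r

        df_resid = 12 - Xf.shape[1]
        F = ((ssr(Xr) - ssr(Xf)) / 2) / (ssr(Xf) / df_resid)
        assert res.omnibus_F == pytest.approx(F, rel=1e-8)
        assert res.df == (2, df_resid)

    def test_collinear_covariate_named(self, rng):
        y = rng.normal(size=12)
        g = np.repeat(["a", "b"], 6)
        age = rng.normal(60, 5, 12)
        cov = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ParameterError, match="age"):
            stats.ancova_f_test(y, g, covariates=cov)


class TestLSD:
    def test_two_group_lsd_equals_omnibus(self, rng):
        y = rng.normal(size=20)
        g = np.repeat(["a", "b"], 10)
        cov = pd.DataFrame({"age": rng.normal(60, 5, 20)})
        res = stats.ancova_f_test(y, g, covariates=cov)
        assert res.posthoc[("a", "b")] == pytest.approx(res.omnibus_p, abs=1e-10)

    def test_shift_pattern_in_three_groups(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                            rng.normal(5, 1, 20)])
        g = np.repeat(["a", "b", "c"], 20)
        res = stats.ancova_f_test(y, g)
        assert res.posthoc[("a", "c")] < 1e-6
        assert res.posthoc[("b", "c")] < 1e-6
        assert res.posthoc[("a", "b")] > 0.01

    def test_null_pairs_have_uniformish_p(self):
        ps = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = r.normal(size=20)
            res = stats.ancova_f_test(y, np.repeat(["a", "b"], 10))
            ps.append(res.posthoc[("a", "b")])
        assert np.mean(ps) > 0.4  # uniform null: mean ~ 0.5


class TestCorrelations:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        feats = pd.DataFrame({"f": x})
        scores = pd.DataFrame({"up": x, "down": -x})
        res = stats.pearson_correlations(feats, scores, np.repeat("g", 10))
        by_test = {r.test: r for r in res}
        assert by_test["up"].r == pytest.approx(1.0)
        assert by_test["down"].r == pytest.approx(-1.0)

    def test_zero_variance_feature_flagged_and_excluded_from_fdr(self, rng):
        feats = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)})
        scores = pd.DataFrame({"s": rng.normal(size=10)})
        res = stats.pearson_correlations(feats, scores, np.repeat("g", 10))
        flat = next(r for r in res if r.feature == "flat")
        ok = next(r for r in res if r.feature == "ok")
        assert flat.undefined and np.isnan(flat.q)
        assert ok.q == pytest.approx(ok.p)  # family of size 1

    def test_partial_mode_removes_confounder(self, rng):
        z = rng.normal(size=200)
        e1 = rng.normal(scale=0.3, size=200)
        e2 = rng.normal(scale=0.3, size=200)
        x, y = z + e1, z + e2
        feats, scores = pd.DataFrame({"x": x}), pd.DataFrame({"y": y})
        cov = pd.DataFrame({"z": z})
        plain = stats.pearson_correlations(feats, scores, np.repeat("g", 200))
        partial = stats.pearson_correlations(
            feats, scores, np.repeat("g", 200), mode="partial", covariates=cov)
        assert plain[0].r > 0.8
        # with the confounder removed only the noise correlation remains
        noise_r = sps.pearsonr(e1 - e1.mean(), e2 - e2.mean()).statistic
        assert partial[0].r == pytest.approx(noise_r, abs=0.05)
        assert abs(partial[0].r) < abs(plain[0].r) / 2

    def test_damage_linked_scores_have_expected_sign_pattern(self):
        """Local-efficiency AUC of damaged subjects correlates positively with
        MoCA/AVLT/SDMT and negatively with SCWT/TMT (timed tests)."""
        from csvdnet import pipeline, synthgen

        cfg = synthgen.SyntheticCohortConfig(
            group_sizes={"CSVD-s": 40, "CSVD-m": 2, "HC": 2}, seed=21)
        mats, table = synthgen.generate_cohort(cfg)
        sel = (table["group"] == "CSVD-s").to_numpy()
        auc = pipeline.compute_eloc_auc(
            [m.weights for m, keep in zip(mats, sel) if keep], (0.06, 0.24, 0.01))
        feats = pd.DataFrame({"eloc_auc": auc})
        scores = table.loc[sel, list(synthgen.COGNITIVE_TESTS)].reset_index(drop=True)
        res = stats.pearson_correlations(feats, scores, np.repeat("CSVD-s", sel.sum()))
        signs = {r.test: np.sign(r.r) for r in res}
        assert signs["MoCA"] == signs["AVLT"] == signs["SDMT"] == 1.0
        assert signs["SCWT"] == signs["TMT_BA"] == -1.0


class TestBHFDR:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            stats.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(stats.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(stats.bh_fdr([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            stats.bh_fdr([0.5, 1.2])

    @given(seed=st.integers(0, 300))
    def test_matches_statsmodels_and_is_permutation_invariant(self, seed):
        from statsmodels.stats.multitest import multipletests

        r = np.random.default_rng(seed)
        p = r.random(12)
        q = stats.bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        perm = r.permutation(12)
        np.testing.assert_allclose(stats.bh_fdr(p[perm]), q[perm], atol=1e-12)
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
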