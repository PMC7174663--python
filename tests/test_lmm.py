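"""Mixed-model engine: likelihood oracles, invariances, pruning, BIC."""

import numpy as np
import pandas as pd
import pytest

from beliefmed import LmmSpec, fit_lmm, information_criteria, prune_random_effects
from beliefmed.lmm import ModelComparison, _design, _Engine
from beliefmed.exceptions import RankDeficiencyError


def make_clusters(J, T, *, sd_int=3.0, sd_slope=0.0, sd_resid=5.0,
                  beta=(50.0, 2.0, 0.5), seed=0):
    """Two-level gaussian data with a +-1 cue and a continuous covariate."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(J):
        u0 = rng.normal(0, sd_int)
        uc = rng.normal(0, sd_slope)
        cue = np.resize([1.0, -1.0], T)
        x = rng.normal(0, 1, T)
        y = beta[0] + u0 + (beta[1] + uc) * cue + beta[2] * x + rng.normal(0, sd_resid, T)
        for i in range(T):
            rows.append((f"p{j:03d}", cue[i], x[i], y[i]))
    return pd.DataFrame(rows, columns=["participant", "cue", "x", "y"])


def dense_reml_loglik(df, spec, vc, sigma2, groups="participant"):
    """Direct evaluation of the REML likelihood: the marginal normal
    density at the GLS solution plus the REML correction term, using a
    dense V = Z G Z' + sigma^2 I (independent of the engine's profiled
    cluster-wise computation)."""
    from scipy.stats import multivariate_normal

    sub = df.sort_values(groups, kind="stable")
    y = sub[spec.outcome].to_numpy(float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [sub[t].to_numpy(float) for t in spec.fixed_terms])
    V = sigma2 * np.eye(n)
    for term, tau2 in vc.items():
        z = np.ones(n) if term == "intercept" else sub[term].to_numpy(float)
        for pid in sub[groups].unique():
            mask = (sub[groups] == pid).to_numpy()
            zz = np.where(mask, z, 0.0)
            V += tau2 * np.outer(zz, zz)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    ll = multivariate_normal.logpdf(y, X @ beta, V)
    _, ldx = np.linalg.slogdet(X.T @ Vi @ X)
    p = X.shape[1]
    return ll - 0.5 * ldx + 0.5 * p * np.log(2 * np.pi)


class TestFixedOnly:
    def test_matches_ols_closed_form(self):
        df = make_clusters(6, 8, seed=3)
        spec = LmmSpec("y", ("cue", "x"))
        fit = fit_lmm(spec, df)
        X = np.column_stack([np.ones(len(df)), df["cue"], df["x"]])
        beta_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params["Estimate"].to_numpy(), beta_ols,
                                   atol=1e-8)
        assert (fit.params["df"] == len(df) - 3).all()

    def test_balanced_two_group_slope_is_half_mean_diff(self):
        """With +-1 coding the OLS cue slope is half the difference of
        the group means (closed-form two-group oracle)."""
        df = make_clusters(5, 10, seed=1)
        fit = fit_lmm(LmmSpec("y", ("cue",)), df)
        m1 = df.loc[df.cue > 0, "y"].mean()
        m2 = df.loc[df.cue < 0, "y"].mean()
        np.testing.assert_allclose(fit.params.loc["cue", "Estimate"],
                                   (m1 - m2) / 2.0, atol=1e-10)

    def test_ml_and_reml_estimates_agree_without_random_terms(self):
        df = make_clusters(4, 6, seed=5)
        reml = fit_lmm(LmmSpec("y", ("cue",), method="reml"), df)
        ml = fit_lmm(LmmSpec("y", ("cue",), method="ml"), df)
        np.testing.assert_allclose(reml.params["Estimate"], ml.params["Estimate"],
                                   atol=1e-6)

    def test_rank_deficiency_names_terms(self):
        df = make_clusters(4, 6, seed=2)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(RankDeficiencyError, match="x2"):
            fit_lmm(LmmSpec("y", ("cue", "x", "x2")), df)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("random_terms", [("intercept",), ("intercept", "cue")])
    def test_reml_loglik_matches_dense_oracle(self, random_terms):
        df = make_clusters(5, 6, sd_slope=1.5, seed=7)  # 30 observations
        spec = LmmSpec("y", ("cue", "x"), random_terms)
        fit = fit_lmm(spec, df)
        oracle = dense_reml_loglik(df, spec, fit.variance_components,
                                   fit.residual_variance)
        np.testing.assert_allclose(fit.loglik, oracle, atol=1e-8)

    def test_estimates_invariant_to_row_and_cluster_order(self):
        df = make_clusters(8, 10, sd_slope=1.0, seed=11)
        spec = LmmSpec("y", ("cue", "x"), ("intercept", "cue"))
        fit1 = fit_lmm(spec, df)
        shuffled = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        shuffled["participant"] = shuffled["participant"].map(
            lambda s: f"z{s}")  # relabel clusters, changing their sort order
        fit2 = fit_lmm(spec, shuffled)
        np.testing.assert_allclose(fit1.params["Estimate"], fit2.params["Estimate"],
                                   atol=1e-8)
        np.testing.assert_allclose(fit1.loglik, fit2.loglik, atol=1e-8)

    def test_balanced_intercept_variance_matches_anova_mom(self):
        """Balanced one-way layout: the REML intercept variance equals
        the ANOVA method-of-moments estimator (MSB - MSW) / T."""
        df = make_clusters(25, 12, sd_int=4.0, sd_resid=3.0,
                           beta=(50.0, 0.0, 0.0), seed=13)
        fit = fit_lmm(LmmSpec("y", (), ("intercept",)), df)
        g = df.groupby("participant")["y"]
        T = 12
        msb = T * g.mean().var(ddof=1)
        msw = g.apply(lambda s: s.var(ddof=1)).mean()
        np.testing.assert_allclose(fit.variance_components["intercept"],
                                   (msb - msw) / T, rtol=1e-6)
        np.testing.assert_allclose(fit.residual_variance, msw, rtol=1e-6)

    def test_matches_statsmodels_diagonal_mixedlm(self):
        """Independent cross-check against statsmodels MixedLM with the
        off-diagonal random-effect covariances pinned to zero."""
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        df = make_clusters(20, 10, sd_slope=2.0, seed=17)
        fit = fit_lmm(LmmSpec("y", ("cue", "x"), ("intercept", "cue")), df)
        X = sm.add_constant(df[["cue", "x"]])
        exog_re = np.column_stack([np.ones(len(df)), df["cue"]])
        free = MixedLMParams.from_components(fe_params=np.ones(3), cov_re=np.eye(2))
        ref = sm.MixedLM(df["y"], X, groups=df["participant"],
                         exog_re=exog_re).fit(free=free, reml=True, method="lbfgs")
        np.testing.assert_allclose(fit.params["Estimate"].to_numpy(),
                                   ref.fe_params.to_numpy(), rtol=1e-5)
        np.testing.assert_allclose(
            [fit.variance_components["intercept"], fit.variance_components["cue"]],
            np.diag(ref.cov_re), rtol=1e-3)
        np.testing.assert_allclose(fit.loglik, ref.llf, atol=1e-5)


class TestInformationCriteria:
    def test_bic_arithmetic(self):
        df = make_clusters(6, 8, seed=19)
        entry = information_criteria(LmmSpec("y", ("cue",), ("intercept",)), df)
        expected = -2.0 * entry["loglik_ml"] + entry["n_params"] * np.log(6 * 8)
        np.testing.assert_allclose(entry["bic"], expected, atol=1e-12)
        # -2*(-100) + 4*ln(50) = 215.648... (definition check)
        np.testing.assert_allclose(-2 * -100 + 4 * np.log(50), 215.64809, atol=1e-5)

    def test_nested_model_has_higher_ml_loglik(self):
        df = make_clusters(10, 10, sd_slope=1.0, seed=23)
        small = information_criteria(LmmSpec("y", ("cue",), ("intercept",)), df)
        big = information_criteria(
            LmmSpec("y", ("cue", "x"), ("intercept", "cue")), df)
        assert big["loglik_ml"] >= small["loglik_ml"] - 1e-6

    def test_comparison_delta_is_positive(self):
        df = make_clusters(10, 10, sd_slope=1.5, seed=29)
        comp = ModelComparison(entries=[
            information_criteria(LmmSpec("y", ("cue",), ("intercept",)), df),
            information_criteria(LmmSpec("y", ("cue",), ("intercept", "cue")), df),
        ])
        assert comp.usable
        assert comp.delta_bic >= 0.0


class TestPruning:
    def test_confounded_random_slope_is_removed(self):
        """A random cue slope on a mediator that is constant within each
        (participant, level) cell absorbs the residual entirely; the
        engine must flag the failure and prune the term."""
        rng = np.random.default_rng(31)
        rows = []
        for j in range(12):
            b1, b2 = rng.normal(60, 10), rng.normal(50, 10)
            for cue, b in ((1.0, b1), (-1.0, b2)):
                for _ in range(5):
                    rows.append((f"p{j}", cue, b))
        df = pd.DataFrame(rows, columns=["participant", "cue", "belief"])
        df["belief_c"] = df["belief"] - df.groupby("participant")["belief"].transform("mean")
        spec = LmmSpec("belief_c", ("cue",), ("cue",))
        final, log, fit = prune_random_effects(spec, df)
        assert final.random_terms == ()
        assert "estimation failure" in log[0]["reason"] or "boundary" in log[0]["reason"]
        assert fit.converged

    def test_supported_random_slope_is_kept(self):
        df = make_clusters(40, 20, sd_slope=2.5, seed=37)
        spec = LmmSpec("y", ("cue", "x"), ("intercept", "cue"))
        final, log, fit = prune_random_effects(spec, df)
        assert final.random_terms == ("intercept", "cue")
        assert log == []
        assert fit.variance_components["cue"] > 1.0

    def test_single_cluster_prunes_to_fixed_only(self):
        df = make_clusters(1, 20, seed=41)
        spec = LmmSpec("y", ("cue",), ("intercept", "cue"))
        final, log, fit = prune_random_effects(spec, df)
        assert final.random_terms == ()
        assert len(log) == 2
        assert fit.converged

    def test_blups_recovered_for_random_intercept(self):
        df = make_clusters(30, 30, sd_int=8.0, sd_resid=2.0,
                           beta=(50.0, 0.0, 0.0), seed=43)
        fit = fit_lmm(LmmSpec("y", (), ("intercept",)), df)
        observed = df.groupby("participant")["y"].mean()
        # shrinkage is mild at this SNR: BLUP intercepts track cluster means
        assert np.corrcoef(fit.blups["intercept"],
                           observed.loc[fit.blups.index])[0, 1] > 0.99


class TestSatterthwaite:
    def test_fixed_only_df_is_residual_df(self):
        df = make_clusters(5, 8, seed=47)
        fit = fit_lmm(LmmSpec("y", ("cue",)), df)
        assert (fit.params["df"] == len(df) - 2).all()

    def test_cluster_level_df_near_cluster_count(self):
        """With a strong random intercept, the intercept df must reflect
        the number of clusters, not the number of trials."""
        df = make_clusters(20, 30, sd_int=10.0, sd_resid=2.0, seed=53)
        fit = fit_lmm(LmmSpec("y", ("cue", "x"), ("intercept",)), df)
        assert 10 < fit.params.loc["Intercept", "df"] < 25
        # trial-level covariate keeps a trial-level df
        assert fit.params.loc["x", "df"] > 400
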