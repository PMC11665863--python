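"""GLMM/LMM estimation: oracle equivalence, inference, predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import trapezoid
from scipy.special import expit

from fishwarm import (
    ModelSpec,
    fit_glmm,
    fit_lmm,
    glmm_marginal_loglik,
    predict_probability,
    slope_sensitivity,
)
from fishwarm.mixedmodels import build_design

from conftest import toy_glmm_data

EXPIT_1 = 0.731058578630004879251159241822
EXPIT_HALF = 0.622459331201854564638900565746


def dense_loglik(y, X, gidx, beta, sigma, lo=-8.0, hi=8.0, n=201):
    """Independent oracle: per-group trapezoid integration of the marginal
    likelihood over the standardized random effect."""
    grid = np.linspace(lo, hi, n)
    total = 0.0
    for j in np.unique(gidx):
        m = gidx == j
        eta0 = X[m] @ beta
        lp = np.array(
            [
                np.sum(y[m] * (eta0 + sigma * v) - np.logaddexp(0.0, eta0 + sigma * v))
                for v in grid
            ]
        )
        dens = np.exp(lp) * np.exp(-grid**2 / 2.0) / np.sqrt(2.0 * np.pi)
        total += np.log(trapezoid(dens, grid))
    return total


class TestGlmmLikelihood:
    def test_agq_matches_dense_integration(self):
        df = toy_glmm_data(seed=42)
        spec = ModelSpec(response="y", fixed_terms=["position"])
        y, X, *_, gidx, _, _ = build_design(df, spec)
        for beta, sigma in [((-0.4, 1.1), 0.9), ((0.2, -0.5), 0.3), ((0.0, 0.0), 1.5)]:
            ours = glmm_marginal_loglik(y, X, gidx, beta, sigma, method="agq", agq_nodes=15)
            oracle = dense_loglik(y, X, gidx, np.asarray(beta), sigma)
            assert abs(ours - oracle) / abs(oracle) < 1e-6

    def test_laplace_close_to_dense_integration(self):
        df = toy_glmm_data(seed=1, n_groups=30, n_per=10)
        spec = ModelSpec(response="y", fixed_terms=["position"])
        y, X, *_, gidx, _, _ = build_design(df, spec)
        ours = glmm_marginal_loglik(y, X, gidx, np.array([-0.4, 1.1]), 0.9, method="laplace")
        oracle = dense_loglik(y, X, gidx, np.array([-0.4, 1.1]), 0.9)
        assert abs(ours - oracle) / abs(oracle) < 5e-3

    def test_sigma_zero_equals_plain_logistic_loglik(self):
        df = toy_glmm_data(seed=3)
        spec = ModelSpec(response="y", fixed_terms=["position"])
        y, X, *_, gidx, _, _ = build_design(df, spec)
        beta = np.array([0.1, 0.7])
        ours = glmm_marginal_loglik(y, X, gidx, beta, 0.0)
        eta = X @ beta
        glm_ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        assert ours == pytest.approx(glm_ll, abs=1e-10)


class TestFitGlmm:
    def test_sigma_zero_data_matches_irls_oracle(self, rng):
        # no group heterogeneity: estimates must match plain logistic
        # regression fitted by IRLS (statsmodels GLM)
        n = 600
        x = rng.uniform(0, 1, n)
        g = np.repeat(np.arange(30), 20)
        y = (rng.random(n) < expit(-0.2 + 0.9 * x)).astype(int)
        df = pd.DataFrame({"y": y, "position": x, "species": g})
        fit = fit_glmm(df, ModelSpec(response="y", fixed_terms=["position"]))
        X = sm.add_constant(x)
        irls = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.random_intercept_sd < 0.15
        assert fit.coefficients["estimate"].to_numpy() == pytest.approx(
            irls.params, abs=2e-2
        )
        # with sigma pinned at zero the match is to optimizer precision
        ll0 = glmm_marginal_loglik(
            df["y"].to_numpy(), X, g, irls.params, 0.0
        )
        assert ll0 == pytest.approx(irls.llf, abs=1e-6)

    def test_intercept_only_balanced_responses(self):
        df = pd.DataFrame(
            {"y": [0, 1] * 60, "species": np.repeat(np.arange(12), 10)}
        )
        fit = fit_glmm(df, ModelSpec(response="y", fixed_terms=[]))
        assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-4)

    def test_recovers_toy_parameters_within_wald_band(self):
        df = toy_glmm_data(seed=42, n_groups=60, n_per=25, beta1=1.1)
        fit = fit_glmm(df, ModelSpec(response="y", fixed_terms=["position"]))
        assert fit.converged
        assert abs(fit.coef("position") - 1.1) < 2.5 * fit.se("position")
        assert 0.3 < fit.random_intercept_sd < 1.6

    def test_laplace_and_agq_estimates_agree(self):
        df = toy_glmm_data(seed=9)
        spec = ModelSpec(response="y", fixed_terms=["position"])
        la = fit_glmm(df, spec, method="laplace")
        ag = fit_glmm(df, spec, method="agq", agq_nodes=15)
        assert la.coef("position") == pytest.approx(ag.coef("position"), abs=0.02)

    def test_determinism(self):
        df = toy_glmm_data(seed=5)
        spec = ModelSpec(response="y", fixed_terms=["position"])
        f1, f2 = fit_glmm(df, spec), fit_glmm(df, spec)
        pd.testing.assert_frame_equal(f1.coefficients, f2.coefficients)
        assert f1.log_likelihood == f2.log_likelihood

    def test_scaling_contract(self):
        df = toy_glmm_data(seed=21)
        df["elevation"] = np.exp(np.random.default_rng(2).normal(5, 1, len(df)))
        spec = ModelSpec(
            response="y",
            fixed_terms=["position", "elevation"],
            scale_predictors=True,
        )
        y, X, names, scale_info, *_ = build_design(df, spec)
        j = names.index("elevation")
        assert X[:, j].mean() == pytest.approx(0.0, abs=1e-10)
        assert X[:, j].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        # position stays unscaled by convention
        assert scale_info["position"] == ("identity",)
        # coefficients transform by the scale factor when scaling is toggled
        fit_s = fit_glmm(df, spec)
        fit_u = fit_glmm(
            df,
            ModelSpec(
                response="y",
                fixed_terms=["position", "elevation"],
                scale_predictors=False,
            ),
        )
        sd = df["elevation"].std(ddof=1)
        assert fit_s.coef("elevation") == pytest.approx(
            fit_u.coef("elevation") * sd, rel=0.02, abs=5e-3
        )


class TestFitLmm:
    def test_zero_group_variance_matches_ols(self, rng):
        n = 300
        x = rng.uniform(0, 1, n)
        g = np.repeat(np.arange(20), 15)
        resp = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"resp": resp, "position": x, "species": g})
        fit = fit_lmm(df, ModelSpec(response="resp", fixed_terms=["position"],
                                    family="gaussian"))
        X = sm.add_constant(x)
        ols = np.linalg.solve(X.T @ X, X.T @ resp)
        assert fit.coefficients["estimate"].to_numpy() == pytest.approx(ols, abs=2e-2)

    def test_duplicated_data_halves_variance(self, rng):
        n = 200
        x = rng.uniform(0, 1, n)
        g = np.repeat(np.arange(20), 10)
        resp = 1.0 + 2.0 * x + rng.normal(0, 0.6, n) + rng.normal(0, 0.5, 20)[g]
        df = pd.DataFrame({"resp": resp, "position": x, "species": g})
        spec = ModelSpec(response="resp", fixed_terms=["position"], family="gaussian")
        single = fit_lmm(df, spec)
        double = fit_lmm(pd.concat([df, df], ignore_index=True), spec)
        # near-identical point estimates (the ML variance components shift
        # slightly with group size, reweighting the GLS fit); the SE of the
        # within-group predictor shrinks by sqrt(2) as information doubles.
        # The intercept SE does not: the number of groups is unchanged and
        # between-group variance dominates it.
        assert double.coef("position") == pytest.approx(single.coef("position"), rel=0.01)
        assert double.se("position") == pytest.approx(
            single.se("position") / np.sqrt(2.0), rel=0.05
        )


class TestPredictProbability:
    def _fake_fit(self, beta, cov=None):
        df = toy_glmm_data(seed=4)
        fit = fit_glmm(df, ModelSpec(response="y", fixed_terms=["position"]))
        fit.coefficients.loc[:, "estimate"] = beta
        if cov is not None:
            fit.cov_fixed = cov
        return fit

    def test_logistic_values_on_grid(self):
        fit = self._fake_fit([0.0, 1.0])
        grid = predict_probability(fit, positions=np.array([0.5, 1.0]))
        assert grid.loc[0, "probability"] == pytest.approx(EXPIT_HALF, abs=1e-9)
        assert grid.loc[1, "probability"] == pytest.approx(EXPIT_1, abs=1e-9)

    def test_probability_half_where_linear_predictor_vanishes(self):
        fit = self._fake_fit([-1.0, 2.0])
        grid = predict_probability(fit, positions=np.array([0.5]))
        assert grid.loc[0, "probability"] == pytest.approx(0.5, abs=1e-9)

    def test_ci_width_shrinks_with_information(self):
        fit = self._fake_fit([0.0, 1.0], cov=np.eye(2) * 1e-12)
        grid = predict_probability(fit, positions=np.array([0.3]))
        width = grid.loc[0, "ci_high"] - grid.loc[0, "ci_low"]
        assert width < 1e-5


class TestSlopeSensitivity:
    def test_strong_effect_agrees_in_sign(self, rng):
        n, G = 900, 45
        g = np.repeat(np.arange(G), n // G)
        x = rng.uniform(0, 1, n)
        latent = -0.5 + 2.0 * x + rng.normal(0, 0.9, G)[g] + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"y": (latent > 0).astype(int), "slope": latent, "position": x, "species": g}
        )
        out = slope_sensitivity(df, ModelSpec(response="y", fixed_terms=["position"]))
        assert out.sign_agreement
        assert out.binomial.coef("position") > 0
        assert out.gaussian.coef("position") > 0

    def test_position_permutation_nulls_both(self, rng):
        n, G = 900, 45
        g = np.repeat(np.arange(G), n // G)
        x = rng.uniform(0, 1, n)
        latent = -0.5 + 2.0 * x + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"y": (latent > 0).astype(int), "slope": latent, "position": x, "species": g}
        )
        df["position"] = rng.permutation(df["position"].to_numpy())
        out = slope_sensitivity(df, ModelSpec(response="y", fixed_terms=["position"]))
        assert abs(out.binomial.coef("position")) < 2 * out.binomial.se("position")
        assert abs(out.gaussian.coef("position")) < 2 * out.gaussian.se("position")
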