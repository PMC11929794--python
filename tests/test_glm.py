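"""GLM chain: exact intercept MLEs, an independent joint-likelihood
oracle for the negative binomial, closed-form VIF, AICc arithmetic,
dredge marginality and backward pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from insularity import glm


def fit_nb_oracle(y, X):
    """Independent NB oracle: direct joint maximisation of the full
    log-likelihood over (beta, log theta) with Nelder–Mead restarts."""
    Xc = np.column_stack([np.ones(len(y)), X])

    def neg(params):
        beta, log_theta = params[:-1], params[-1]
        mu = np.exp(np.clip(Xc @ beta, -30, 30))
        return -glm.nb_loglik(np.asarray(y, float), mu, np.exp(log_theta))

    x0 = np.r_[np.log(np.mean(y) + 0.5), np.zeros(Xc.shape[1] - 1), 0.0]
    best = None
    for scale in (1.0, 0.3):
        res = optimize.minimize(neg, x0 * scale if scale != 1.0 else x0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:-1], np.exp(best.x[-1]), -best.fun


class TestScreenTransform:
    def test_normal_sample_unchanged(self):
        rng = np.random.default_rng(101)
        x = rng.normal(10, 1, 47)
        assert stats.shapiro(x).pvalue >= 0.05  # oracle premise
        pt = pd.DataFrame({"v": x})
        out, flags = glm.screen_transform(pt)
        assert not flags["v"]
        np.testing.assert_array_equal(out["v"], x)

    def test_lognormal_sample_transformed(self):
        rng = np.random.default_rng(7)
        x = np.exp(rng.normal(0, 1, 47))
        assert stats.shapiro(x).pvalue < 0.05  # oracle premise
        out, flags = glm.screen_transform(pd.DataFrame({"v": x}))
        assert flags["v"]
        np.testing.assert_allclose(out["v"], np.log10(x + 0.01))

    def test_constant_column_error(self):
        with pytest.raises(ValueError, match="constant"):
            glm.screen_transform(pd.DataFrame({"v": np.ones(30)}))

    def test_negative_values_error_or_keep(self):
        rng = np.random.default_rng(8)
        x = -np.exp(rng.normal(0, 1, 47))
        with pytest.raises(ValueError, match="undefined"):
            glm.screen_transform(pd.DataFrame({"v": x}))
        with pytest.warns(UserWarning, match="untransformed"):
            out, flags = glm.screen_transform(pd.DataFrame({"v": x}), on_domain_error="keep")
        assert not flags["v"]


class TestStandardize:
    def test_three_points(self):
        out = glm.standardize(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["v"], [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        x = rng.gamma(2, 3, 60)
        z1 = glm.standardize(pd.DataFrame({"v": x}))
        z2 = glm.standardize(z1)
        np.testing.assert_allclose(z1["v"], z2["v"], atol=1e-12)
        assert z1["v"].mean() == pytest.approx(0.0, abs=1e-9)
        assert z1["v"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            glm.standardize(pd.DataFrame({"v": np.full(10, 3.0)}))


class TestInterceptOnlyMles:
    def test_poisson_log_mean(self):
        fit = glm.fit_glm([2, 4, 6], pd.DataFrame(index=range(3)), "poisson")
        assert fit.params["const"] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_binomial_logit_proportion(self):
        fit = glm.fit_glm([30], pd.DataFrame(index=range(1)), "binomial", trials=[100])
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_intercept_only_pseudo_r2_zero(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(5, 40)
        fit = glm.fit_glm(y, pd.DataFrame(index=range(40)), "nb")
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-9)


class TestNegativeBinomial:
    def test_against_joint_likelihood_oracle(self):
        rng = np.random.default_rng(7)
        n, b0, b1, theta = 47, 2.0, 0.5, 4.0
        x = rng.normal(size=n)
        mu = np.exp(b0 + b1 * x)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        design = pd.DataFrame({"x": x})
        fit = glm.fit_glm(y, design, "nb")
        beta_o, theta_o, ll_o = fit_nb_oracle(y, x[:, None])
        assert fit.loglik == pytest.approx(ll_o, abs=1e-4)
        np.testing.assert_allclose(
            [fit.params["const"], fit.params["x"]], beta_o, atol=1e-3
        )
        assert fit.theta == pytest.approx(theta_o, rel=1e-2)
        # recovery: within 3 SE of the generating coefficients
        assert abs(fit.params["x"] - b1) < 3 * fit.bse["x"]
        assert abs(fit.params["const"] - b0) < 3 * fit.bse["const"]

    def test_deviance_identity(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        mu = np.exp(1.5 + 0.4 * x)
        y = rng.negative_binomial(3, 3 / (3 + mu))
        fit = glm.fit_glm(y, pd.DataFrame({"x": x}), "nb")
        assert fit.pseudo_r2 == pytest.approx(
            (fit.null_deviance - fit.residual_deviance) / fit.null_deviance, abs=1e-12
        )
        assert fit.residual_deviance <= fit.null_deviance


class TestOverdispersion:
    def test_equidispersed_near_one(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=200)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        fit = glm.fit_glm(y, pd.DataFrame({"x": x}), "poisson")
        ratio, flagged = glm.overdispersion_check(fit)
        assert 0.7 <= ratio <= 1.3
        assert not flagged

    def test_nb_counts_flagged(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=200)
        mu = np.exp(1.5 + 0.3 * x)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        fit = glm.fit_glm(y, pd.DataFrame({"x": x}), "poisson")
        ratio, flagged = glm.overdispersion_check(fit)
        assert ratio > 1.5 and flagged

    def test_saturated_df_error(self):
        fit = glm.fit_glm([3, 5], pd.DataFrame({"x": [0.0, 1.0]}), "poisson")
        with pytest.raises(ValueError, match="degrees of freedom"):
            glm.overdispersion_check(fit)


class TestVif:
    def test_orthogonal_predictors(self):
        n = 32
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        v = glm.vif(pd.DataFrame({"x1": x1, "x2": x2}))
        np.testing.assert_allclose(v, 1.0, atol=1e-6)

    def test_closed_form_from_correlation(self, rng):
        x1 = rng.normal(size=300)
        x2 = 0.8 * x1 + 0.6 * rng.normal(size=300)
        r = np.corrcoef(x1, x2)[0, 1]
        v = glm.vif(pd.DataFrame({"x1": x1, "x2": x2}))
        expect = 1.0 / (1.0 - r**2)
        assert v["x1"] == pytest.approx(expect, abs=1e-6)
        assert v["x2"] == pytest.approx(expect, abs=1e-6)

    def test_near_duplicate_explodes(self, rng):
        x1 = rng.normal(size=100)
        x2 = x1 + 1e-6 * rng.normal(size=100)
        v = glm.vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert (v > 1e6).all()

    def test_perfect_collinearity_is_inf(self):
        x1 = np.arange(10.0)
        v = glm.vif(pd.DataFrame({"x1": x1, "x2": 2 * x1}))
        assert np.isinf(v).all()


class TestAicc:
    def test_limit_matches_closed_form(self):
        ll, k = -123.4, 3
        for n in (50, 1000, 10**6):
            diff = glm.aicc_from(ll, k, n) - (-2 * ll + 2 * k)
            assert diff == pytest.approx(2 * k * (k + 1) / (n - k - 1), rel=1e-12)
        assert glm.aicc_from(ll, k, 10**6) - (-2 * ll + 2 * k) < 1e-4

    def test_hand_computed_ordering_one_candidate(self, rng):
        x = rng.normal(size=40)
        y = rng.poisson(np.exp(1.0 + 0.8 * x))
        pt = pd.DataFrame({"x": x})
        table, best = glm.dredge_aicc(y, pt, ["x"], "poisson")
        assert len(table) == 2
        f_null = glm.fit_glm(y, pd.DataFrame(index=range(40)), "poisson")
        f_full = glm.fit_glm(y, pt, "poisson")
        by_terms = table.set_index("terms")["aicc"]
        assert by_terms["(intercept)"] == pytest.approx(glm.aicc_from(f_null.loglik, 1, 40))
        assert by_terms["x"] == pytest.approx(glm.aicc_from(f_full.loglik, 2, 40))
        assert best.terms == ["x"]


class TestDredge:
    def test_marginality_structural(self, rng):
        x = rng.normal(size=50)
        y = rng.poisson(np.exp(1.0 + 0.3 * x - 0.4 * x**2))
        pt = pd.DataFrame({"x": x})
        table, _ = glm.dredge_aicc(y, pt, ["x", "x^2"], "poisson")
        for label in table["terms"]:
            terms = label.split(" + ")
            if "x^2" in terms:
                assert "x" in terms
        assert len(table) == 3  # {}, {x}, {x, x²}

    def test_strong_single_effect_selected(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=["x1", "x2", "x3"])
        y = rng.poisson(np.exp(1.5 + 0.9 * x["x1"]))
        table, best = glm.dredge_aicc(y, x, ["x1", "x2", "x3"], "poisson")
        assert "x1" in best.terms and len(table) == 8
        assert table.iloc[0]["delta_aicc"] == 0.0

    def test_nested_poisson_deviance_monotone(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x1", "x2", "x3"])
        y = rng.poisson(np.exp(1.0 + 0.5 * x["x1"] + 0.2 * x["x2"]))
        devs = [
            glm.fit_glm(y, x[cols], "poisson").residual_deviance
            for cols in (["x1"], ["x1", "x2"], ["x1", "x2", "x3"])
        ]
        assert devs[0] >= devs[1] >= devs[2]


class TestScanAndFinalize:
    def test_hump_shape_detected(self, rng):
        x = rng.normal(size=80)
        y = rng.poisson(np.exp(2.0 + 0.4 * x - 0.7 * x**2))
        pt = glm.standardize(pd.DataFrame({"x": x}))
        scan = glm.single_predictor_scan(y, pt, "poisson")
        quad = scan[scan["form"] == "quadratic"].iloc[0]
        lin = scan[scan["form"] == "linear"].iloc[0]
        assert quad["p_quadratic"] < 0.05
        assert quad["pseudo_r2"] > lin["pseudo_r2"]
        assert glm.candidate_terms_from_scan(scan) == ["x", "x^2"]

    def test_noise_free_link_linear_saturates(self):
        x = np.linspace(-1, 1, 30)
        y = np.round(np.exp(3.0 + 1.2 * x)).astype(int)
        fit = glm.fit_glm(y, pd.DataFrame({"x": x}), "poisson")
        assert fit.pseudo_r2 > 0.99

    def test_finalize_fixed_point(self, rng):
        x = pd.DataFrame(rng.normal(size=(80, 2)), columns=["x1", "x2"])
        y = rng.poisson(np.exp(1.0 + 0.8 * x["x1"] + 0.7 * x["x2"]))
        fit = glm.fit_glm(y, x, "poisson")
        final = glm.finalize_model(fit, y, x, "poisson")
        assert final.terms == ["x1", "x2"]

    def test_planted_null_dropped(self, rng):
        x = pd.DataFrame(rng.normal(size=(80, 2)), columns=["x1", "null"])
        y = rng.poisson(np.exp(1.5 + 0.9 * x["x1"].to_numpy()))
        fit = glm.fit_glm(y, x, "poisson")
        final = glm.finalize_model(fit, y, x, "poisson")
        assert "null" not in final.terms

    def test_collinear_pair_pruned_to_one(self, rng):
        z = rng.normal(size=100)
        x = pd.DataFrame({"a": z, "b": z + 0.01 * rng.normal(size=100)})
        y = rng.poisson(np.exp(1.0 + 0.8 * z))
        fit = glm.fit_glm(y, x, "poisson")
        final = glm.finalize_model(fit, y, x, "poisson")
        assert len(final.terms) == 1 and final.terms[0] in {"a", "b"}
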