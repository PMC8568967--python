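"""Mixed-model fitter: GLM equivalence, quadrature, Wald tests, pseudo-R2."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from nectarweb.formula import linear, quadratic
from nectarweb.glmm import (
    fit_glmm,
    fit_glmm_terms,
    pseudo_r2,
    select_random_effect,
    wald_type2,
)


class TestFitting:
    def test_single_group_equals_glm(self, glmm_sim):
        import statsmodels.api as sm

        d = glmm_sim
        fit = fit_glmm(d["X"], d["y"], np.zeros(len(d["y"])), trials=d["m"])
        glm = sm.GLM(
            np.column_stack([d["y"], d["m"] - d["y"]]), d["X"], family=sm.families.Binomial()
        ).fit()
        assert fit.sigma_u == 0.0
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)
        assert np.allclose(fit.beta, glm.params, atol=1e-8)
        # AIC still counts the (inestimable) variance parameter
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (d["X"].shape[1] + 1))

    def test_quadrature_refinement_stable(self, glmm_sim):
        d = glmm_sim
        f15 = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"], nodes=15)
        f51 = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"], nodes=51)
        assert abs(f15.loglik - f51.loglik) < 1e-6
        assert np.allclose(f15.beta, f51.beta, atol=1e-5)

    def test_laplace_close_but_distinct(self, glmm_sim):
        d = glmm_sim
        f1 = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"], nodes=1)
        f15 = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"], nodes=15)
        assert abs(f1.loglik - f15.loglik) < 1.0

    def test_poisson_family(self):
        rng = np.random.default_rng(4)
        n, strips = 60, np.repeat([1, 2, 3], 20)
        x = rng.normal(size=n)
        u = rng.normal(0, 0.4, 3)
        y = rng.poisson(np.exp(0.5 + 0.4 * x + u[strips - 1]))
        X = np.column_stack([np.ones(n), x])
        fit = fit_glmm(X, y, strips, family="poisson")
        assert fit.converged
        assert abs(fit.beta[1] - 0.4) < 0.2
        assert fit.sigma_u >= 0.0

    def test_matches_lme4_glmer(self, glmm_sim, tmp_path):
        """Independent oracle: R lme4 glmer with nAGQ=15 on the same data."""
        d = glmm_sim
        df = pd.DataFrame(
            {"y": d["y"], "m": d["m"], "x": d["X"][:, 1], "strip": d["strips"]}
        )
        csv = tmp_path / "dat.csv"
        df.to_csv(csv, index=False)
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            fit <- glmer(cbind(y, m - y) ~ x + (1 | strip), data = d,
                         family = binomial, nAGQ = 15)
            co <- summary(fit)$coefficients
            cat(co[,1], co[,2], sqrt(unlist(VarCorr(fit))), sep = "\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1, sig = map(float, out.stdout.split())
        fit = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"], nodes=15)
        assert fit.beta[0] == pytest.approx(b0, abs=2e-4)
        assert fit.beta[1] == pytest.approx(b1, abs=2e-4)
        assert fit.se[0] == pytest.approx(se0, rel=1e-3)
        assert fit.se[1] == pytest.approx(se1, rel=1e-3)
        assert fit.sigma_u == pytest.approx(sig, abs=2e-4)

    def test_nested_models_loglik_monotone(self, glmm_sim):
        d = glmm_sim
        X1 = d["X"][:, :1]
        f0 = fit_glmm(X1, d["y"], d["strips"], trials=d["m"])
        f1 = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"])
        X2 = np.column_stack([d["X"], d["x"] ** 2])
        f2 = fit_glmm(X2, d["y"], d["strips"], trials=d["m"])
        assert f1.loglik >= f0.loglik - 1e-6
        assert f2.loglik >= f1.loglik - 1e-6

    def test_deterministic_given_data(self, glmm_sim):
        d = glmm_sim
        a = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"])
        b = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"])
        assert a.loglik == b.loglik
        assert np.array_equal(a.beta, b.beta)


class TestRandomEffectSelection:
    def test_argmin_aic(self, glmm_sim):
        d = glmm_sim
        candidates = {
            "plot": np.arange(len(d["y"])),
            "strip": d["strips"],
            "block": np.repeat([1, 2, 3, 1, 2, 3, 1, 2, 3], 3),
        }
        best, fits = select_random_effect(
            d["X"], d["y"], candidates, trials=d["m"], restarts=1
        )
        aics = {k: f.aic for k, f in fits.items()}
        assert best == min(aics, key=aics.get)
        # strips generated the data, so they should win here
        assert best == "strip"

    def test_tie_takes_first(self, glmm_sim):
        d = glmm_sim
        candidates = {"first": d["strips"], "second": d["strips"].copy()}
        best, _ = select_random_effect(
            d["X"], d["y"], candidates, trials=d["m"], restarts=1
        )
        assert best == "first"


class TestWaldType2:
    def test_single_df_chi2_is_z_squared(self, glmm_sim):
        d = glmm_sim
        data = pd.DataFrame(
            {"y": d["y"], "m": d["m"], "x": d["X"][:, 1], "strip": d["strips"]}
        )
        fit = fit_glmm_terms(
            data, (linear("x"),), response="y", trials="m", group="strip"
        )
        tab = wald_type2(fit)
        z = fit.beta[1] / fit.se[1]
        assert tab.loc["x", "chisq"] == pytest.approx(z**2, rel=1e-10)
        assert tab.loc["x", "df"] == 1
        assert set(tab.index) == {"x"}  # absent terms not reported

    def test_quadratic_form_oracle(self, glmm_sim):
        d = glmm_sim
        rng = np.random.default_rng(9)
        data = pd.DataFrame(
            {
                "y": d["y"], "m": d["m"], "x": d["X"][:, 1],
                "w": rng.normal(size=len(d["y"])), "strip": d["strips"],
            }
        )
        terms = (linear("x"), linear("w"))
        fit = fit_glmm_terms(data, terms, response="y", trials="m", group="strip")
        tab = wald_type2(fit)
        for name in ("x", "w"):
            j = fit.names.index(name)
            b = np.array([fit.beta[j]])
            V = fit.cov_beta[np.ix_([j], [j])]
            brute = float(b @ np.linalg.solve(V, b))
            assert tab.loc[name, "chisq"] == pytest.approx(brute, rel=1e-8)

    def test_marginality_refit_for_contained_terms(self, glmm_sim):
        d = glmm_sim
        data = pd.DataFrame(
            {"y": d["y"], "m": d["m"], "x": d["X"][:, 1], "strip": d["strips"]}
        )
        terms = (linear("x"), quadratic("x"))
        fit = fit_glmm_terms(data, terms, response="y", trials="m", group="strip")
        tab = wald_type2(fit)
        # the linear term is tested in a refit without its quadratic relative
        sub = fit_glmm_terms(data, (linear("x"),), response="y", trials="m", group="strip")
        z = sub.beta[1] / sub.se[1]
        assert tab.loc["x", "chisq"] == pytest.approx(z**2, rel=1e-6)
        # the highest-order term is tested in the full model
        j = fit.names.index("x^2")
        z2 = fit.beta[j] / fit.se[j]
        assert tab.loc["x^2", "chisq"] == pytest.approx(z2**2, rel=1e-10)


class TestPseudoR2:
    def test_sigma_zero_marginal_equals_conditional(self, glmm_sim):
        d = glmm_sim
        fit = fit_glmm(d["X"], d["y"], np.zeros(len(d["y"])), trials=d["m"])
        m, c = pseudo_r2(fit)
        assert m == pytest.approx(c)

    def test_intercept_only_marginal_zero(self, glmm_sim):
        d = glmm_sim
        fit = fit_glmm(d["X"][:, :1], d["y"], d["strips"], trials=d["m"])
        m, c = pseudo_r2(fit)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert c >= m

    def test_hand_formula_binomial(self, glmm_sim):
        d = glmm_sim
        fit = fit_glmm(d["X"], d["y"], d["strips"], trials=d["m"])
        var_f = np.var(d["X"] @ fit.beta)
        denom = var_f + fit.sigma_u**2 + np.pi**2 / 3
        m, c = pseudo_r2(fit)
        assert m == pytest.approx(var_f / denom, abs=1e-8)
        assert c == pytest.approx((var_f + fit.sigma_u**2) / denom, abs=1e-8)

    def test_hand_formula_poisson(self):
        rng = np.random.default_rng(2)
        n, strips = 60, np.repeat([1, 2, 3], 20)
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.8 + 0.3 * x))
        X = np.column_stack([np.ones(n), x])
        fit = fit_glmm(X, y, strips, family="poisson")
        var_f = np.var(X @ fit.beta)
        var_d = np.log1p(1.0 / np.exp(fit.beta[0]))
        m, c = pseudo_r2(fit)
        assert m == pytest.approx(var_f / (var_f + fit.sigma_u**2 + var_d), abs=1e-8)
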