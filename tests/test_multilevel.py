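"""Random-intercept logistic fitting, its quadrature, and the variance
reporting measures."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prevdecomp.core import CovariateSpec
from prevdecomp.multilevel import (
    ModelSpec,
    aic,
    build_design,
    default_model_specs,
    fit_model_sequence,
    fit_random_intercept_logit,
    icc,
    pcv,
    vif,
)
from prevdecomp.multilevel import _Marginal


def brute_force_loglik(frame, beta0, sigma, n_grid=10_000, span=10.0):
    """Trapezoid integration of the marginal likelihood, cluster by
    cluster — an oracle independent of the quadrature code path."""
    u = np.linspace(-span * sigma, span * sigma, n_grid + 1)
    phi = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    y = frame["outcome"].to_numpy()
    ll = 0.0
    for _, sub in frame.groupby("cluster_id"):
        yc = sub["outcome"].to_numpy()
        p = expit(beta0 + u)[None, :]
        lik = np.prod(np.where(yc[:, None] == 1, p, 1 - p), axis=0)
        ll += np.log(np.trapezoid(lik * phi, u))
    return ll


class TestQuadrature:
    @pytest.mark.parametrize("beta0,sigma", [(-0.5, 0.7), (0.3, 1.5), (0.0, 0.2)])
    def test_marginal_loglik_matches_brute_force(self, toy_cluster_frame, beta0, sigma):
        codes = pd.Categorical(toy_cluster_frame["cluster_id"]).codes.astype(np.int64)
        X = np.ones((len(toy_cluster_frame), 1))
        marg = _Marginal(X, toy_cluster_frame["outcome"].to_numpy(), codes, nodes=15)
        got = marg.loglik(np.array([beta0]), sigma)
        want = brute_force_loglik(toy_cluster_frame, beta0, sigma)
        assert got == pytest.approx(want, abs=1e-6)

    def test_node_count_converged(self, toy_cluster_frame):
        codes = pd.Categorical(toy_cluster_frame["cluster_id"]).codes.astype(np.int64)
        X = np.ones((len(toy_cluster_frame), 1))
        ll7 = _Marginal(X, toy_cluster_frame["outcome"].to_numpy(), codes, 7).loglik(
            np.array([-0.5]), 0.9
        )
        ll15 = _Marginal(X, toy_cluster_frame["outcome"].to_numpy(), codes, 15).loglik(
            np.array([-0.5]), 0.9
        )
        assert abs(ll7 - ll15) < 1e-4


def clustered_frame(seed, C=60, m=25, sigma=0.8, alpha=-1.0, beta_x=0.7):
    rng = np.random.default_rng(seed)
    cl = np.repeat(np.arange(C), m)
    u = rng.normal(0, sigma, C)
    x = rng.choice(["lo", "hi"], C * m)
    eta = alpha + beta_x * (x == "hi") + u[cl]
    return pd.DataFrame(
        {
            "respondent_id": np.arange(C * m).astype(str),
            "wave": "w",
            "stratum_id": "s",
            "cluster_id": cl.astype(str),
            "weight": 1.0,
            "outcome": (rng.random(C * m) < expit(eta)).astype(int),
            "x": x,
        }
    )


class TestFitting:
    def test_sigma_zero_collapses_to_plain_logistic(self):
        import statsmodels.api as sm

        frame = clustered_frame(3, sigma=0.0)
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)))
        X, _ = build_design(frame, ["x"])
        glm = sm.GLM(frame["outcome"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.sigma2_u < 0.01
        assert np.abs(fit.beta - glm.params).max() < 1e-3

    def test_recovers_generating_parameters(self):
        frame = clustered_frame(11, C=150, m=30, sigma=0.9, alpha=-1.2, beta_x=0.7)
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)))
        assert fit.converged
        lo, hi = fit.sigma2_ci
        assert lo < 0.81 < hi  # true variance inside the Wald CI
        b = dict(zip(fit.terms, fit.beta))
        se = dict(zip(fit.terms, fit.se))
        assert abs(b["x[lo]"] + 0.7) < 3 * se["x[lo]"]  # "hi" is the reference

    def test_aic_consistent_with_loglik_and_k(self):
        frame = clustered_frame(5)
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)))
        assert fit.aic == pytest.approx(aic(fit.loglik, fit.k_params), abs=1e-10)
        assert fit.k_params == 3  # intercept + dummy + variance

    def test_weighted_pseudo_likelihood_runs(self):
        frame = clustered_frame(7)
        frame["weight"] = np.where(frame["x"] == "hi", 1.5, 0.7)
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)), use_weights=True)
        unw = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)))
        assert fit.converged
        assert fit.loglik != unw.loglik

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Cross-check against an independent implementation (lme4's
        adaptive-quadrature glmer) on a modest dataset."""
        frame = clustered_frame(23, C=50, m=12, sigma=0.9)
        csv = tmp_path / "d.csv"
        frame[["outcome", "cluster_id", "x"]].to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$x <- relevel(factor(d$x), ref = "hi")
            m <- glmer(outcome ~ x + (1 | cluster_id), data = d,
                       family = binomial, nAGQ = 7)
            cat(sprintf("%.8f %.8f %.8f\\n", as.numeric(logLik(m)),
                as.numeric(VarCorr(m)$cluster_id[1]), fixef(m)[["xlo"]]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ll_r, var_r, beta_r = map(float, out.stdout.split())
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)))
        assert fit.loglik == pytest.approx(ll_r, abs=5e-3)
        assert fit.sigma2_u == pytest.approx(var_r, rel=0.02)
        assert dict(zip(fit.terms, fit.beta))["x[lo]"] == pytest.approx(beta_r, abs=5e-3)

    def test_reference_level_from_schema(self):
        frame = clustered_frame(9)
        spec = CovariateSpec("x", ("lo", "hi"), reference="lo")
        fit = fit_random_intercept_logit(frame, ModelSpec("m", ("x",)), schema=[spec])
        assert fit.terms == ["Intercept", "x[hi]"]

    def test_requires_binary_outcome(self):
        frame = clustered_frame(1)
        frame.loc[0, "outcome"] = 2
        with pytest.raises(ValueError, match="binary"):
            fit_random_intercept_logit(frame, ModelSpec("m", ()))


class TestVarianceMeasures:
    def test_icc_endpoints_and_monotonicity(self):
        assert icc(0.0) == 0.0
        assert icc(np.pi**2 / 3) == pytest.approx(0.5)
        grid = np.linspace(0, 5, 50)
        vals = [icc(v) for v in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            icc(-0.1)

    def test_pcv_identity_and_monotonicity(self):
        assert pcv(0.5, 0.5) == 0.0
        assert pcv(0.74, 0.37) == pytest.approx(50.0)
        assert pcv(0.74, 0.49) > pcv(0.74, 0.59)
        with pytest.raises(ValueError):
            pcv(0.0, 0.1)

    def test_aic_base_case(self):
        assert aic(0.0, 1) == 2.0


class TestModelSequence:
    def test_ladder_on_synthetic_two_level_data(self, two_wave_frame, two_wave_config):
        sub = two_wave_frame[two_wave_frame["wave"] == "w1"]
        specs = default_model_specs(two_wave_config.covariate_specs)
        assert [s.label for s in specs] == ["Model-0", "Model-I", "Model-II", "Model-III"]
        report, fits = fit_model_sequence(
            sub, specs, schema=two_wave_config.covariate_specs
        )
        assert report.pcv[0] is None  # null model is the reference
        assert all(f.converged for f in fits)
        # the community covariate (residence, constant within clusters)
        # explains part of the between-cluster variance
        assert report.variance[2] < report.variance[0]
        assert report.variance[3] < report.variance[0]
        assert report.icc[3] < report.icc[0]
        table = report.to_frame()
        assert table.loc[0, "pcv_pct"] == "Reference"

    def test_aic_ranking_recomputable(self, two_wave_frame, two_wave_config):
        sub = two_wave_frame[two_wave_frame["wave"] == "w2"]
        specs = default_model_specs(two_wave_config.covariate_specs)[:2]
        report, fits = fit_model_sequence(sub, specs, schema=two_wave_config.covariate_specs)
        recomputed = [aic(f.loglik, f.k_params) for f in fits]
        assert np.argsort(report.aic).tolist() == np.argsort(recomputed).tolist()


class TestVif:
    def test_orthogonal_balanced_covariates_give_unit_vif(self):
        # perfectly balanced crossed design -> orthogonal dummies
        grid = pd.DataFrame(
            [(a, b) for a in ("a0", "a1") for b in ("b0", "b1") for _ in range(25)],
            columns=["f1", "f2"],
        )
        grid["respondent_id"] = grid.index.astype(str)
        grid["wave"], grid["stratum_id"], grid["cluster_id"] = "w", "s", "c"
        grid["weight"], grid["outcome"] = 1.0, 0
        table = vif(grid, ["f1", "f2"])
        assert np.allclose(table["vif"], 1.0, atol=1e-10)

    def test_duplicated_covariate_flagged_infinite(self):
        frame = clustered_frame(2)
        frame["x_copy"] = frame["x"]
        with pytest.warns(UserWarning, match="collinear"):
            table = vif(frame, ["x", "x_copy"])
        assert np.isinf(table["vif"]).all()

    def test_preset_covariates_pass_screen(self, two_wave_frame):
        table = vif(two_wave_frame, ["education", "residence"])
        assert (table["vif"] < 5).all()
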