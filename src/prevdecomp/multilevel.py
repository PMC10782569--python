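"""Two-level random-intercept logistic regression with ICC/PCV/AIC reporting.

The model for respondent *i* in cluster *c* is

    logit P(y_ic = 1) = x_ic' beta + u_c,     u_c ~ Normal(0, sigma_u^2),

with the cluster (primary sampling unit) as the grouping level.  The
marginal likelihood integrates the random intercept out of each cluster's
contribution; the integral is evaluated by *adaptive* Gauss-Hermite
quadrature (nodes centered at the mode of each cluster's integrand and
scaled by its curvature), which stays accurate for large clusters where
fixed-node quadrature degrades.  Maximization is over (beta, log sigma_u),
the log parameterization keeping the variance non-negative.

Between-cluster heterogeneity is summarized by the intraclass correlation
on the latent-response scale, ICC = sigma_u^2 / (sigma_u^2 + pi^2/3), and
by the proportional change in variance relative to the null model,
PCV = (V_null - V_model) / V_null.  Model comparison uses the maximized
log-likelihood and AIC with k = number of fixed effects + 1 variance
parameter.

Sampling weights enter, optionally, as a weighted pseudo-likelihood with
level-1 weights rescaled to sum to the cluster size ("method A" scaling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .core import CovariateSpec, SurveyRecord, as_frame

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MultilevelFit",
    "VarianceReport",
    "build_design",
    "fit_random_intercept_logit",
    "fit_model_sequence",
    "default_model_specs",
    "icc",
    "pcv",
    "aic",
    "vif",
]

_LATENT_RESIDUAL_VAR = np.pi**2 / 3.0  # latent-threshold residual variance, logit link


@dataclass(frozen=True)
class ModelSpec:
    """One model of the incremental sequence (null -> individual ->
    community -> full)."""

    label: str
    fixed_covariates: tuple[str, ...] = ()
    cluster_var: str = "cluster_id"


@dataclass
class MultilevelFit:
    """Result of one random-intercept logistic fit."""

    label: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_u: float
    sigma2_ci: tuple[float, float]
    loglik: float
    aic: float
    n_obs: int
    n_clusters: int
    converged: bool
    nodes: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        return len(self.terms) + 1  # fixed effects + variance

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """aOR table: exponentiated coefficients with Wald CIs (intercept
        excluded)."""
        q = stats.norm.ppf(0.5 + level / 2)
        rows = []
        for name, b, s in zip(self.terms, self.beta, self.se):
            if name == "Intercept":
                continue
            rows.append(
                {
                    "term": name,
                    "estimate": b,
                    "se": s,
                    "aOR": np.exp(b),
                    "ci_low": np.exp(b - q * s),
                    "ci_high": np.exp(b + q * s),
                    "p_value": 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VarianceReport:
    """Table of variance, ICC, PCV, log-likelihood and AIC per model."""

    models: tuple[str, ...]
    variance: tuple[float, ...]
    icc: tuple[float, ...]
    pcv: tuple[float | None, ...]  # None for the reference (null) model
    loglik: tuple[float, ...]
    aic: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "variance": self.variance,
                "icc_pct": [100 * v for v in self.icc],
                "pcv_pct": ["Reference" if v is None else 100 * v for v in self.pcv],
                "loglik": self.loglik,
                "aic": self.aic,
            }
        )


# ---------------------------------------------------------------------------
# scalar reporting measures


def icc(sigma2_u: float) -> float:
    """Latent-scale intraclass correlation, sigma2 / (sigma2 + pi^2/3)."""
    if sigma2_u < 0:
        raise ValueError("variance must be non-negative")
    return sigma2_u / (sigma2_u + _LATENT_RESIDUAL_VAR)


def pcv(v_null: float, v_model: float) -> float:
    """Proportional change in variance versus the null model, in percent."""
    if v_null <= 0:
        raise ValueError("null-model variance must be positive")
    return 100.0 * (v_null - v_model) / v_null


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2 loglik + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik + 2.0 * k


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    schema: Sequence[CovariateSpec] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with intercept.

    Reference categories come from ``schema`` when given; otherwise the
    lexicographically first observed category is the baseline.  Term names
    follow the ``covariate[category]`` convention.
    """
    by_name = {s.name: s for s in schema} if schema else {}
    cols = [np.ones(len(frame))]
    names = ["Intercept"]
    for cov in covariates:
        values = frame[cov].astype(str)
        if cov in by_name:
            spec = by_name[cov]
            cats, ref = list(spec.categories), spec.reference
            unknown = set(values.unique()) - set(cats)
            if unknown:
                raise ValueError(f"covariate {cov!r} has undeclared categories {unknown}")
        else:
            cats = sorted(values.unique())
            ref = cats[0]
        for cat in cats:
            if cat == ref:
                continue
            cols.append((values == cat).to_numpy(float))
            names.append(f"{cov}[{cat}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature


class _Marginal:
    """Evaluator of the marginal log-likelihood for fixed data.

    Observations are sorted by cluster once; per-cluster aggregation then
    uses contiguous ``reduceat`` segments.  Each evaluation locates every
    cluster's posterior mode by vectorized Newton steps, then applies
    mode-centered, curvature-scaled Gauss-Hermite quadrature.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cluster_codes: np.ndarray,
        nodes: int,
        weights: np.ndarray | None = None,
    ) -> None:
        order = np.argsort(cluster_codes, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(float)
        codes = cluster_codes[order]
        self.n_clusters = int(codes.max()) + 1
        self.starts = np.searchsorted(codes, np.arange(self.n_clusters))
        self.codes = codes
        if weights is None:
            self.w = np.ones(len(self.y))
        else:
            w = weights[order].astype(float)
            # "method A": rescale level-1 weights to sum to the cluster size
            cluster_w = np.add.reduceat(w, self.starts)
            cluster_n = np.add.reduceat(np.ones_like(w), self.starts)
            self.w = w * (cluster_n / cluster_w)[codes]
        gx, gw = hermgauss(nodes)
        self.gx, self.loggw = gx, np.log(gw)
        self._mode = np.zeros(self.n_clusters)

    def _sum_by_cluster(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta0 = self.X @ beta
        inv_s2 = 1.0 / (sigma * sigma)
        u = self._mode.copy()
        # Newton iterations for every cluster's posterior mode, vectorized
        for _ in range(50):
            p = expit(eta0 + u[self.codes])
            g = self._sum_by_cluster(self.w * (self.y - p)) - u * inv_s2
            h = -self._sum_by_cluster(self.w * p * (1.0 - p)) - inv_s2
            step = g / h
            np.clip(step, -4.0, 4.0, out=step)
            u -= step
            if np.max(np.abs(g)) < 1e-9:
                break
        self._mode = u  # warm start for the next evaluation
        tau = 1.0 / np.sqrt(-h)
        # nodes per cluster: u_ck = mode_c + sqrt(2) tau_c x_k
        U = u[:, None] + np.sqrt(2.0) * tau[:, None] * self.gx[None, :]
        eta = eta0[:, None] + U[self.codes]
        ll_obs = self.w[:, None] * (self.y[:, None] * eta - np.logaddexp(0.0, eta))
        ll_cluster = self._sum_by_cluster(ll_obs)
        prior = -0.5 * U * U * inv_s2 - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)
        exponent = self.loggw[None, :] + self.gx[None, :] ** 2 + ll_cluster + prior
        per_cluster = logsumexp(exponent, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
        return float(per_cluster.sum())


def _neg_loglik_factory(marg: _Marginal):
    def f(theta: np.ndarray) -> float:
        beta, s = theta[:-1], theta[-1]
        return -marg.loglik(beta, np.exp(s))

    return f


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def fit_random_intercept_logit(
    data: pd.DataFrame | Iterable[SurveyRecord],
    spec: ModelSpec,
    schema: Sequence[CovariateSpec] | None = None,
    quadrature_nodes: int = 7,
    use_weights: bool = False,
    tol: float = 1e-8,
) -> MultilevelFit:
    """Maximum-likelihood fit of the two-level random-intercept logit.

    Parameters
    ----------
    data
        Individual records (tidy frame or record sequence).
    spec
        Which covariates enter as fixed effects, and the cluster column.
    schema
        Covariate declarations fixing dummy-coding reference levels.
    quadrature_nodes
        Adaptive Gauss-Hermite node count (7 is ample for typical cluster
        sizes; the likelihood moves by < 1e-4 between 7 and 15 nodes).
    use_weights
        Use the sampling weights as a pseudo-likelihood (level-1 weights
        rescaled to cluster size).  The default is an unweighted ML fit.

    Non-convergence is reported through ``converged`` and ``diagnostics``
    rather than raised; suspected separation (|coef| > 15) is warned.
    """
    frame = as_frame(data)
    y = frame["outcome"].to_numpy(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary")
    clusters = pd.Categorical(frame[spec.cluster_var].astype(str))
    if len(clusters.categories) < 2:
        raise ValueError("need at least 2 clusters")
    X, names = build_design(frame, spec.fixed_covariates, schema)
    weights = frame["weight"].to_numpy(float) if use_weights else None
    marg = _Marginal(X, y, clusters.codes.astype(np.int64), quadrature_nodes, weights)
    neg = _neg_loglik_factory(marg)

    # initial values: ordinary logistic fit, sigma = 0.5
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=marg_weights(weights)).fit()
    x0 = np.append(glm.params, np.log(0.5))

    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(
        neg,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-6},
    )
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    sigma2 = sigma * sigma
    loglik = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)
    if np.any(np.abs(beta) > 15):
        warnings.warn("possible separation: a coefficient exceeds 15 in absolute value")

    # Wald covariance from the numerical Hessian of the negative loglik
    at_floor = sigma <= 1.5e-4
    se = np.full(X.shape[1], np.nan)
    sigma2_ci = (0.0, np.inf)
    try:
        H = _numeric_hessian(neg, res.x)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d[:-1] > 0).all():
            se = np.sqrt(d[:-1])
        if not at_floor and d[-1] > 0:
            se_s = np.sqrt(d[-1])
            q = stats.norm.ppf(0.975)
            sigma2_ci = (
                float(np.exp(np.minimum(2 * (res.x[-1] - q * se_s), 700.0))),
                float(np.exp(np.minimum(2 * (res.x[-1] + q * se_s), 700.0))),
            )
        elif at_floor:
            sigma2_ci = (0.0, 0.0)
    except np.linalg.LinAlgError:
        logger.warning("Hessian not invertible; standard errors unavailable")
        converged = False

    return MultilevelFit(
        label=spec.label,
        terms=names,
        beta=beta,
        se=se,
        sigma2_u=0.0 if at_floor else sigma2,
        sigma2_ci=sigma2_ci,
        loglik=loglik,
        aic=aic(loglik, X.shape[1] + 1),
        n_obs=len(y),
        n_clusters=len(clusters.categories),
        converged=converged,
        nodes=quadrature_nodes,
        diagnostics={"optimizer_message": str(res.message), "n_iter": int(res.nit)},
    )


def marg_weights(weights: np.ndarray | None) -> np.ndarray | None:
    """Weights for the initial GLM fit (identity passthrough)."""
    return weights


# ---------------------------------------------------------------------------
# model sequence


def default_model_specs(schema: Sequence[CovariateSpec]) -> list[ModelSpec]:
    """The standard four-model ladder: null, individual-level covariates,
    community-level covariates, and their union."""
    indiv = tuple(s.name for s in schema if s.level == "individual")
    comm = tuple(s.name for s in schema if s.level == "community")
    return [
        ModelSpec("Model-0", ()),
        ModelSpec("Model-I", indiv),
        ModelSpec("Model-II", comm),
        ModelSpec("Model-III", indiv + comm),
    ]


def fit_model_sequence(
    data: pd.DataFrame | Iterable[SurveyRecord],
    specs: Sequence[ModelSpec],
    schema: Sequence[CovariateSpec] | None = None,
    quadrature_nodes: int = 7,
    use_weights: bool = False,
) -> tuple[VarianceReport, list[MultilevelFit]]:
    """Fit an incremental model sequence on one common estimation sample.

    All models are fitted on the identical set of rows (rows with a missing
    value in any covariate used by *any* model must be removed first; a
    mismatch raises).  Returns the variance/ICC/PCV/loglik/AIC report (PCV
    is relative to the first, null, model) plus the individual fits.
    """
    frame = as_frame(data)
    needed = sorted({c for s in specs for c in s.fixed_covariates})
    if frame[needed].isna().any().any() if needed else False:
        raise ValueError(
            "missing covariate values: restrict to complete cases before fitting "
            "so all models share one estimation sample"
        )
    fits = [
        fit_random_intercept_logit(
            frame, s, schema=schema, quadrature_nodes=quadrature_nodes, use_weights=use_weights
        )
        for s in specs
    ]
    v0 = fits[0].sigma2_u
    report = VarianceReport(
        models=tuple(f.label for f in fits),
        variance=tuple(f.sigma2_u for f in fits),
        icc=tuple(icc(f.sigma2_u) for f in fits),
        pcv=tuple([None] + [pcv(v0, f.sigma2_u) / 100.0 for f in fits[1:]]),
        loglik=tuple(f.loglik for f in fits),
        aic=tuple(f.aic for f in fits),
    )
    return report, fits


# ---------------------------------------------------------------------------
# collinearity screen


def vif(
    data: pd.DataFrame | Iterable[SurveyRecord],
    covariates: Sequence[str],
    schema: Sequence[CovariateSpec] | None = None,
) -> pd.DataFrame:
    """Variance inflation factors of the dummy-coded design.

    Each dummy term is regressed on all remaining terms (with intercept);
    VIF = 1/(1 - R^2).  A perfectly collinear term is reported as ``inf``
    with a warning.  Returns one row per term with its parent covariate,
    so per-covariate maxima are a single groupby away.
    """
    frame = as_frame(data)
    try:
        X, names = build_design(frame, covariates, schema)
    except ValueError as exc:
        if "rank deficient" not in str(exc):
            raise
        # rebuild without the rank check to report the offending terms
        X, names = _design_no_rank_check(frame, covariates, schema)
    terms = names[1:]
    Xt = X[:, 1:]
    if Xt.shape[1] < 2:
        raise ValueError("need at least 2 dummy terms for a collinearity screen")
    rows = []
    for j, term in enumerate(terms):
        target = Xt[:, j]
        others = np.column_stack([np.ones(len(target)), np.delete(Xt, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
        if r2 > 1.0 - 1e-10:
            warnings.warn(f"term {term!r} is perfectly collinear; VIF infinite")
            value = np.inf
        else:
            value = 1.0 / (1.0 - r2)
        rows.append({"covariate": term.split("[")[0], "term": term, "vif": value})
    return pd.DataFrame(rows)


def _design_no_rank_check(frame, covariates, schema):
    by_name = {s.name: s for s in schema} if schema else {}
    cols, names = [np.ones(len(frame))], ["Intercept"]
    for cov in covariates:
        values = frame[cov].astype(str)
        if cov in by_name:
            cats, ref = list(by_name[cov].categories), by_name[cov].reference
        else:
            cats = sorted(values.unique())
            ref = cats[0]
        for cat in cats:
            if cat != ref:
                cols.append((values == cat).to_numpy(float))
                names.append(f"{cov}[{cat}]")
    return np.column_stack(cols), names
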