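"""Design-weighted prevalence, trend statistics, and chi-square screening.

Estimation follows standard complex-survey practice: the prevalence is the
ratio estimator ``sum(w*y)/sum(w)``; its variance comes from Taylor
linearization with clusters as primary sampling units nested in strata;
confidence intervals are built on the logit scale and back-transformed so
they stay inside [0, 1].  Association screens on clustered data use the
Rao-Scott corrected chi-square (first- or second-order); the classical
Pearson statistic is available for unit-weight, unclustered tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .core import SurveyRecord, as_frame

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceEstimate",
    "ChiSquareResult",
    "weighted_prevalence",
    "prevalence_ratio",
    "relative_change",
    "design_chisq",
    "counts_frame",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A design-weighted prevalence with its design-based uncertainty."""

    domain: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    wn: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.domain}: {100 * self.p_hat:.1f}% "
            f"(95% CI {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}), n={self.n}"
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: float
    p_value: float
    method: str


DomainLike = Callable[[pd.DataFrame], "pd.Series"] | "pd.Series" | np.ndarray | None


def _domain_mask(frame: pd.DataFrame, domain: DomainLike) -> np.ndarray:
    if domain is None:
        return np.ones(len(frame), dtype=bool)
    if callable(domain):
        mask = np.asarray(domain(frame), dtype=bool)
    else:
        mask = np.asarray(domain, dtype=bool)
    if mask.shape != (len(frame),):
        raise ValueError("domain mask length does not match the data")
    return mask


def _cluster_variance(frame: pd.DataFrame, z: np.ndarray) -> float:
    """Between-cluster variance of a linearized total, stratified.

    ``z`` holds per-observation influence values; the variance is
    ``sum_h n_h/(n_h-1) sum_c (z_hc - zbar_h)^2`` over cluster totals
    ``z_hc``.  Strata containing a single cluster are treated as certainty
    units (zero contribution) with a logged warning.
    """
    dd = pd.DataFrame(
        {"stratum": frame["stratum_id"].values, "cluster": frame["cluster_id"].values, "z": z}
    )
    totals = dd.groupby(["stratum", "cluster"], sort=False)["z"].sum()
    var = 0.0
    for stratum, zc in totals.groupby(level=0, sort=False):
        n_h = len(zc)
        if n_h < 2:
            logger.warning(
                "stratum %r has a single cluster: treated as a certainty unit", stratum
            )
            continue
        var += n_h / (n_h - 1) * float(((zc - zc.mean()) ** 2).sum())
    return var


def weighted_prevalence(
    data: pd.DataFrame | Iterable[SurveyRecord],
    domain: DomainLike = None,
    domain_label: str = "all",
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Design-weighted prevalence of the binary outcome over a domain.

    The point estimate is the Hajek ratio ``sum(w y)/sum(w)`` over the
    domain; the standard error comes from Taylor linearization of the ratio
    with clusters as PSUs within strata (clusters with no domain member
    still contribute zero totals, as in standard domain estimation).  The
    confidence interval is symmetric on the logit scale with a Student-t
    reference on (clusters - strata) degrees of freedom.
    """
    frame = as_frame(data)
    mask = _domain_mask(frame, domain)
    if not mask.any():
        raise ValueError(f"domain {domain_label!r} selects no records")
    w = frame["weight"].to_numpy(float) * mask
    y = frame["outcome"].to_numpy(float)
    W = w.sum()
    p_hat = float((w * y).sum() / W)
    z = w * (y - p_hat) / W
    var = _cluster_variance(frame, z)
    se = float(np.sqrt(max(var, 0.0)))
    n = int(mask.sum())
    n_clusters = frame.groupby("stratum_id")["cluster_id"].nunique()
    df = int(n_clusters.sum() - len(n_clusters))
    q = stats.t.ppf(0.5 + level / 2, df) if df > 0 else stats.norm.ppf(0.5 + level / 2)
    if 0.0 < p_hat < 1.0 and se > 0:
        l = logit(p_hat)
        se_l = se / (p_hat * (1 - p_hat))
        ci_low = float(expit(l - q * se_l))
        ci_high = float(expit(l + q * se_l))
    else:
        ci_low = ci_high = p_hat
    return PrevalenceEstimate(
        domain=domain_label,
        p_hat=p_hat,
        se=se,
        ci_low=min(ci_low, p_hat),
        ci_high=max(ci_high, p_hat),
        n=n,
        wn=float(W),
    )


def prevalence_ratio(p_a: PrevalenceEstimate, p_b: PrevalenceEstimate) -> float:
    """Ratio of two prevalences, ``p_a / p_b``."""
    if p_b.p_hat <= 0:
        raise ZeroDivisionError("denominator prevalence is zero")
    return p_a.p_hat / p_b.p_hat


def relative_change(p_from: PrevalenceEstimate, p_to: PrevalenceEstimate) -> float:
    """Percent decline from ``p_from`` to ``p_to`` (positive = decline)."""
    if p_from.p_hat <= 0:
        raise ZeroDivisionError("baseline prevalence is zero")
    return 100.0 * (p_from.p_hat - p_to.p_hat) / p_from.p_hat


# ---------------------------------------------------------------------------
# chi-square screening


def design_chisq(
    data: pd.DataFrame | Iterable[SurveyRecord],
    factor: str,
    method: str = "rao-scott-2",
) -> ChiSquareResult:
    """Test of association between a categorical factor and the outcome.

    ``method="pearson"`` gives the classical chi-square on the weighted
    R x 2 table (identical to the textbook statistic under unit weights).
    ``"rao-scott-1"`` / ``"rao-scott-2"`` apply the first-order (mean
    design-effect) and second-order (Satterthwaite) Rao-Scott corrections,
    estimating the design covariance of the cell proportions by cluster
    linearization; the second-order correction also adjusts the reference
    degrees of freedom and is the appropriate default for weighted
    clustered data.
    """
    if method not in ("pearson", "rao-scott-1", "rao-scott-2"):
        raise ValueError(f"unknown method {method!r}")
    frame = as_frame(data)
    rows = pd.Categorical(frame[factor])
    if len(rows.categories) < 2:
        raise ValueError(f"factor {factor!r} is constant")
    cols = frame["outcome"].to_numpy(int)
    w = frame["weight"].to_numpy(float)
    R, C = len(rows.categories), 2
    n = len(frame)

    # weighted cell proportions, vectorized over the RC cells
    cell = rows.codes * C + cols
    W = w.sum()
    p = np.bincount(cell, weights=w, minlength=R * C) / W
    P = p.reshape(R, C)
    prow = P.sum(axis=1)
    pcol = P.sum(axis=0)
    E = np.outer(prow, pcol)
    if (n * E < 1).any():
        warnings.warn("expected cell count below 1; chi-square may be unreliable")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(E > 0, (P - E) ** 2 / E, 0.0)
    x2 = float(n * contrib.sum())
    df = (R - 1) * (C - 1)

    if method == "pearson":
        return ChiSquareResult(x2, df, float(stats.chi2.sf(x2, df)), method)

    # design covariance of the RC cell proportions via linearization
    ind = np.zeros((n, R * C))
    ind[np.arange(n), cell] = 1.0
    z = (w[:, None] * (ind - p)) / W
    dd = pd.DataFrame(z)
    dd["stratum"] = frame["stratum_id"].values
    dd["cluster"] = frame["cluster_id"].values
    totals = dd.groupby(["stratum", "cluster"], sort=False).sum()
    V = np.zeros((R * C, R * C))
    for stratum, zc in totals.groupby(level=0, sort=False):
        n_h = len(zc)
        if n_h < 2:
            logger.warning(
                "stratum %r has a single cluster: treated as a certainty unit", stratum
            )
            continue
        dev = zc.to_numpy() - zc.to_numpy().mean(axis=0)
        V += n_h / (n_h - 1) * dev.T @ dev

    # Jacobian of h = p_rc - p_r+ p_+c with respect to the cell proportions
    H = np.zeros((R * C, R * C))
    for r in range(R):
        for c in range(C):
            for r2 in range(R):
                for c2 in range(C):
                    H[r * C + c, r2 * C + c2] = (
                        (r == r2) * (c == c2) - (r == r2) * pcol[c] - (c == c2) * prow[r]
                    )
    Vh = H @ V @ H.T
    V0h = H @ ((np.diag(p) - np.outer(p, p)) / n) @ H.T

    # generalized design effects: eigenvalues of pinv(V0_h) V_h on the
    # (R-1)(C-1)-dimensional contrast space
    eig = np.linalg.eigvals(np.linalg.pinv(V0h) @ Vh)
    delta = np.sort(np.real(eig))[::-1][:df]
    delta = np.clip(delta, 1e-12, None)
    dbar = float(delta.mean())
    if method == "rao-scott-1":
        stat = x2 / dbar
        return ChiSquareResult(stat, df, float(stats.chi2.sf(stat, df)), method)
    cv2 = float(((delta - dbar) ** 2).mean() / dbar**2)
    stat = x2 / (dbar * (1.0 + cv2))
    df_adj = df / (1.0 + cv2)
    return ChiSquareResult(stat, df_adj, float(stats.chi2.sf(stat, df_adj)), method)


# ---------------------------------------------------------------------------
# reconstruction of estimates from published count tables


def counts_frame(counts: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Unit-weight individual data reconstructed from per-wave count pairs.

    ``counts[wave] = (n_tested, n_not_tested)``.  Each respondent forms her
    own pseudo-cluster in a single stratum, so design-based estimates reduce
    to their simple-random-sampling form — the convention under which
    published aggregate tables can be re-analyzed.
    """
    frames = []
    for wave, (n_yes, n_no) in counts.items():
        n = n_yes + n_no
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": [f"{wave}-{i}" for i in range(n)],
                    "wave": wave,
                    "stratum_id": "all",
                    "cluster_id": [f"{wave}-{i}" for i in range(n)],
                    "weight": 1.0,
                    "outcome": [1] * n_yes + [0] * n_no,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
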