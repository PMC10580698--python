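"""Causal estimators and heterogeneity diagnostics for two-sample MR.

Given harmonized per-SNP effects (gamma_j ± se_xj on the exposure, Gamma_j ±
se_yj on the outcome), the causal log-odds ratio theta is estimated by:

* Wald ratio — Gamma_j / gamma_j for a single SNP;
* IVW — inverse-variance-weighted mean of the ratios with first-order
  weights w_j = gamma_j²/se_yj², equivalently weighted zero-intercept
  regression of Gamma on gamma, with multiplicative random-effects SE
  inflation max(1, sqrt(Q/(J-1)));
* MR-Egger — weighted regression with free intercept; a nonzero intercept
  indicates directional pleiotropy, the slope remains causal under InSIDE;
* weighted median — consistent when >=50% of weight comes from valid
  instruments; SE by seeded parametric bootstrap;
* RAPS — robust adjusted profile score, tolerant of weak instruments and
  balanced pleiotropy through an overdispersion parameter tau².

Cochran's Q (IVW flavor on the ratio scale, Egger flavor on regression
residuals) quantifies heterogeneity. All p-values are two-sided normal or
chi-square upper-tail; estimates carry odds-ratio transforms of the
log-odds results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import integrate, optimize, stats

from .errors import EstimationError, InsufficientInstrumentsError
from .harmonize import HarmonizedPair, HarmonizedSet

#: two-sided 95% normal quantile, fixed across the package
Z95 = 1.959964


@dataclass
class MREstimate:
    """A causal estimate on the log-odds scale with its OR transform."""

    method: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_: Optional[float] = None
    or_low: Optional[float] = None
    or_high: Optional[float] = None


@dataclass
class EggerResult:
    """MR-Egger slope (causal) and intercept (directional-pleiotropy test)."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class QResult:
    """Cochran heterogeneity statistic with its chi-square p-value."""

    method: str
    Q: float
    df: int
    pval: float


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _make_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    ci_low = beta - Z95 * se
    ci_high = beta + Z95 * se
    p = _two_sided_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    p = max(p, np.nextafter(0, 1))
    est = MREstimate(
        method=method, beta_hat=float(beta), se=float(se),
        ci_low=float(ci_low), ci_high=float(ci_high), pval=p, n_snp=n_snp,
    )
    return estimate_to_or(est)


def estimate_to_or(est: MREstimate) -> MREstimate:
    """Populate the odds-ratio fields by exponentiating the log-odds fields."""
    return replace(
        est,
        or_=math.exp(est.beta_hat),
        or_low=math.exp(est.ci_low),
        or_high=math.exp(est.ci_high),
    )


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE se_y/|gamma|."""
    if pair.gamma == 0:
        raise EstimationError(f"Wald ratio undefined for gamma = 0 ({pair.rsid})")
    beta = pair.Gamma / pair.gamma
    se = pair.se_y / abs(pair.gamma)
    return _make_estimate("Wald ratio", beta, se, 1)


def _ivw_arrays(gamma: np.ndarray, Gamma: np.ndarray, se_y: np.ndarray):
    """Fixed-effect IVW point estimate and Q on the ratio scale."""
    w = gamma**2 / se_y**2
    ratios = Gamma / gamma
    sum_w = w.sum()
    theta = float((w * ratios).sum() / sum_w)
    Q = float((w * (ratios - theta) ** 2).sum())
    return theta, Q, sum_w


def ivw(hset: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    A single-pair set is by definition the Wald ratio.
    """
    n = hset.n_snp
    if n == 0:
        raise InsufficientInstrumentsError(0, 1, context="IVW")
    if n == 1:
        est = wald_ratio(hset.pairs[0])
        return replace(est, method="IVW")
    theta, Q, sum_w = _ivw_arrays(hset.gamma, hset.Gamma, hset.se_y)
    inflation = max(1.0, math.sqrt(Q / (n - 1)))
    se = math.sqrt(1.0 / sum_w) * inflation
    return _make_estimate("IVW", theta, se, n)


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Pairs are oriented so gamma >= 0 (both signs flipped otherwise); SEs
    carry multiplicative inflation max(1, sqrt(Q'/(J-2))) from the
    regression's Cochran statistic.
    """
    n = hset.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(n, 3, context="MR-Egger")
    sign = np.where(hset.gamma < 0, -1.0, 1.0)
    g = hset.gamma * sign
    G = hset.Gamma * sign
    w = 1.0 / hset.se_y**2
    X = sm.add_constant(g)
    res = sm.WLS(G, X, weights=w).fit()
    intercept, slope = res.params
    q_egger = float(res.ssr)  # weighted residual sum of squares
    inflation = max(1.0, math.sqrt(q_egger / (n - 2)))
    ncov = res.normalized_cov_params
    se_intercept = math.sqrt(ncov[0, 0]) * inflation
    se_slope = math.sqrt(ncov[1, 1]) * inflation
    return EggerResult(
        slope=_make_estimate("MR-Egger", slope, se_slope, n),
        intercept=float(intercept),
        intercept_se=se_intercept,
        intercept_pval=_two_sided_p(intercept / se_intercept),
    )


def _weighted_median_point(betas: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With normalized weights sorted by beta, the cumulative midpoint score
    s_j = cumsum(w)_j - w_j/2 is piecewise linear in beta; the estimate is
    the beta at which it crosses 0.5 (clamped to the extremes).
    """
    order = np.argsort(betas)
    b = betas[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: Optional[int] = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    The bootstrap resamples gamma_j and Gamma_j from normal(observed, se)
    and recomputes the weighted median; the SE is the standard deviation of
    the replicates. ``seed`` makes the bootstrap reproducible.
    """
    n = hset.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(n, 3, context="weighted median")
    gamma, Gamma, se_x, se_y = hset.gamma, hset.Gamma, hset.se_x, hset.se_y
    w = gamma**2 / se_y**2
    point = _weighted_median_point(Gamma / gamma, w)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(gamma, se_x, size=(n_boot, n))
    G_star = rng.normal(Gamma, se_y, size=(n_boot, n))
    w_star = g_star**2 / se_y**2
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = _weighted_median_point(G_star[i] / g_star[i], w_star[i])
    se = float(reps.std(ddof=1))
    return _make_estimate("Weighted median", point, se, n)


# --- RAPS -------------------------------------------------------------------

_HUBER_C = 1.345
_TUKEY_C = 4.685


def _psi(t: np.ndarray, loss: str, c: float) -> np.ndarray:
    if loss == "l2":
        return t
    if loss == "huber":
        return np.clip(t, -c, c)
    if loss == "tukey":
        out = t * (1.0 - (t / c) ** 2) ** 2
        return np.where(np.abs(t) < c, out, 0.0)
    raise EstimationError(f"unknown loss {loss!r}")


@lru_cache(maxsize=None)
def _psi_delta(loss: str, c: float) -> float:
    """E[psi(Z)·Z] for Z ~ N(0,1): centers the overdispersion equation."""
    if loss == "l2":
        return 1.0
    if loss == "huber":
        return 2.0 * stats.norm.cdf(c) - 1.0
    val, _ = integrate.quad(
        lambda z: _psi(np.array([z]), loss, c)[0] * z * stats.norm.pdf(z),
        -c, c,
    )
    return float(val)


def raps(
    hset: HarmonizedSet,
    overdispersion: bool = True,
    loss: str = "huber",
    c: Optional[float] = None,
    max_iter: int = 200,
) -> MREstimate:
    """Robust adjusted profile-score estimate of the causal effect.

    Profiles out the true instrument effects: with standardized residuals
    t_j(theta) = (Gamma_j - theta·gamma_j) / sqrt(se_yj² + theta²·se_xj² + tau²),
    theta solves the robust profile score sum_j psi(t_j)·dt_j/dtheta = 0 and,
    when ``overdispersion`` is on, tau² >= 0 solves
    sum_j [psi(t_j)·t_j - E(psi(Z)Z)] = 0. The default Huber influence
    (c = 1.345) bounds the leverage of pleiotropic outliers; ``l2`` recovers
    the plain profile likelihood. SE is the sandwich estimate at the
    solution.
    """
    n = hset.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(n, 3, context="RAPS")
    if c is None:
        c = {"huber": _HUBER_C, "tukey": _TUKEY_C, "l2": 1.0}[loss]
    gamma, Gamma, se_x, se_y = hset.gamma, hset.Gamma, hset.se_x, hset.se_y
    delta = _psi_delta(loss, c)

    def score(theta: float, tau2: float) -> float:
        var = se_y**2 + theta**2 * se_x**2 + tau2
        sd = np.sqrt(var)
        t = (Gamma - theta * gamma) / sd
        # -dt/dtheta = gamma/sd + t * theta * se_x² / var
        u = gamma / sd + t * theta * se_x**2 / var
        return float(np.sum(_psi(t, loss, c) * u))

    def overdisp_eq(tau2: float, theta: float) -> float:
        sd = np.sqrt(se_y**2 + theta**2 * se_x**2 + tau2)
        t = (Gamma - theta * gamma) / sd
        return float(np.sum(_psi(t, loss, c) * t) - n * delta)

    def solve_theta(tau2: float, start: float) -> float:
        lo = hi = start
        step = max(0.1, abs(start))
        f_lo = f_hi = score(start, tau2)
        for _ in range(80):
            if f_lo > 0 > f_hi or f_lo < 0 < f_hi:
                break
            lo -= step
            hi += step
            f_lo, f_hi = score(lo, tau2), score(hi, tau2)
            step *= 2.0
        else:
            raise EstimationError(
                f"RAPS: could not bracket the profile-score root "
                f"(start={start:.4g}, tau2={tau2:.4g})"
            )
        return float(optimize.brentq(score, lo, hi, args=(tau2,), xtol=1e-12))

    def solve_tau2(theta: float) -> float:
        if overdisp_eq(0.0, theta) <= 0:
            return 0.0
        hi = float(np.mean(se_y**2))
        for _ in range(80):
            if overdisp_eq(hi, theta) < 0:
                break
            hi *= 2.0
        else:
            raise EstimationError("RAPS: overdispersion equation has no root")
        return float(optimize.brentq(overdisp_eq, 0.0, hi, args=(theta,), xtol=1e-14))

    # start from the fixed-effect IVW estimate
    theta, _, _ = _ivw_arrays(gamma, Gamma, se_y)
    tau2 = 0.0
    for _ in range(max_iter):
        theta_new = solve_theta(tau2, theta)
        tau2_new = solve_tau2(theta_new) if overdispersion else 0.0
        done = abs(theta_new - theta) < 1e-11 and abs(tau2_new - tau2) < 1e-13
        theta, tau2 = theta_new, tau2_new
        if done:
            break
    else:
        raise EstimationError(
            f"RAPS did not converge in {max_iter} iterations "
            f"(theta={theta:.4g}, tau2={tau2:.4g})"
        )

    # sandwich SE: sqrt(B)/|A| with B the squared score contributions and
    # A the numerical derivative of the score at the solution
    var = se_y**2 + theta**2 * se_x**2 + tau2
    sd = np.sqrt(var)
    t = (Gamma - theta * gamma) / sd
    u = gamma / sd + t * theta * se_x**2 / var
    B = float(np.sum((_psi(t, loss, c) * u) ** 2))
    h = 1e-6 * max(1.0, abs(theta))
    A = (score(theta + h, tau2) - score(theta - h, tau2)) / (2 * h)
    if A == 0:
        raise EstimationError("RAPS: degenerate score derivative")
    se = math.sqrt(B) / abs(A)
    return _make_estimate("MR.RAPS", theta, se, n)


def cochran_q(hset: HarmonizedSet, method: str = "ivw") -> QResult:
    """Cochran heterogeneity statistic.

    ``ivw``: Q = sum w_j (beta_j - theta_fixed)² on the ratio scale with
    w_j = gamma_j²/se_yj², df = J - 1. ``egger``: weighted residual sum of
    squares of the intercept regression, df = J - 2.
    """
    n = hset.n_snp
    method = method.lower()
    if method == "ivw":
        df = n - 1
        if df < 1:
            raise InsufficientInstrumentsError(n, 2, context="Cochran Q (IVW)")
        _, Q, _ = _ivw_arrays(hset.gamma, hset.Gamma, hset.se_y)
    elif method == "egger":
        df = n - 2
        if df < 1:
            raise InsufficientInstrumentsError(n, 3, context="Cochran Q (Egger)")
        sign = np.where(hset.gamma < 0, -1.0, 1.0)
        g, G = hset.gamma * sign, hset.Gamma * sign
        res = sm.WLS(G, sm.add_constant(g), weights=1.0 / hset.se_y**2).fit()
        Q = float(res.ssr)
    else:
        raise EstimationError(f"unknown Q flavor {method!r}")
    return QResult(method=method.upper() if method == "ivw" else "Egger",
                   Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))
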