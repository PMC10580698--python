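"""MR-PRESSO: pleiotropy residual sum and outlier tests.

Three simulation-based tests on a harmonized set:

* global test — the observed residual sum of squares (RSS), built from
  leave-one-out IVW predictions, against a parametric null distribution
  simulated from the observed effects and their SEs;
* outlier test — each SNP's observed RSS contribution against its own
  simulated distribution, with Bonferroni adjustment across SNPs;
* distortion test — whether removing the flagged outliers materially moves
  the IVW estimate, calibrated against random same-sized removals.

Empirical p-values use the add-one rule, so the smallest attainable p is
1/(n_sim + 1). Leave-one-out IVW inside PRESSO uses fixed-effect weights
for speed and determinism. All randomness is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EstimationError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    """Bundle of the global, outlier and distortion test outputs."""

    global_rss: float
    global_p: float
    outlier_p: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    distortion_p: Optional[float] = None
    raw_estimate: Optional[MREstimate] = None
    corrected_estimate: Optional[MREstimate] = None
    n_sim: int = 0
    seed: Optional[int] = None


def _loo_contributions(gamma, Gamma, se_y):
    """Per-SNP RSS contributions w_j (Gamma_j - theta_{-j} gamma_j)².

    theta_{-j} is the fixed-effect IVW estimate with SNP j left out.
    Accepts 1-D observed arrays or 2-D (n_sim, J) simulated arrays.
    """
    w = gamma**2 / se_y**2
    ratios = Gamma / gamma
    sw = w.sum(axis=-1, keepdims=True)
    swr = (w * ratios).sum(axis=-1, keepdims=True)
    theta_loo = (swr - w * ratios) / (sw - w)
    return w * (Gamma - theta_loo * gamma) ** 2


def _simulate_contributions(hset: HarmonizedSet, n_sim: int, rng) -> np.ndarray:
    gamma, Gamma, se_x, se_y = hset.gamma, hset.Gamma, hset.se_x, hset.se_y
    w = gamma**2 / se_y**2
    ratios = Gamma / gamma
    sw, swr = w.sum(), (w * ratios).sum()
    theta_loo = (swr - w * ratios) / (sw - w)
    g_star = rng.normal(gamma, se_x, size=(n_sim, gamma.size))
    G_star = rng.normal(theta_loo * gamma, se_y, size=(n_sim, gamma.size))
    return _loo_contributions(g_star, G_star, se_y)


def _empirical_p(count_ge: int, n_sim: int) -> float:
    return (1 + count_ge) / (n_sim + 1)


def presso_global(
    hset: HarmonizedSet, n_sim: int = 1000, seed: Optional[int] = None
) -> tuple[float, float]:
    """Global pleiotropy test: observed RSS vs its simulated null."""
    _require(hset)
    rng = np.random.default_rng(seed)
    d_obs = _loo_contributions(hset.gamma, hset.Gamma, hset.se_y)
    rss_obs = float(d_obs.sum())
    rss_star = _simulate_contributions(hset, n_sim, rng).sum(axis=1)
    p = _empirical_p(int((rss_star >= rss_obs).sum()), n_sim)
    return rss_obs, p


def presso_outlier(
    hset: HarmonizedSet, n_sim: int = 1000, seed: Optional[int] = None
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test with Bonferroni-adjusted empirical p-values."""
    _require(hset)
    rng = np.random.default_rng(seed)
    d_obs = _loo_contributions(hset.gamma, hset.Gamma, hset.se_y)
    d_star = _simulate_contributions(hset, n_sim, rng)
    return _outlier_from_contributions(hset, d_obs, d_star, n_sim)


def _outlier_from_contributions(hset, d_obs, d_star, n_sim):
    J = hset.n_snp
    rsids = hset.rsids
    outlier_p: dict[str, float] = {}
    outliers: list[str] = []
    for j, rsid in enumerate(rsids):
        p_raw = _empirical_p(int((d_star[:, j] >= d_obs[j]).sum()), n_sim)
        p_adj = min(1.0, p_raw * J)
        outlier_p[rsid] = p_adj
        if p_adj < 0.05:
            outliers.append(rsid)
    return outlier_p, outliers


def presso_distortion(
    hset: HarmonizedSet,
    outliers: list[str],
    n_sim: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, MREstimate]:
    """Distortion test: does removing the outliers move the IVW estimate?

    The statistic is (theta_raw - theta_corrected)/theta_corrected; its
    reference distribution comes from removing random subsets of the same
    size.
    """
    if not outliers:
        raise EstimationError("distortion test requires a nonempty outlier list")
    keep = [i for i, r in enumerate(hset.rsids) if r not in set(outliers)]
    if not keep:
        raise EstimationError("all SNPs flagged as outliers; cannot correct")
    raw = ivw(hset)
    corrected = ivw(hset.subset(keep))
    if corrected.beta_hat == 0:
        raise EstimationError("corrected estimate is exactly zero; distortion undefined")
    stat = (raw.beta_hat - corrected.beta_hat) / corrected.beta_hat

    rng = np.random.default_rng(seed)
    J = hset.n_snp
    k = J - len(keep)
    stats_star = np.empty(n_sim)
    idx = np.arange(J)
    for b in range(n_sim):
        drop = rng.choice(idx, size=k, replace=False)
        sub = ivw(hset.subset(np.delete(idx, drop)))
        stats_star[b] = (raw.beta_hat - sub.beta_hat) / sub.beta_hat
    p = _empirical_p(int((np.abs(stats_star) >= abs(stat)).sum()), n_sim)
    return p, corrected


def run_presso(
    hset: HarmonizedSet, n_sim: int = 1000, seed: Optional[int] = None
) -> PressoResult:
    """Global, outlier and (when needed) distortion tests on shared simulations."""
    _require(hset)
    rng = np.random.default_rng(seed)
    d_obs = _loo_contributions(hset.gamma, hset.Gamma, hset.se_y)
    rss_obs = float(d_obs.sum())
    d_star = _simulate_contributions(hset, n_sim, rng)
    rss_star = d_star.sum(axis=1)
    global_p = _empirical_p(int((rss_star >= rss_obs).sum()), n_sim)
    outlier_p, outliers = _outlier_from_contributions(hset, d_obs, d_star, n_sim)

    result = PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        raw_estimate=ivw(hset),
        n_sim=n_sim,
        seed=seed,
    )
    if outliers:
        result.distortion_p, result.corrected_estimate = presso_distortion(
            hset, outliers, n_sim=n_sim, seed=rng.integers(2**31)
        )
    return result


def _require(hset: HarmonizedSet) -> None:
    if hset.n_snp < 4:
        raise InsufficientInstrumentsError(hset.n_snp, 4, context="MR-PRESSO")
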