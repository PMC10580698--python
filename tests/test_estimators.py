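"""Causal estimators: exact identities, equivariances, Monte-Carlo recovery."""

import math

import numpy as np
import pytest

from mr2s.errors import EstimationError, InsufficientInstrumentsError
from mr2s.estimators import (
    _weighted_median_point,
    cochran_q,
    egger,
    estimate_to_or,
    ivw,
    raps,
    wald_ratio,
    weighted_median,
)
from mr2s.harmonize import HarmonizedPair, HarmonizedSet
from mr2s.simulate import SimConfig, simulate_harmonized


def hset_from(gamma, Gamma, se_y, se_x=None):
    gamma = np.asarray(gamma, dtype=float)
    if se_x is None:
        se_x = np.full_like(gamma, 1e-8)
    return HarmonizedSet.from_arrays(gamma, se_x, Gamma, se_y)


# --- Wald ratio -------------------------------------------------------------

@pytest.mark.parametrize(
    "Gamma, gamma, se_y, beta, se",
    [(0.05, 0.10, 0.10, 0.5, 1.0),
     (0.0, 0.2, 0.1, 0.0, 0.5),
     (-0.02, 0.04, 0.06, -0.5, 1.5)],
)
def test_wald_ratio_arithmetic(Gamma, gamma, se_y, beta, se):
    pair = HarmonizedPair("rs1", gamma=gamma, se_x=0.01, Gamma=Gamma, se_y=se_y)
    est = wald_ratio(pair)
    assert est.beta_hat == pytest.approx(beta)
    assert est.se == pytest.approx(se)


def test_wald_ratio_zero_gamma_undefined():
    with pytest.raises(EstimationError):
        wald_ratio(HarmonizedPair("rs1", gamma=0.0, se_x=0.01, Gamma=0.1, se_y=0.1))


# --- IVW --------------------------------------------------------------------

def test_ivw_hand_computed_weighted_average():
    h = hset_from([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1] * 3)
    est = ivw(h)
    assert est.beta_hat == pytest.approx(0.5)
    assert est.se == pytest.approx(1 / math.sqrt(14))  # weights (1, 4, 9), Q = 0
    assert cochran_q(h, "ivw").Q == pytest.approx(0.0, abs=1e-20)


def test_ivw_single_pair_equals_wald_ratio():
    h = hset_from([0.1], [0.05], [0.1])
    est = ivw(h)
    ref = wald_ratio(h.pairs[0])
    assert est.beta_hat == ref.beta_hat
    assert est.se == ref.se


def test_ivw_random_effects_inflation_floored_at_one():
    # heterogeneous ratios: inflation kicks in
    h = hset_from([0.1, 0.1, 0.1], [0.05, 0.0, -0.05], [0.01] * 3)
    q = cochran_q(h, "ivw").Q
    base = math.sqrt(1.0 / (3 * (0.1 / 0.01) ** 2))
    assert ivw(h).se == pytest.approx(base * math.sqrt(q / 2))
    # homogeneous ratios: no deflation below the fixed-effect SE
    h0 = hset_from([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1] * 3)
    assert ivw(h0).se >= math.sqrt(1.0 / 14) - 1e-15


# --- MR-Egger ---------------------------------------------------------------

def test_egger_exact_line_recovers_intercept_and_slope():
    g = np.array([0.1, 0.2, 0.3])
    h = hset_from(g, 0.02 + 0.5 * g, [0.1] * 3)
    res = egger(h)
    assert res.intercept == pytest.approx(0.02, abs=1e-12)
    assert res.slope.beta_hat == pytest.approx(0.5, abs=1e-12)
    assert cochran_q(h, "egger").Q == pytest.approx(0.0, abs=1e-18)


def test_egger_slope_equals_ivw_on_zero_intercept_line():
    g = np.array([0.1, 0.2, 0.3])
    h = hset_from(g, 0.5 * g, [0.1] * 3)
    assert egger(h).slope.beta_hat == pytest.approx(ivw(h).beta_hat, abs=1e-12)


def test_egger_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(hset_from([0.1, 0.2], [0.05, 0.1], [0.1] * 2))


def test_egger_intercept_recovers_directional_pleiotropy():
    """Mean intercept over replicates matches the planted mean direct effect."""
    reps = 200
    intercepts = []
    for i in range(reps):
        config = SimConfig(J=100, theta=0.1, pleio_frac=1.0, pleio_mean=0.03,
                           pleio_sd=0.01, seed=9_000 + i)
        h, _ = simulate_harmonized(config)
        intercepts.append(egger(h).intercept)
    assert abs(np.mean(intercepts) - 0.03) < 0.01


# --- weighted median --------------------------------------------------------

def test_weighted_median_all_ratios_equal():
    h = hset_from([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.1, 0.3, 0.7])
    assert weighted_median(h, n_boot=20, seed=0).beta_hat == pytest.approx(0.5)


def test_weighted_median_interpolation_hand_example():
    # ratios (0.1, 0.5, 0.9), normalized weights (0.2, 0.3, 0.5)
    w = np.array([0.2, 0.3, 0.5])
    h = hset_from([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], 1.0 / np.sqrt(w))
    est = weighted_median(h, n_boot=20, seed=0)
    assert est.beta_hat == pytest.approx(0.65)


def test_weighted_median_matches_exhaustive_oracle_small_sets():
    """Grid search over the piecewise-linear cumulative-weight curve."""
    rng = np.random.default_rng(21)
    for _ in range(30):
        j = rng.integers(3, 9)
        betas = rng.normal(0, 1, j)
        weights = rng.uniform(0.1, 1.0, j)
        fast = _weighted_median_point(betas, weights)
        order = np.argsort(betas)
        b, w = betas[order], weights[order] / weights.sum()
        s = np.cumsum(w) - w / 2
        grid = np.linspace(b[0], b[-1], 200_001)
        curve = np.interp(grid, b, s)
        oracle = grid[np.argmin(np.abs(curve - 0.5))]
        assert fast == pytest.approx(oracle, abs=(b[-1] - b[0]) / 100_000 + 1e-12)


def test_weighted_median_bootstrap_is_seeded():
    h = hset_from([0.1, 0.2, 0.3], [0.06, 0.09, 0.16], [0.1] * 3,
                  se_x=[0.01] * 3)
    a = weighted_median(h, n_boot=200, seed=7)
    b = weighted_median(h, n_boot=200, seed=7)
    c = weighted_median(h, n_boot=200, seed=8)
    assert a.se == b.se
    assert a.se != c.se


# --- RAPS -------------------------------------------------------------------

def test_raps_consistent_toy_matches_truth():
    h = hset_from([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1] * 3)
    est = raps(h, overdispersion=False, loss="l2")
    assert est.beta_hat == pytest.approx(0.5, abs=1e-6)


def test_raps_agrees_with_ivw_and_egger_on_noiseless_line():
    g = np.array([0.1, 0.2, 0.3])
    h = hset_from(g, 0.5 * g, [0.1] * 3)
    r = raps(h, overdispersion=False, loss="l2").beta_hat
    assert r == pytest.approx(ivw(h).beta_hat, abs=1e-6)
    assert r == pytest.approx(egger(h).slope.beta_hat, abs=1e-6)


def test_raps_two_snps_error():
    with pytest.raises(InsufficientInstrumentsError):
        raps(hset_from([0.1, 0.2], [0.05, 0.1], [0.1] * 2))


def test_raps_less_biased_than_ivw_under_weak_instruments():
    """With mean F around 15 the exposure noise dilutes IVW toward zero;
    the profile score accounts for it."""
    theta = 0.1
    reps = 300
    ivw_est, raps_est = [], []
    for i in range(reps):
        config = SimConfig(J=80, theta=theta, f_range=(10.0, 20.0),
                           n_exp=30_000, n_out=120_000, seed=40_000 + i)
        h, _ = simulate_harmonized(config)
        ivw_est.append(ivw(h).beta_hat)
        raps_est.append(raps(h, overdispersion=False, loss="l2").beta_hat)
    bias_ivw = abs(np.mean(ivw_est) - theta)
    bias_raps = abs(np.mean(raps_est) - theta)
    assert bias_raps < bias_ivw


def test_raps_huber_overdispersion_runs_on_pleiotropic_data():
    config = SimConfig(J=60, theta=0.2, pleio_frac=0.5, pleio_mean=0.0,
                       pleio_sd=0.05, seed=77)
    h, _ = simulate_harmonized(config)
    est = raps(h)  # defaults: huber, overdispersion on
    assert est.se > 0
    assert abs(est.beta_hat - 0.2) < 0.15


# --- Cochran Q --------------------------------------------------------------

def test_q_perfectly_consistent_ratios():
    h = hset_from([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.1] * 3)
    q = cochran_q(h, "ivw")
    assert q.Q == pytest.approx(0.0, abs=1e-20)
    assert q.pval == pytest.approx(1.0)
    assert q.df == 2


def test_q_two_term_hand_sum():
    # ratios 0 and 1 with equal weights w = 1 (se_y = gamma = 1)
    h = hset_from([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
    q = cochran_q(h, "ivw")
    assert q.Q == pytest.approx(0.5)
    assert q.df == 1


def test_q_rejection_rate_rises_with_pleiotropy_variance():
    """Balanced pleiotropy inflates Q; power is monotone in its variance."""
    rates = []
    for tau in (0.0, 0.02, 0.05):
        rejections = 0
        for i in range(300):
            config = SimConfig(J=30, theta=0.1, pleio_frac=1.0, pleio_mean=0.0,
                               pleio_sd=tau, seed=60_000 + i)
            h, _ = simulate_harmonized(config)
            if cochran_q(h, "ivw").pval < 0.05:
                rejections += 1
        rates.append(rejections / 300)
    assert rates[0] < rates[1] < rates[2]


def test_egger_q_df_is_n_minus_two():
    g = np.array([0.1, 0.2, 0.3, 0.4])
    h = hset_from(g, 0.02 + 0.5 * g, [0.1] * 4)
    assert cochran_q(h, "egger").df == 2


# --- equivariances and OR transform ----------------------------------------

def _pleiotropic_set(seed=123):
    config = SimConfig(J=20, theta=0.15, pleio_frac=0.3, pleio_sd=0.02, seed=seed)
    h, _ = simulate_harmonized(config)
    return h


def test_sign_equivariance_all_estimators():
    h = _pleiotropic_set()
    flipped = HarmonizedSet.from_arrays(h.gamma, h.se_x, -h.Gamma, h.se_y)
    assert ivw(flipped).beta_hat == pytest.approx(-ivw(h).beta_hat)
    assert egger(flipped).slope.beta_hat == pytest.approx(-egger(h).slope.beta_hat)
    assert weighted_median(flipped, n_boot=10, seed=0).beta_hat == pytest.approx(
        -weighted_median(h, n_boot=10, seed=0).beta_hat
    )
    assert raps(flipped, overdispersion=False, loss="l2").beta_hat == pytest.approx(
        -raps(h, overdispersion=False, loss="l2").beta_hat, abs=1e-8
    )


def test_scale_equivariance_all_estimators():
    h = _pleiotropic_set(321)
    c = 2.5
    scaled = HarmonizedSet.from_arrays(c * h.gamma, c * h.se_x, h.Gamma, h.se_y)
    assert ivw(scaled).beta_hat == pytest.approx(ivw(h).beta_hat / c)
    assert egger(scaled).slope.beta_hat == pytest.approx(egger(h).slope.beta_hat / c)
    assert weighted_median(scaled, n_boot=10, seed=0).beta_hat == pytest.approx(
        weighted_median(h, n_boot=10, seed=0).beta_hat / c
    )
    assert raps(scaled, overdispersion=False, loss="l2").beta_hat == pytest.approx(
        raps(h, overdispersion=False, loss="l2").beta_hat / c, abs=1e-8
    )


def test_estimators_invariant_under_allele_recoding():
    """Negating gamma and Gamma together (re-coding the effect allele) must
    leave every estimate unchanged; Egger relies on its gamma >= 0 orientation."""
    h = _pleiotropic_set(55)
    sign = np.where(np.arange(h.n_snp) % 3 == 0, -1.0, 1.0)
    recoded = HarmonizedSet.from_arrays(sign * h.gamma, h.se_x,
                                        sign * h.Gamma, h.se_y)
    assert ivw(recoded).beta_hat == pytest.approx(ivw(h).beta_hat)
    res, ref = egger(recoded), egger(h)
    assert res.slope.beta_hat == pytest.approx(ref.slope.beta_hat)
    assert res.intercept == pytest.approx(ref.intercept)
    assert weighted_median(recoded, n_boot=10, seed=0).beta_hat == pytest.approx(
        weighted_median(h, n_boot=10, seed=0).beta_hat
    )
    assert raps(recoded, overdispersion=False, loss="l2").beta_hat == pytest.approx(
        raps(h, overdispersion=False, loss="l2").beta_hat, abs=1e-8
    )


def test_or_transform_hand_example():
    h = hset_from([1.0], [-0.1863], [0.0770])
    est = estimate_to_or(ivw(h))
    assert round(est.or_, 2) == 0.83
    assert round(est.or_low, 2) == 0.71
    assert round(est.or_high, 2) == 0.97


def test_or_transform_null_and_monotone():
    h0 = hset_from([1.0], [0.0], [0.1])
    assert estimate_to_or(ivw(h0)).or_ == pytest.approx(1.0)
    ors = [estimate_to_or(ivw(hset_from([1.0], [b], [0.1]))).or_
           for b in (-0.2, 0.0, 0.3)]
    assert ors == sorted(ors)
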