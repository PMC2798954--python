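"""Persistence estimators: direct, fluctuation, excursion, calibration."""

import math

import numpy as np
import pytest

from metapersist.local_maps import LocalMapSpec
from metapersist.persistence import (
    apply_calibration,
    calibrate,
    estimate_direct,
    estimate_excursion,
    estimate_fluctuation,
    exact_single_patch_lifetime,
    lifetime_distribution_check,
    sweep_migration,
)
from metapersist.stochastic import make_rng
from metapersist.topology import build_topology


def test_certain_death_config_gives_tau_one():
    """A full single patch crashes deterministically: Binomial(lam N, 0) = 0."""
    from metapersist.stochastic import simulate_lifetimes

    spec = LocalMapSpec("logistic", N=40, lam=4.0)
    top = build_topology("chain_1d", 1)
    init = np.full((50, 1), 40, dtype=np.int64)
    lifetimes, censored = simulate_lifetimes(spec, top, 0.0, init, make_rng(0), 100)
    assert np.all(lifetimes == 1)
    assert not censored.any()


def test_direct_estimator_matches_markov_oracle():
    """Single patch N=20: mean lifetime within 3 SE of the exact
    absorbing-chain expectation (initial conditions drawn uniformly)."""
    spec = LocalMapSpec("logistic", N=20, lam=4.0)
    top = build_topology("chain_1d", 1)
    # oracle averaged over the uniform init rule on {1..N}
    exact = np.mean([exact_single_patch_lifetime(spec, n) for n in range(1, 21)])
    est = estimate_direct(spec, top, 0.0, reps=4000, rng=make_rng(2), max_gen=10_000)
    assert est.n_censored == 0
    assert est.tau_bar == pytest.approx(exact, abs=3 * est.se)


def test_lifetime_check_on_synthetic_exponential():
    rng = np.random.default_rng(0)
    lt = rng.exponential(100.0, size=10_000)
    rate, cv, ks, p = lifetime_distribution_check(lt)
    assert rate == pytest.approx(0.01, rel=0.05)
    assert cv == pytest.approx(1.0, abs=0.03)
    assert p > 0.01


def test_lifetime_check_rejects_constant_lifetimes():
    lt = np.full(500, 37.0)
    rate, cv, ks, p = lifetime_distribution_check(lt)
    assert cv == pytest.approx(0.0, abs=1e-12)
    assert p < 0.01


def test_lifetime_check_needs_enough_data():
    with pytest.raises(ValueError):
        lifetime_distribution_check(np.ones(50))


def test_fluctuation_score_arithmetic():
    """Gaussian series around 500 with sd 50 gives s2 = 500^2/(2*2500) = 50."""
    # synthetic check through the same formula the estimator applies
    n_bar, sigma2 = 500.0, 50.0**2
    assert n_bar**2 / (2 * sigma2) == pytest.approx(50.0)


def test_fluctuation_estimator_runs_and_orders(logistic4, two_patch):
    """Configs whose direct lifetimes differ sharply order their
    fluctuation scores the same way."""
    rng = make_rng(3)
    _, est_good = estimate_fluctuation(logistic4, two_patch, 0.15, rng,
                                       run_length=800, transient=100)
    _, est_poor = estimate_fluctuation(logistic4, two_patch, 0.45, rng,
                                       run_length=800, transient=100)
    assert est_good.raw_score > est_poor.raw_score


def test_fluctuation_estimator_fails_where_no_survival(two_patch):
    spec = LocalMapSpec("logistic", N=30, lam=4.0)
    with pytest.raises(RuntimeError):
        estimate_fluctuation(spec, two_patch, 0.0, make_rng(1),
                             run_length=5000, transient=100, max_retries=3)


def test_excursion_estimator_udud_exceeds_uudd(logistic4, ring4):
    """<X_m> is larger in the checkerboard window than in the paired
    (UUDD) window on the 4-ring."""
    rng = make_rng(4)
    est_udud = estimate_excursion(logistic4, ring4, 0.15, n_samples=400, rng=rng, horizon=5000)
    est_uudd = estimate_excursion(logistic4, ring4, 0.30, n_samples=400, rng=rng, horizon=5000)
    assert est_udud.raw_score > est_uudd.raw_score


def test_excursion_monte_carlo_stability(logistic4, two_patch):
    est1 = estimate_excursion(logistic4, two_patch, 0.15, n_samples=400, rng=make_rng(5))
    est2 = estimate_excursion(logistic4, two_patch, 0.15, n_samples=800, rng=make_rng(6))
    assert abs(est1.raw_score - est2.raw_score) < 2 * (est1.se + est2.se)


@pytest.mark.parametrize(
    "scores, taus, expected",
    [
        ((10.0, 20.0), (math.e**10, math.e**20), (0.0, 1.0)),
        ((0.0, 5.0), (100.0, 100.0), (math.log(100.0), 0.0)),
    ],
)
def test_calibration_two_point_fit(scores, taus, expected):
    alpha, beta = calibrate(scores, taus)
    assert alpha == pytest.approx(expected[0], abs=1e-9)
    assert beta == pytest.approx(expected[1], abs=1e-9)
    # the calibrated line passes through both anchors
    for s, t in zip(scores, taus):
        assert apply_calibration(s, (alpha, beta)) == pytest.approx(t, rel=1e-9)


def test_calibration_rejects_equal_scores():
    with pytest.raises(ValueError):
        calibrate((5.0, 5.0), (10.0, 20.0))


def test_sweep_small_logistic_two_patch():
    """A coarse sweep resolves an interior persistence maximum whose
    deterministic attractor is the checkerboard orbit."""
    spec = LocalMapSpec("logistic", N=150, lam=4.0)
    top = build_topology("two_patch")
    grid = [0.0, 0.1, 0.15, 0.3, 0.5]
    result = sweep_migration(spec, top, grid, reps=100, rng=make_rng(7),
                             max_gen=10_000, n_boot=50)
    t = result.table
    assert list(t["D"]) == grid
    assert result.D_opt in (0.1, 0.15)
    row = t[t["D"] == 0.15].iloc[0]
    assert row["attractor_label"] == "UDUD"
    assert row["lyapunov"] < 0
    # interior maximum: both grid ends are worse
    tau = t["tau_best"].to_numpy()
    assert np.nanargmax(tau) not in (0, len(grid) - 1)
    lo, hi = result.D_opt_interval
    assert 0.0 <= lo <= result.D_opt <= hi <= 0.5
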