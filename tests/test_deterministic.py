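"""Coupled-map-lattice iteration, Lyapunov, classification, excursions."""

import numpy as np
import pytest

from metapersist.deterministic import (
    NoAttractorError,
    Trajectory,
    basin_map,
    classify_attractor,
    excursion_xm,
    excursion_xm_batch,
    find_attractor,
    find_period2_antiphase,
    iterate_cml,
    lyapunov_exponent,
    orbit_diagram,
)
from metapersist.local_maps import LocalMapSpec, map_mean
from metapersist.topology import build_topology


def test_decoupled_patches_match_single_map(logistic4, two_patch):
    """D=0 trajectories equal per-patch single-map iteration bit-exactly."""
    x0 = np.array([0.3, 0.8])
    traj = iterate_cml(logistic4, two_patch, 0.0, x0, steps=50)
    x = x0.copy()
    for t in range(50):
        assert np.array_equal(traj.states[t], x)
        x = map_mean(logistic4, x)


def test_uniform_state_stays_uniform(logistic4, ring4):
    """The synchronized manifold is invariant for every D."""
    for D in (0.0, 0.2, 0.7, 1.0):
        traj = iterate_cml(logistic4, ring4, D, np.full(4, 0.37), steps=100)
        spread = traj.states.max(axis=1) - traj.states.min(axis=1)
        assert spread.max() < 1e-12


def test_single_step_hand_computation(logistic4, two_patch):
    traj = iterate_cml(logistic4, two_patch, 0.5, np.array([0.5, 0.0]), steps=2)
    assert np.allclose(traj.states[1], [0.5, 0.5])


def test_nb_cml_disperses_both_species(nb_spec, two_patch):
    x0 = np.array([[1.0, 0.5], [0.2, 0.1]])
    traj = iterate_cml(nb_spec, two_patch, 1.0, x0, steps=2)
    # D=1 swaps patches entirely, for hosts and parasitoids alike
    reacted = map_mean(nb_spec, x0)
    assert np.allclose(traj.states[1], reacted[::-1])


def test_orbit_diagram_fixed_point_and_period2(single_patch):
    spec25 = LocalMapSpec("logistic", N=100, lam=2.5)
    d = orbit_diagram(spec25, single_patch, [0.0], transient=500, keep=32)
    assert np.allclose(d.recorded[0], 0.6, atol=1e-9)  # 1 - 1/2.5

    spec32 = LocalMapSpec("logistic", N=100, lam=3.2)
    d = orbit_diagram(spec32, single_patch, [0.0], transient=2000, keep=64)
    vals = np.unique(np.round(d.recorded[0].ravel(), 9))
    assert len(vals) == 2  # period-2 beyond the lam=3 doubling threshold


def test_orbit_diagram_two_patch_regimes(logistic4, two_patch):
    """Incoherent chaos at low D, a narrow 2-value band in the up-down
    window, broad-band synchronized chaos at high D."""
    d = orbit_diagram(logistic4, two_patch, [0.02, 0.15, 0.4], transient=3000, keep=200, seed=3)
    spread_low = np.ptp(d.recorded[0])
    band_mid = np.unique(np.round(d.recorded[1].ravel(), 6))
    spread_high = np.ptp(d.recorded[2])
    assert spread_low > 0.5
    assert len(band_mid) == 2
    assert spread_high > 0.5


def test_lyapunov_chaotic_anchor(single_patch, logistic4):
    """Lambda(lam=4) = ln 2 via tent-map conjugacy."""
    est = lyapunov_exponent(logistic4, single_patch, 0.0, np.array([0.123]), n_iter=20000)
    assert est.Lambda == pytest.approx(np.log(2), abs=0.01)


def test_lyapunov_fixed_point_anchor(single_patch):
    """At the stable fixed point Lambda = ln|2-lam| analytically."""
    spec = LocalMapSpec("logistic", N=100, lam=2.5)
    est = lyapunov_exponent(spec, single_patch, 0.0, np.array([0.6]))
    assert est.Lambda == pytest.approx(np.log(0.5), abs=1e-6)


def test_lyapunov_negative_in_updown_window(logistic4, two_patch):
    est = lyapunov_exponent(logistic4, two_patch, 0.15, np.array([0.46, 0.9]))
    assert est.Lambda < 0


def test_lyapunov_periodic_orbit_oracle(logistic4, two_patch):
    """On a detected period-k orbit, Lambda equals (1/k) ln|dominant
    eigenvalue of the k-step Jacobian product|."""
    from metapersist.local_maps import map_jacobian
    from metapersist.topology import dispersal_matrix

    # D chosen inside the stable window where the 2-step product has real,
    # separated eigenvalues (a complex pair makes the tangent average
    # converge only ~1/n and the 1e-6 comparison meaningless)
    D = 0.185
    orbit = find_attractor(logistic4, two_patch, D, x0=np.array([0.46, 0.9]))
    assert orbit.shape[0] == 2
    M = dispersal_matrix(two_patch, D)
    Jprod = np.eye(2)
    for state in orbit:
        Jprod = (M @ np.diag(map_jacobian(logistic4, state))) @ Jprod
    expected = np.log(np.max(np.abs(np.linalg.eigvals(Jprod)))) / 2
    est = lyapunov_exponent(logistic4, two_patch, D, orbit[0], n_iter=8000)
    assert est.Lambda == pytest.approx(expected, abs=1e-6)


def _as_traj(arr):
    return Trajectory(states=np.asarray(arr, dtype=float))


def test_classify_synthetic_patterns(two_patch, ring4):
    rng = np.random.default_rng(0)
    chaos = rng.uniform(0.1, 0.9, 200)
    sync = np.stack([chaos, chaos], axis=1)
    assert classify_attractor(_as_traj(sync), two_patch, max_period=32) == "SYNC_CHAOS"

    a, b = 0.3, 0.8
    udud = np.array([[a, b], [b, a]] * 100)
    assert classify_attractor(_as_traj(udud), two_patch, max_period=32) == "UDUD"

    uudd = np.array([[a, a, b, b], [b, b, a, a]] * 100)
    assert classify_attractor(_as_traj(uudd), ring4, max_period=32) == "UUDD"

    udud4 = np.array([[a, b, a, b], [b, a, b, a]] * 100)
    assert classify_attractor(_as_traj(udud4), ring4, max_period=32) == "UDUD"

    fp = np.tile([0.2, 0.5], (200, 1))
    assert classify_attractor(_as_traj(fp), two_patch, max_period=32) == "FIXED_POINT"

    incoherent = rng.uniform(0.1, 0.9, (200, 2))
    assert classify_attractor(_as_traj(incoherent), two_patch, max_period=32) == "INCOHERENT_CHAOS"


def test_classify_requires_long_enough_trajectory(two_patch):
    with pytest.raises(ValueError):
        classify_attractor(_as_traj(np.zeros((10, 2))), two_patch, max_period=32)


def test_period2_antiphase_sum_identity(logistic4):
    """lam [a(1-a) + b(1-b)] = a + b follows from summing the two
    defining equations."""
    for D in (0.145, 0.15, 0.16, 0.175, 0.19):
        out = find_period2_antiphase(logistic4, D)
        assert out is not None
        a, b = out
        assert logistic4.lam * (a * (1 - a) + b * (1 - b)) == pytest.approx(a + b, abs=1e-10)


def test_period2_antiphase_is_exact_cycle(logistic4, two_patch):
    a, b = find_period2_antiphase(logistic4, 0.15)
    traj = iterate_cml(logistic4, two_patch, 0.15, np.array([a, b]), steps=3)
    assert np.allclose(traj.states[1], [b, a], atol=1e-10)
    assert np.allclose(traj.states[2], [a, b], atol=1e-10)


def test_period2_antiphase_absent_when_unstable(logistic4):
    # at D=0 the antiphase pair exists algebraically but is unstable
    assert find_period2_antiphase(logistic4, 0.0) is None
    assert find_period2_antiphase(logistic4, 0.45) is None


def test_period2_inverse_consistency():
    """Orbit values near (0.48, 0.89) imply lam ~ 3.94 by the sum identity."""
    a, b = 0.48, 0.89
    lam = (a + b) / (a * (1 - a) + b * (1 - b))
    assert lam == pytest.approx(3.94, abs=0.01)
    # and the fixture lam=4 orbit at mid-window is close to those values
    out = find_period2_antiphase(LocalMapSpec("logistic", N=10, lam=4.0), 0.16)
    assert out == pytest.approx((0.47, 0.90), abs=0.03)


def test_excursion_from_attractor_is_cycle_minimum(logistic4, two_patch):
    orbit = find_attractor(logistic4, two_patch, 0.15)
    rec = excursion_xm(logistic4, two_patch, 0.15, orbit[0], reference=orbit)
    assert rec.converged and rec.t_converge == 0
    assert rec.X_m == pytest.approx(orbit.sum(axis=1).min())


def test_excursion_from_zero_state(logistic4, two_patch):
    orbit = find_attractor(logistic4, two_patch, 0.15)
    rec = excursion_xm(logistic4, two_patch, 0.15, np.zeros(2), horizon=200, reference=orbit)
    assert rec.X_m == 0.0
    assert not rec.converged  # all-zero is absorbing, never reaches the orbit


def test_excursion_errors_in_chaotic_regime(logistic4, two_patch):
    with pytest.raises(NoAttractorError):
        find_attractor(logistic4, two_patch, 0.02)


def test_basin_map_symmetric_and_zero_cell(logistic4, two_patch):
    grid, xm = basin_map(logistic4, two_patch, 0.15, grid_resolution=40, horizon=2000)
    assert np.array_equal(xm, xm.T)  # bit-exact patch-exchange symmetry
    assert xm[0, 0] == 0.0
    assert xm.min() >= 0.0


def test_basin_diagonal_matches_synchronized_transient(logistic4, two_patch):
    """On x1=x2 the trajectory stays synchronized, so X_m is twice the
    single-map running minimum over the same horizon."""
    orbit = find_attractor(logistic4, two_patch, 0.15)
    x = 0.4321
    horizon = 500
    xm, _, _ = excursion_xm_batch(
        logistic4, two_patch, 0.15, np.array([[x, x]]), horizon=horizon, reference=orbit
    )
    m, y = 2 * x, x
    for _ in range(horizon):
        y = float(map_mean(logistic4, y))
        m = min(m, 2 * y)
    assert xm[0] == pytest.approx(m, abs=1e-12)
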