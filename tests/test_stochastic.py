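"""Individual-based engine: binomial reaction, parallel migration, lifetimes."""

import numpy as np
import pytest

from metapersist.local_maps import LocalMapSpec
from metapersist.stochastic import (
    EnvNoiseSpec,
    MetapopState,
    RNGSpec,
    initial_counts,
    make_rng,
    migration_step,
    reaction_step,
    run_recorded,
    run_to_extinction,
    simulate_lifetimes,
    step_generation,
)
from metapersist.deterministic import _step_fn
from metapersist.topology import build_topology


def _state(counts):
    return MetapopState(t=0, counts=np.asarray(counts, dtype=np.int64))


def test_reaction_zero_is_absorbing(logistic4, rng):
    out = reaction_step(_state([0, 0]), logistic4, rng)
    assert np.array_equal(out.counts, [0, 0])


def test_reaction_full_patch_crashes(rng):
    """n = N gives survival probability 0, mirroring lam*1*(1-1) = 0."""
    spec = LocalMapSpec("logistic", N=50, lam=4.0)
    out = reaction_step(_state([50]), spec, rng)
    assert out.counts[0] == 0


def test_nb_reaction_without_parasitoids_is_deterministic(rng):
    spec = LocalMapSpec("nicholson_bailey", N=100, lam=2.0, a=1.0, c=1)
    out = reaction_step(_state([[30, 0]]), spec, rng)
    assert np.array_equal(out.counts, [[60, 0]])


def test_reaction_monte_carlo_mean_and_variance():
    """Binomial law: mean lam*n*(1-n/N) = 75, variance lam*n*p*(1-p) = 18.75."""
    spec = LocalMapSpec("logistic", N=100, lam=4.0)
    rng = make_rng(99)
    reps = 100_000
    counts = np.full((reps, 1), 25, dtype=np.int64)
    out = reaction_step(_state(counts), spec, rng).counts[:, 0]
    se_mean = np.sqrt(18.75 / reps)
    assert out.mean() == pytest.approx(75.0, abs=3 * se_mean)
    assert out.var() == pytest.approx(18.75, rel=0.05)


def test_migration_identity_at_zero_D(logistic4, two_patch, rng):
    s = _state([123, 45])
    out = migration_step(s, two_patch, 0.0, rng)
    assert np.array_equal(out.counts, s.counts)


def test_migration_full_swap_at_D_one(logistic4, two_patch, rng):
    out = migration_step(_state([123, 45]), two_patch, 1.0, rng)
    assert np.array_equal(out.counts, [45, 123])


def test_migration_conserves_total_exactly(rng):
    top = build_topology("lattice_2d", (5, 5), "periodic", [(2, 2)])
    counts = np.arange(top.L, dtype=np.int64) * 7
    out = migration_step(_state(counts), top, 0.43, rng)
    assert out.counts.sum() == counts.sum()
    assert np.all(out.counts >= 0)


def test_migration_ring_expected_arrivals():
    """4-ring, D=0.4, n=1000 on one patch: each neighbor receives D*n/2 = 200."""
    top = build_topology("chain_1d", 4)
    rng = make_rng(5)
    reps = 10_000
    counts = np.zeros((reps, 4), dtype=np.int64)
    counts[:, 0] = 1000
    out = migration_step(_state(counts), top, 0.4, rng).counts
    arrivals = out[:, 1].astype(float)
    se = arrivals.std(ddof=1) / np.sqrt(reps)
    assert arrivals.mean() == pytest.approx(200.0, abs=3 * se)
    assert np.array_equal(out.sum(axis=1), np.full(reps, 1000))


def test_determinism_contract(logistic4, ring4):
    """Identical RNGSpec + config give bit-identical runs."""
    init = np.array([100, 200, 50, 250], dtype=np.int64)
    out = []
    for _ in range(2):
        rng = RNGSpec(seed=7, stream=3).generator()
        lifetime, censored, series = run_to_extinction(
            logistic4, ring4, 0.2, init, rng, max_gen=300, record_every=1
        )
        out.append((lifetime, censored, series))
    assert out[0][0] == out[1][0]
    assert np.array_equal(out[0][2], out[1][2])


def test_env_amplitude_zero_is_bitexact_noop(logistic4, two_patch):
    init = np.array([150, 80], dtype=np.int64)
    r1 = run_recorded(logistic4, two_patch, 0.3, init, make_rng(3), n_gen=100)
    r2 = run_recorded(
        logistic4, two_patch, 0.3, init, make_rng(3), n_gen=100,
        env=EnvNoiseSpec(amplitude=0.0),
    )
    assert np.array_equal(r1, r2)


def test_env_noise_perturbs_dynamics(logistic4, two_patch):
    init = np.array([150, 80], dtype=np.int64)
    r1 = run_recorded(logistic4, two_patch, 0.3, init, make_rng(3), n_gen=50)
    r2 = run_recorded(
        logistic4, two_patch, 0.3, init, make_rng(3), n_gen=50,
        env=EnvNoiseSpec(amplitude=0.1),
    )
    assert not np.array_equal(r1[: min(len(r1), len(r2))], r2[: min(len(r1), len(r2))])


def test_all_zero_state_stays_zero(logistic4, ring4, rng):
    s = _state([0, 0, 0, 0])
    out = step_generation(s, logistic4, ring4, 0.5, rng)
    assert out.t == 1
    assert np.array_equal(out.counts, [0, 0, 0, 0])


def test_large_N_one_generation_matches_deterministic(two_patch):
    """Law of large numbers: the density drift matches the coupled map
    within 5/sqrt(N) at N = 10^6."""
    N = 10**6
    spec = LocalMapSpec("logistic", N=N, lam=4.0)
    x0 = np.array([0.3, 0.6])
    det = _step_fn(spec, two_patch, 0.25)(x0)
    rng = make_rng(17)
    state = _state(np.rint(x0 * N).astype(np.int64))
    out = step_generation(state, spec, two_patch, 0.25, rng)
    assert np.max(np.abs(out.counts / N - det)) < 5 / np.sqrt(N)


def test_run_to_extinction_immediate_for_empty_init(logistic4, two_patch, rng):
    lifetime, censored, _ = run_to_extinction(
        logistic4, two_patch, 0.1, np.zeros(2, dtype=np.int64), rng, max_gen=10
    )
    assert lifetime == 0 and not censored


def test_nb_either_species_rule(rng):
    spec = LocalMapSpec("nicholson_bailey", N=100, lam=2.0, a=1.0, c=1)
    top = build_topology("two_patch")
    init = np.array([[50, 0], [60, 0]], dtype=np.int64)  # parasitoid-free
    lifetime, censored, _ = run_to_extinction(spec, top, 0.1, init, rng, max_gen=10)
    assert lifetime == 0 and not censored


def test_single_patch_lifetime_matches_markov_chain_oracle():
    """Direct simulation agrees with the exact absorbing-chain solution
    (N=4, lam=4, start n=2) within 3 standard errors."""
    from metapersist.persistence import exact_single_patch_lifetime

    spec = LocalMapSpec("logistic", N=4, lam=4.0)
    top = build_topology("chain_1d", 1)
    exact = exact_single_patch_lifetime(spec, 2)
    rng = make_rng(23)
    init = np.full((10_000, 1), 2, dtype=np.int64)
    lifetimes, censored = simulate_lifetimes(spec, top, 0.0, init, rng, max_gen=10_000)
    assert not censored.any()
    se = lifetimes.std(ddof=1) / np.sqrt(lifetimes.size)
    assert lifetimes.mean() == pytest.approx(exact, abs=3 * se)


def test_initial_counts_rules(logistic4, ring4, rng):
    u = initial_counts(logistic4, ring4, "uniform_random", rng, reps=5)
    assert u.shape == (5, 4) and u.min() >= 1 and u.max() <= logistic4.N
    f = initial_counts(logistic4, ring4, "fixed", rng, reps=3, fixed=[1, 2, 3, 4])
    assert np.array_equal(f, np.tile([1, 2, 3, 4], (3, 1)))
    with pytest.raises(ValueError):
        initial_counts(logistic4, ring4, "bogus", rng)
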