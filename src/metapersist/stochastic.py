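"""Individual-based stochastic metapopulation engine.

Each generation is a binomial *reaction* step (demographic stochasticity)
followed by a per-individual *migration* step with parallel update:

reaction (per patch, independently)
    logistic:  n' = min(N, Binomial(lam * n, 1 - n/N))
    ricker:    n' = min(cap, Binomial(exp(r) * n, exp(-r n / N)))
    host-parasitoid: uninfected k = Binomial(H, exp(-a P / N));
                     H' = lam * k;  P' = c * (H - k)
migration
    every individual emigrates with probability D and picks a destination
    uniformly among the patch's neighbors; all moves are applied only after
    the whole cycle (parallel update), so the global count is conserved
    exactly and no residual drift along the update order can appear.

The integer-first-argument rule (lam integer; exp(r) integer) makes the
binomial argument exact; the all-zero state is absorbing. The mean of one
reaction step is the deterministic local map, so the engine converges to
the coupled map lattice as N grows, with relative fluctuations ~ 1/sqrt(N).

Optional environmental stochasticity multiplies the per-generation
fecundity by a random factor (per patch or global); amplitude zero
reproduces the purely demographic model bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .local_maps import ConfigurationError, LocalMapSpec, integer_fecundity
from .topology import Topology

__all__ = [
    "MetapopState",
    "RNGSpec",
    "EnvNoiseSpec",
    "make_rng",
    "reaction_step",
    "migration_step",
    "step_generation",
    "run_to_extinction",
    "run_recorded",
    "simulate_lifetimes",
    "initial_counts",
]

HOST_CAP = 10**9  # overflow guard for parasitoid-free host growth


@dataclass(frozen=True)
class RNGSpec:
    """Seed + stream id; identical (seed, stream, config) gives bit-identical runs."""

    seed: int
    stream: int = 0

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), int(self.stream))))


def make_rng(seed: int, stream: int = 0) -> np.random.Generator:
    return RNGSpec(seed, stream).generator()


@dataclass(frozen=True)
class EnvNoiseSpec:
    """Multiplicative environmental noise on the per-generation fecundity.

    ``amplitude`` A draws a factor uniform in [1-A, 1+A] (or lognormal with
    sigma = A) each generation, independently per patch unless
    ``scope="global"``. Amplitude 0 draws nothing, so the purely
    demographic path is reproduced bit-exactly with the same seed.
    """

    amplitude: float = 0.0
    scope: str = "per_patch"
    law: str = "uniform_multiplicative"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("environmental noise amplitude must be >= 0")
        if self.scope not in ("per_patch", "global"):
            raise ConfigurationError("env noise scope must be per_patch | global")
        if self.law not in ("uniform_multiplicative", "lognormal_multiplicative"):
            raise ConfigurationError("env noise law must be uniform_multiplicative | lognormal_multiplicative")

    def draw(self, rng: np.random.Generator, L: int, reps: Optional[int] = None):
        """Fecundity factors: shape (L,), or (reps, L) for batched replicates."""
        if self.amplitude == 0.0:
            return None
        if self.scope == "per_patch":
            size = (L,) if reps is None else (reps, L)
        else:
            size = (1,) if reps is None else (reps, 1)
        if self.law == "uniform_multiplicative":
            f = rng.uniform(1.0 - self.amplitude, 1.0 + self.amplitude, size=size)
        else:
            f = np.exp(rng.normal(0.0, self.amplitude, size=size))
        if self.scope == "global":
            f = np.broadcast_to(f, (L,) if reps is None else (reps, L))
        return f


@dataclass
class MetapopState:
    """Integer per-patch abundances at generation ``t``.

    ``counts`` has shape (L,) for one-species families and (L, 2) for the
    host-parasitoid family (column 0 hosts, column 1 parasitoids). Defect
    sites are absent from the topology, so no entry exists for them.
    """

    t: int
    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())

    def extinct(self, spec: LocalMapSpec) -> bool:
        if spec.n_species == 1:
            return bool(self.counts.sum() == 0)
        # either species globally extinct ends the system (a parasitoid-free
        # host population grows without bound; a host-free parasitoid dies)
        return bool(self.counts[..., 0].sum() == 0 or self.counts[..., 1].sum() == 0)


def _reaction_counts(
    counts: np.ndarray,
    spec: LocalMapSpec,
    rng: np.random.Generator,
    fecundity_factor: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binomial reaction applied to an integer array of shape (..., L[, 2])."""
    fec = integer_fecundity(spec)
    if spec.family == "logistic":
        n = counts
        if fecundity_factor is None:
            first = fec * n
        else:
            first = np.rint(fecundity_factor * spec.lam * n).astype(np.int64)
        # counts may transiently exceed N after immigration; the survival
        # probability is then clipped to 0 and the overfull patch crashes,
        # mirroring lam*x*(1-x) <= 0 for x >= 1
        p = np.clip(1.0 - n / spec.N, 0.0, 1.0)
        out = rng.binomial(first, p)
        return np.minimum(out, spec.N).astype(np.int64)
    if spec.family == "ricker":
        n = counts
        if fecundity_factor is None:
            first = fec * n
        else:
            first = np.rint(fecundity_factor * np.exp(spec.r) * n).astype(np.int64)
        p = np.exp(-spec.r * n / spec.N)
        out = rng.binomial(first, p)
        cap = 10 * spec.N  # overflow guard only; rarely binding
        return np.minimum(out, cap).astype(np.int64)
    # nicholson_bailey
    H = counts[..., 0]
    P = counts[..., 1]
    esc = np.exp(-spec.a * P / spec.N)
    k = rng.binomial(H, esc)
    if fecundity_factor is None:
        H2 = fec * k
    else:
        H2 = np.rint(fecundity_factor * spec.lam * k).astype(np.int64)
    P2 = int(spec.c) * (H - k)
    H2 = np.minimum(H2, HOST_CAP)
    return np.stack([H2, P2], axis=-1).astype(np.int64)


def _migration_counts(
    counts: np.ndarray,
    topology: Topology,
    D: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parallel-update migration on an integer array of shape (..., L).

    Emigrant counts are Binomial(n_j, D) per patch and are split uniformly
    among the neighbors by a multinomial draw — distributionally identical
    to per-individual Bernoulli choices. Departures and arrivals are
    applied simultaneously after the full cycle.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("migration rate D must lie in [0, 1]")
    out = counts.astype(np.int64).copy()
    if D == 0.0:
        return out
    for j, nbrs in enumerate(topology.adjacency):
        k = len(nbrs)
        if k == 0:
            continue
        e = rng.binomial(counts[..., j], D)
        out[..., j] -= e
        if k == 1:
            out[..., nbrs[0]] += e
        else:
            splits = rng.multinomial(e, np.full(k, 1.0 / k))
            for s, nb in enumerate(nbrs):
                out[..., nb] += splits[..., s]
    return out


def _migrate(counts, spec, topology, D, rng):
    if spec.n_species == 1:
        return _migration_counts(counts, topology, D, rng)
    h = _migration_counts(counts[..., 0], topology, D, rng)
    p = _migration_counts(counts[..., 1], topology, D, rng)
    return np.stack([h, p], axis=-1)


def reaction_step(state: MetapopState, spec: LocalMapSpec, rng: np.random.Generator,
                  env_factor: Optional[np.ndarray] = None) -> MetapopState:
    """One binomial reaction step (generation index unchanged)."""
    return MetapopState(t=state.t, counts=_reaction_counts(state.counts, spec, rng, env_factor))


def migration_step(state: MetapopState, topology: Topology, D: float,
                   rng: np.random.Generator, spec: Optional[LocalMapSpec] = None) -> MetapopState:
    """One parallel-update migration step (generation index unchanged)."""
    counts = state.counts
    if counts.ndim == 2 and counts.shape[-1] == 2:
        h = _migration_counts(counts[..., 0], topology, D, rng)
        p = _migration_counts(counts[..., 1], topology, D, rng)
        new = np.stack([h, p], axis=-1)
    else:
        new = _migration_counts(counts, topology, D, rng)
    return MetapopState(t=state.t, counts=new)


def step_generation(
    state: MetapopState,
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    rng: np.random.Generator,
    env: Optional[EnvNoiseSpec] = None,
) -> MetapopState:
    """Reaction followed by migration; advances the generation index."""
    factor = env.draw(rng, topology.L) if env is not None else None
    counts = _reaction_counts(state.counts, spec, rng, factor)
    counts = _migrate(counts, spec, topology, D, rng)
    return MetapopState(t=state.t + 1, counts=counts)


def initial_counts(
    spec: LocalMapSpec,
    topology: Topology,
    rule: str,
    rng: np.random.Generator,
    reps: int = 1,
    fixed=None,
) -> np.ndarray:
    """Initial integer counts of shape (reps, L[, 2]).

    Rules: ``uniform_random`` draws each patch count uniformly in [1, N]
    (both species for the host-parasitoid family); ``fixed`` tiles the
    given counts; ``near_attractor`` rounds N times the deterministic
    attractor state (falling back to uniform_random in chaotic regimes).
    """
    L = topology.L
    shape = (reps, L) if spec.n_species == 1 else (reps, L, 2)
    if rule == "uniform_random":
        return rng.integers(1, spec.N + 1, size=shape, dtype=np.int64)
    if rule == "fixed":
        if fixed is None:
            raise ValueError("fixed init rule needs explicit counts")
        base = np.asarray(fixed, dtype=np.int64)
        return np.broadcast_to(base, shape).copy()
    if rule == "near_attractor":
        from .deterministic import NoAttractorError, find_attractor

        try:
            # the caller supplies D through `fixed` for this rule
            D = float(fixed) if fixed is not None else 0.0
            ref = find_attractor(spec, topology, D)
            base = np.rint(ref[0] * spec.N).astype(np.int64)
            base = np.maximum(base, 0)
            return np.broadcast_to(base, shape).copy()
        except NoAttractorError:
            return rng.integers(1, spec.N + 1, size=shape, dtype=np.int64)
    raise ValueError(f"unknown init rule {rule!r}")


def _extinct_mask(counts: np.ndarray, spec: LocalMapSpec) -> np.ndarray:
    if spec.n_species == 1:
        return counts.sum(axis=-1) == 0
    return (counts[..., 0].sum(axis=-1) == 0) | (counts[..., 1].sum(axis=-1) == 0)


def run_to_extinction(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    init,
    rng: np.random.Generator,
    max_gen: int,
    env: Optional[EnvNoiseSpec] = None,
    record_every: int = 0,
):
    """Simulate until global extinction or ``max_gen``.

    ``init`` is a MetapopState or an integer count array. Returns
    ``(lifetime, censored, series)`` where lifetime is the first generation
    with global extinction (one-species: total count 0; host-parasitoid:
    either species globally at 0), censored flags hitting ``max_gen``
    alive, and series is the thinned per-patch count history (or None if
    ``record_every`` is 0).
    """
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    state = init if isinstance(init, MetapopState) else MetapopState(t=0, counts=np.asarray(init, dtype=np.int64))
    series = [state.counts.copy()] if record_every else None
    if state.extinct(spec):
        return 0, False, (np.asarray(series) if series is not None else None)
    for _ in range(max_gen):
        state = step_generation(state, spec, topology, D, rng, env)
        if record_every and state.t % record_every == 0:
            series.append(state.counts.copy())
        if state.extinct(spec):
            return state.t, False, (np.asarray(series) if series is not None else None)
    return state.t, True, (np.asarray(series) if series is not None else None)


def run_recorded(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    init,
    rng: np.random.Generator,
    n_gen: int,
    env: Optional[EnvNoiseSpec] = None,
) -> np.ndarray:
    """Per-generation count history of shape (T+1, L[, 2]); stops at extinction."""
    state = init if isinstance(init, MetapopState) else MetapopState(t=0, counts=np.asarray(init, dtype=np.int64))
    out = [state.counts.copy()]
    for _ in range(n_gen):
        if state.extinct(spec):
            break
        state = step_generation(state, spec, topology, D, rng, env)
        out.append(state.counts.copy())
    return np.asarray(out)


def simulate_lifetimes(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    init: np.ndarray,
    rng: np.random.Generator,
    max_gen: int,
    env: Optional[EnvNoiseSpec] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lifetimes for a batch of replicate initial conditions.

    ``init`` has shape (reps, L[, 2]). All replicates advance in lockstep
    (one vectorized reaction + migration per generation); extinct
    replicates drop out. Returns ``(lifetimes, censored)``; censored
    replicates report ``max_gen`` as a lower bound on their lifetime.

    The random-number consumption differs from per-replicate
    :func:`run_to_extinction` loops, so the two paths are each reproducible
    under their own seed discipline but not against each other.
    """
    counts = np.asarray(init, dtype=np.int64).copy()
    reps = counts.shape[0]
    lifetimes = np.full(reps, max_gen, dtype=np.int64)
    censored = np.ones(reps, dtype=bool)
    dead0 = _extinct_mask(counts, spec)
    lifetimes[dead0] = 0
    censored[dead0] = False
    active = np.where(~dead0)[0]
    t = 0
    while t < max_gen and active.size:
        t += 1
        sub = counts[active]
        factor = env.draw(rng, topology.L, reps=active.size) if env is not None else None
        sub = _reaction_counts(sub, spec, rng, factor)
        sub = _migrate(sub, spec, topology, D, rng)
        counts[active] = sub
        dead = _extinct_mask(sub, spec)
        if dead.any():
            idx = active[dead]
            lifetimes[idx] = t
            censored[idx] = False
            active = active[~dead]
    return lifetimes, censored
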