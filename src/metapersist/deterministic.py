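"""Deterministic coupled-map-lattice analysis.

One generation is reaction followed by dispersal:
``x(t+1) = M(D) @ f(x(t))``, with the local map ``f`` applied patchwise and
the column-stochastic dispersal matrix ``M(D)`` mixing neighbors. For the
host-parasitoid family the same ``M`` is applied separately to the host and
the parasitoid fields.

The module produces orbit (bifurcation) diagrams over the migration rate,
largest Lyapunov exponents via tangent-vector propagation, attractor
classification (synchronized / incoherent chaos, checkerboard "up-down"
and paired "up-up-down-down" cycles), and the excursion statistic ``X_m``:
the minimum total density along the transient from an arbitrary initial
state back to the attractor, which controls the extinction risk of the
finite-population system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .local_maps import LocalMapSpec, map_jacobian, map_mean
from .topology import Topology, dispersal_matrix, two_coloring

__all__ = [
    "Trajectory",
    "OrbitDiagram",
    "LyapunovEstimate",
    "ExcursionRecord",
    "NoAttractorError",
    "iterate_cml",
    "orbit_diagram",
    "lyapunov_exponent",
    "classify_attractor",
    "find_period2_antiphase",
    "find_attractor",
    "excursion_xm",
    "excursion_xm_batch",
    "basin_map",
]

DIVERGENCE_GUARD = 1e9


class NoAttractorError(RuntimeError):
    """No periodic attractor was detected at this migration rate.

    Raised by excursion-based operations, which are defined only where the
    deterministic dynamics settles onto a periodic orbit; chaotic regimes
    need the stochastic machinery instead.
    """


@dataclass
class Trajectory:
    """Time-ordered density states. ``states[t]`` has shape (L,) or (L, 2)."""

    states: np.ndarray
    transient_discarded: int = 0
    diverged: bool = False


@dataclass
class OrbitDiagram:
    D_grid: np.ndarray
    recorded: list  # per D: array (keep, L) or (keep, L, 2)
    observable: str = "per_patch"


@dataclass
class LyapunovEstimate:
    Lambda: float
    n_iter: int
    transient: int
    collapsed: bool = False  # exact-zero density met; Lambda is -inf


@dataclass
class ExcursionRecord:
    x0: np.ndarray
    X_m: float
    t_converge: int
    converged: bool


def _neighbor_avg_matrix(topology: Topology) -> np.ndarray:
    """W with W[i, j] = 1/n_j on edges: the inflow part of M = (1-D)I + DW."""
    L = topology.L
    W = np.zeros((L, L))
    for j, nbrs in enumerate(topology.adjacency):
        if nbrs:
            for i in nbrs:
                W[i, j] = 1.0 / len(nbrs)
        else:
            W[j, j] = 1.0  # isolated patch keeps its residents
    return W


def _step_fn(spec: LocalMapSpec, topology: Topology, D: float) -> Callable[[np.ndarray], np.ndarray]:
    """Return the one-generation map acting on batched states (..., L[, 2]).

    Dispersal is evaluated as ``y + D * (W y - y)`` rather than a single
    matrix product: mathematically identical to M(D) y, but exact on the
    synchronized manifold (equal densities give W y = y bit-exactly on
    regular graphs), so uniform states remain uniform for every D.
    """
    WT = _neighbor_avg_matrix(topology).T.copy()

    def disperse(y):
        return y + D * (y @ WT - y)

    if spec.n_species == 1:
        def step(x):
            return disperse(map_mean(spec, x))
    else:
        def step(x):
            y = map_mean(spec, x)
            # the same operator disperses host and parasitoid fields
            return np.stack([disperse(y[..., 0]), disperse(y[..., 1])], axis=-1)
    return step


def iterate_cml(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    x0,
    steps: int,
    transient: int = 0,
) -> Trajectory:
    """Iterate the coupled map lattice, recording post-transient states.

    Records ``steps`` states starting with the state after ``transient``
    generations (so ``transient=0`` records ``x0`` itself first). Diverging
    trajectories (possible for the unstable host-parasitoid map) are halted
    and flagged.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x0, dtype=float)
    expected = (topology.L,) if spec.n_species == 1 else (topology.L, 2)
    if x.shape != expected:
        raise ValueError(f"x0 has shape {x.shape}, expected {expected}")
    step = _step_fn(spec, topology, D)
    for _ in range(transient):
        x = step(x)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > DIVERGENCE_GUARD):
            return Trajectory(states=x[None, ...], transient_discarded=transient, diverged=True)
    out = np.empty((steps,) + x.shape)
    out[0] = x
    for t in range(1, steps):
        x = step(x)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > DIVERGENCE_GUARD):
            return Trajectory(states=out[:t], transient_discarded=transient, diverged=True)
        out[t] = x
    return Trajectory(states=out, transient_discarded=transient)


def orbit_diagram(
    spec: LocalMapSpec,
    topology: Topology,
    D_grid: Sequence[float],
    transient: int = 2000,
    keep: int = 128,
    x0_rule: str = "fixed",
    x0=None,
    seed: int = 0,
) -> OrbitDiagram:
    """Post-transient attractor samples for each migration rate.

    ``x0_rule``: "fixed" restarts every D from the same state, "random_per_D"
    draws a fresh (seeded) random state per grid point, "continued" carries
    the final state from one D to the next (hysteresis-friendly).
    """
    if x0_rule not in ("fixed", "random_per_D", "continued"):
        raise ValueError("x0_rule must be fixed | random_per_D | continued")
    rng = np.random.default_rng(seed)
    D_grid = np.asarray(D_grid, dtype=float)

    def default_x0():
        shape = (topology.L,) if spec.n_species == 1 else (topology.L, 2)
        u = rng.uniform(0.05, 0.95, size=shape)
        if spec.family == "ricker":
            u = u * 2.0
        if spec.family == "nicholson_bailey":
            from .local_maps import nb_fixed_point

            h, p = nb_fixed_point(spec)
            u = u * np.array([2 * h, 2 * p])
        return u

    start = np.asarray(x0, dtype=float) if x0 is not None else default_x0()
    recorded = []
    x = start
    for D in D_grid:
        if x0_rule == "fixed":
            x = start
        elif x0_rule == "random_per_D":
            x = default_x0()
        traj = iterate_cml(spec, topology, D, x, steps=keep, transient=transient)
        recorded.append(traj.states)
        if x0_rule == "continued" and not traj.diverged:
            x = traj.states[-1]
    return OrbitDiagram(D_grid=D_grid, recorded=recorded)


def _tangent_step(spec, M, x, v):
    """Propagate tangent vector v through one generation at state x."""
    J = map_jacobian(spec, x)
    if spec.n_species == 1:
        return M @ (J * v)
    w = np.einsum("lij,lj->li", J, v)
    return np.stack([M @ w[:, 0], M @ w[:, 1]], axis=-1)


def lyapunov_exponent(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    x0,
    n_iter: int = 4000,
    transient: int = 1000,
    tol: float = 1e-3,
    max_iter: int = 64000,
) -> LyapunovEstimate:
    """Largest Lyapunov exponent (natural log per generation).

    Tangent-vector propagation through the chain Jacobian
    ``M(D) @ J_f(x(t))`` with per-step renormalization. The iteration count
    is extended (doubled, up to ``max_iter``) until the estimate from the
    full run and from its second half agree within ``tol``; this converges
    quickly on periodic orbits, which is where the tolerance matters.
    A collapsing tangent (exact zero derivative chain) reports -inf.
    """
    M = dispersal_matrix(topology, D)
    x = np.asarray(x0, dtype=float)
    step = _step_fn(spec, topology, D)
    for _ in range(transient):
        x = step(x)
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(x.shape)
    v /= np.linalg.norm(v)
    # align the tangent with the dominant direction before accumulating, so
    # that on a period-k orbit every k-block of log increments is exact
    for _ in range(256):
        v = _tangent_step(spec, M, x, v)
        nv = np.linalg.norm(v)
        if nv == 0.0:
            return LyapunovEstimate(Lambda=-np.inf, n_iter=0, transient=transient, collapsed=True)
        v /= nv
        x = step(x)

    logs: list[float] = []
    total = 0
    n_target = n_iter
    while True:
        while total < n_target:
            v = _tangent_step(spec, M, x, v)
            nv = np.linalg.norm(v)
            if nv == 0.0:
                return LyapunovEstimate(Lambda=-np.inf, n_iter=total, transient=transient, collapsed=True)
            logs.append(np.log(nv))
            v /= nv
            x = step(x)
            if not np.all(np.isfinite(x)) or np.any(np.abs(x) > DIVERGENCE_GUARD):
                break
            total += 1
        arr = np.asarray(logs)
        full = arr.mean()
        half = arr[arr.size // 2 :].mean()
        if abs(full - half) < tol or n_target >= max_iter or total < n_target:
            return LyapunovEstimate(Lambda=float(full), n_iter=total, transient=transient)
        n_target *= 2


def _detect_period(X: np.ndarray, tol: float, max_period: int) -> Optional[int]:
    """Smallest period p <= max_period with x(t) = x(t-p) over the tail."""
    T = X.shape[0]
    flat = X.reshape(T, -1)
    scale = max(1.0, float(np.max(np.abs(flat))))
    atol = tol * scale
    window = min(T - max_period, 4 * max_period)
    for p in range(1, max_period + 1):
        tail = flat[T - window :]
        lagged = flat[T - window - p : T - p]
        if np.max(np.abs(tail - lagged)) <= atol:
            return p
    return None


def classify_attractor(
    trajectory: Trajectory,
    topology: Topology,
    tol: float = 1e-3,
    max_period: int = 64,
) -> str:
    """Label the post-transient trajectory.

    Returns one of ``SYNC_CHAOS``, ``INCOHERENT_CHAOS``, ``UDUD``, ``UUDD``,
    ``PERIODIC_OTHER``, ``FIXED_POINT``.

    UDUD ("checkerboard"): patches split into the two bipartite color
    classes, each class internally synchronized, the classes in antiphase
    (half-period time shift) — not necessarily period 2. UUDD: two
    antiphase classes where every patch has at least one *same*-class
    neighbor (synchronized adjacent pairs, pairs in antiphase). A patch
    whose two phase values coincide within tolerance merges the classes and
    the trajectory classifies as synchronized at that resolution.

    For the host-parasitoid family the classification uses host densities.
    """
    X = trajectory.states
    if X.ndim == 3:
        X = X[..., 0]
    T, L = X.shape
    if T < 2 * max_period:
        raise ValueError(f"trajectory length {T} too short; need >= {2 * max_period}")
    scale = max(1.0, float(np.max(np.abs(X))))
    atol = tol * scale

    spread = np.max(X, axis=1) - np.min(X, axis=1)
    synchronized = bool(np.all(spread <= atol))
    period = _detect_period(X, tol, max_period)

    if period is None:
        return "SYNC_CHAOS" if synchronized else "INCOHERENT_CHAOS"
    if period == 1:
        return "FIXED_POINT"
    if synchronized or L == 1:
        return "PERIODIC_OTHER"

    tail = X[-4 * period :]
    # group patches by in-phase equality of their periodic time series
    groups = -np.ones(L, dtype=int)
    n_groups = 0
    for i in range(L):
        if groups[i] >= 0:
            continue
        groups[i] = n_groups
        for j in range(i + 1, L):
            if groups[j] < 0 and np.max(np.abs(tail[:, i] - tail[:, j])) <= atol:
                groups[j] = n_groups
        n_groups += 1
    if n_groups != 2 or period % 2 != 0:
        return "PERIODIC_OTHER"
    a_idx = np.where(groups == 0)[0]
    b_idx = np.where(groups == 1)[0]
    sa = tail[:, a_idx[0]]
    sb = tail[:, b_idx[0]]
    half = period // 2
    antiphase = np.max(np.abs(sa[half:] - sb[:-half])) <= atol
    if not antiphase:
        return "PERIODIC_OTHER"
    # cross-group edges vs within-group edges decide UDUD vs UUDD
    all_cross = True
    every_patch_has_same = True
    for i, nbrs in enumerate(topology.adjacency):
        same = [j for j in nbrs if groups[j] == groups[i]]
        if same:
            all_cross = False
        else:
            every_patch_has_same = False
    if all_cross:
        colors = two_coloring(topology)
        if colors is not None:
            return "UDUD"
        return "PERIODIC_OTHER"
    if every_patch_has_same:
        return "UUDD"
    return "PERIODIC_OTHER"


def find_period2_antiphase(spec: LocalMapSpec, D: float) -> Optional[tuple[float, float]]:
    """Antiphase period-2 orbit (x_low, x_high) of the two-patch logistic CML.

    Solves ``b = (1-D) g(a) + D g(b)``, ``a = (1-D) g(b) + D g(a)`` with
    ``g(x) = lam x (1-x)``. Writing u = a+b, v = b-a the system reduces to
    ``u = 1 + 1/(lam (1-2D))`` and ``v^2 = 2u(lam-1)/lam - u^2``. Returns
    None when no real orbit exists in (0,1) or when the orbit is unstable
    (spectral radius of the 2-step Jacobian product >= 1, i.e. nonnegative
    Lyapunov exponent).
    """
    if spec.family != "logistic":
        raise ValueError("find_period2_antiphase applies to the logistic family")
    lam = spec.lam
    if D == 0.5:
        return None
    u = 1.0 + 1.0 / (lam * (1.0 - 2.0 * D))
    v2 = 2.0 * u * (lam - 1.0) / lam - u * u
    if v2 <= 0:
        return None
    v = float(np.sqrt(v2))
    a = (u - v) / 2.0
    b = (u + v) / 2.0
    if not (0.0 < a < b < 1.0):
        return None
    # stability of the 2-cycle: product of one-step Jacobians M @ diag(g')
    from .topology import build_topology

    top2 = build_topology("two_patch")
    M = dispersal_matrix(top2, D)
    J1 = M @ np.diag(lam * (1.0 - 2.0 * np.array([a, b])))
    J2 = M @ np.diag(lam * (1.0 - 2.0 * np.array([b, a])))
    radius = np.max(np.abs(np.linalg.eigvals(J2 @ J1)))
    if radius >= 1.0:
        return None
    return (a, b)


def find_attractor(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    x0=None,
    transient: int = 5000,
    max_period: int = 64,
    tol: float = 1e-9,
    seed: int = 0,
    n_starts: int = 8,
) -> np.ndarray:
    """Reference periodic-attractor states at migration rate D.

    Long pre-iteration followed by period detection, repeated from
    ``n_starts`` seeded random initial states (or just the supplied ``x0``);
    the union of all detected orbit states is returned as an array
    (n_states, L[, 2]). Multiple starts matter because coexisting attractors
    (mirror-image up-down fixed points, UDUD/UUDD orbits with interleaved
    basins) are the rule in the interesting migration windows. Raises
    :class:`NoAttractorError` if no start settles onto a cycle of period
    <= max_period.
    """
    rng = np.random.default_rng(seed)
    shape = (topology.L,) if spec.n_species == 1 else (topology.L, 2)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    else:
        for _ in range(n_starts):
            u = rng.uniform(0.05, 0.95, size=shape)
            if spec.family == "ricker":
                u = u * 2.0
            starts.append(u)
    collected: list[np.ndarray] = []
    for s in starts:
        traj = iterate_cml(spec, topology, D, s, steps=8 * max_period, transient=transient)
        if traj.diverged:
            continue
        p = _detect_period(traj.states, tol=1e-6, max_period=max_period)
        if p is None:
            continue
        for state in traj.states[-p:]:
            if not any(np.max(np.abs(state - c)) < 1e-6 for c in collected):
                collected.append(state.copy())
    if not collected:
        raise NoAttractorError(
            f"no periodic attractor (period <= {max_period}) detected at D={D}; "
            "the regime is chaotic — use the stochastic machinery instead"
        )
    return np.asarray(collected)


def excursion_xm_batch(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    X0: np.ndarray,
    horizon: int = 10_000,
    attractor_tol: float = 1e-6,
    reference: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized excursion statistic for a batch of initial states.

    For each row of ``X0`` (shape (n, L) — one-species families only),
    iterates until the state is within ``attractor_tol`` (max-norm over
    patches, minimized over the orbit's points) of the reference orbit, or
    the horizon is hit. Returns ``(X_m, t_converge, converged)`` where
    ``X_m`` is the minimum over the transient of the total density
    (the initial state included).
    """
    if spec.n_species != 1:
        raise ValueError("excursion statistics are defined for one-species families")
    if reference is None:
        reference = find_attractor(spec, topology, D)
    ref = np.asarray(reference, dtype=float)  # (p, L)
    X = np.array(X0, dtype=float)
    n = X.shape[0]
    step = _step_fn(spec, topology, D)
    xm = X.sum(axis=1)
    tconv = np.full(n, horizon, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)

    def near(Y):
        # (m, p, L) -> max over patches, min over orbit points
        d = np.abs(Y[:, None, :] - ref[None, :, :]).max(axis=2).min(axis=1)
        return d <= attractor_tol

    hit0 = near(X)
    converged[hit0] = True
    tconv[hit0] = 0
    active = active[~hit0]
    for t in range(1, horizon + 1):
        if active.size == 0:
            break
        Y = step(X[active])
        X[active] = Y
        xm[active] = np.minimum(xm[active], Y.sum(axis=1))
        hit = near(Y)
        idx = active[hit]
        converged[idx] = True
        tconv[idx] = t
        active = active[~hit]
    return xm, tconv, converged


def excursion_xm(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    x0,
    horizon: int = 10_000,
    attractor_tol: float = 1e-6,
    reference: Optional[np.ndarray] = None,
) -> ExcursionRecord:
    """Excursion record for a single initial state (see the batch variant)."""
    x0 = np.asarray(x0, dtype=float)
    xm, tconv, conv = excursion_xm_batch(
        spec, topology, D, x0[None, :], horizon=horizon,
        attractor_tol=attractor_tol, reference=reference,
    )
    return ExcursionRecord(x0=x0, X_m=float(xm[0]), t_converge=int(tconv[0]), converged=bool(conv[0]))


def basin_map(
    spec: LocalMapSpec,
    topology: Topology,
    D: float,
    grid_resolution: int = 200,
    horizon: int = 10_000,
    x_max: float = 1.0,
    attractor_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """X_m over a regular (x1, x2) grid of two-patch initial conditions.

    Returns ``(grid, Xm)`` where ``Xm[i, j]`` is the excursion minimum from
    ``(grid[i], grid[j])``. The map is exactly symmetric under patch
    exchange because the two-patch dynamics commutes with relabeling.
    """
    if topology.L != 2:
        raise ValueError("basin_map is defined for two-patch topologies")
    if spec.family not in ("logistic", "ricker"):
        raise ValueError("basin_map supports the logistic and ricker families")
    grid = np.linspace(0.0, x_max, grid_resolution)
    ref = find_attractor(spec, topology, D)
    # close the reference set under patch exchange so the convergence test
    # (and hence the whole map) is exactly symmetric under relabeling
    ref = np.concatenate([ref, ref[:, ::-1]], axis=0)
    X0 = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1).reshape(-1, 2)
    xm, _, _ = excursion_xm_batch(
        spec, topology, D, X0, horizon=horizon, attractor_tol=attractor_tol, reference=ref
    )
    return grid, xm.reshape(grid_resolution, grid_resolution)
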