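# metapersist

Individual-based simulation of stochastic metapopulations on coupled map
lattices, with the analysis toolkit needed to ask one sharp question: **at
which migration rate does a spatially structured, extinction-prone
population live longest?**

The package is for quantitative ecologists and biostatisticians studying
dispersal, synchronization and extinction risk in patchy populations
(single-species logistic/Ricker dynamics, or Nicholson–Bailey
host–parasitoid dynamics), and for anyone who needs a rigorously tested
discrete-generation island-model simulator with demographic noise.

## The model

Space is a graph of habitat patches (two patches, 1-D chains/rings, 2-D
lattices with optional periodic boundaries and inaccessible "defect"
sites). Each generation has two steps:

1. **Local reaction** (demographic stochasticity). With carrying-capacity
   scale N per patch, each of the λn offspring of the n residents survives
   local competition independently, so

   n′ = min(N, Binomial(λn, 1 − n/N)) (logistic),
   n′ = Binomial(e^r n, e^(−rn/N)) (Ricker),

   and for the host–parasitoid pair the number of hosts escaping
   parasitism is k = Binomial(H, e^(−aP/N)), after which H′ = λk and
   P′ = c(H − k). The mean of each rule is the familiar deterministic map
   (x′ = λx(1−x); x′ = x e^{r(1−x)}; the Nicholson–Bailey pair), and the
   engine converges to the deterministic coupled map lattice
   x(t+1) = M(D)·f(x(t)) as N → ∞, with relative fluctuations ~ 1/√N.
2. **Migration.** Every individual emigrates with probability D and picks
   a destination uniformly among its patch's neighbors; all moves are
   applied in a parallel update, so the global count is conserved exactly.
   In the deterministic limit this is the column-stochastic dispersal
   matrix M(D) with M_jj = 1 − D and M_ij = D/n_j on edges.

The all-zero state is absorbing. Because the local dynamics are chaotic
(or otherwise unstable), the deterministic system never goes extinct but
the stochastic one always does — the question is how slowly. Three
estimators of the mean time to extinction τ̄ are provided: direct
averaging of simulated lifetimes; a Gaussian-fluctuation score
N̄²/(2σ²) from a long surviving run; and a purely deterministic
excursion score N·⟨X_m⟩, where X_m is the minimum total density along the
transient from a random state back to the attractor. The central
phenomenon the package reproduces: **τ̄(D) is maximal exactly where the
deterministic lattice supports the antiphase "checkerboard" (up-down)
pattern, and this optimum is set by decoherence, not by the Lyapunov
attractiveness of the orbit.**

## Worked example

The canonical two-patch experiment (λ = 4, N = 300 individuals per patch,
300 replicate lifetimes per grid point) is packaged as a study function:

```python
from metapersist.studies import logistic_bell_study
from metapersist import LocalMapSpec, find_period2_antiphase

bell = logistic_bell_study(seed=1)
print(f"optimal migration rate D*   = {bell['D_opt']}")
print(f"mean lifetime at D*         = {bell['tau_at_opt']:.0f} generations")
print(f"mean lifetime at D=0, D=0.5 = {bell['tau_at_ends'][0]:.0f}, "
      f"{bell['tau_at_ends'][1]:.0f}")
print(f"attractor at D*             = {bell['label_at_opt']}")
spec = LocalMapSpec("logistic", N=300, lam=4.0)
print(f"antiphase orbit at D*       = {find_period2_antiphase(spec, bell['D_opt'])}")
```

Output:

```
optimal migration rate D*   = 0.15
mean lifetime at D*         = 5188 generations
mean lifetime at D=0, D=0.5 = 21, 1368
attractor at D*             = UDUD
antiphase orbit at D*       = (0.4584137856082511, 0.8987290715346061)
```

Reading: an isolated pair of patches (D = 0) survives ~20 generations and
a strongly mixed pair ~1400, but at D* = 0.15 — precisely where the
deterministic map locks into the period-2 up-down cycle alternating
between densities 0.46 and 0.90 — the metapopulation survives over five
thousand generations. The attractor label comes from the deterministic
lattice, the lifetime from the individual-based engine; their coincidence
is the checkerboard effect. (The bell's top is flat to within sampling
error across one grid step around the stable window's edge, so the
sampled argmax can land one step left of the window; see
docs/methods.md.) The same machinery, at lower level, is
`sweep_migration(spec, topology, D_grid, reps, rng, max_gen)`.

A command-line interface mirrors the library for batch work:

```bash
metapersist sweep --fixture logistic_2patch --out results/
metapersist orbit --fixture logistic_2patch --dgrid 0:0.5:200 --out results/
metapersist basin --fixture logistic_2patch --out results/
```

Every CSV ships with a JSON sidecar (config hash, seed, versions);
re-running any command with the same inputs is byte-identical.

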