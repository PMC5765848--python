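# gradsense

Splitting probabilities of Brownian particles to small absorbing windows in
unbounded two-dimensional domains, an efficient hybrid analytic–stochastic
simulator, and recovery of the emitting source from the window fluxes.

## The problem

A point source at `x0` emits particles that diffuse in the plane around a
reflecting obstacle — a cell-like disk, the boundary line of a half-plane, or
a disk inside a reflecting strip.  `N` small absorbing windows (receptors) of
common arclength `ε` sit on the obstacle boundary.  Because planar Brownian
motion is recurrent, every particle is eventually captured, and the quantity
of interest is the *splitting probability* `P_k`: the fraction of the
steady-state flux captured by window `k`.  This is the physical signal a cell
can use to sense the direction and position of a diffusive gradient source.

Three routes to `P_k` are implemented and cross-validated:

1. **Matched asymptotics.**  In the narrow-escape regime (`ε` small compared
   with the window separations) the steady state is

   `P(x) = G(x, x0) + Σ_k A_k (ln|x − x_k| − ln ε̂) + C`,

   where `G` is the Neumann Green's function of the domain (method of
   images), and matching at the window centres gives a bordered
   `(N+1)×(N+1)` linear system for the flux coefficients `A_k` and the
   constant `C`, with `P_k = π A_k` and `Σ P_k = 1`.  The matching constant
   uses the exact logarithmic capacity of a window, `ε̂ = ε/4` (an absorbing
   segment of length `ε` on a reflecting line has capacity `ε/4`); the plain
   leading-log convention `ε̂ = ε` is available via `capacity_factor=1`.
   For two windows the system reduces to the closed form
   `P_1 = 1/2 + (π/2)(G(x_1,x0) − G(x_2,x0))/ln(d/ε̂)`
   — the window nearer the source wins; for three windows an explicit
   determinant solution is provided.

2. **Hybrid analytic–stochastic simulation.**  Instead of tracking Brownian
   paths through the unbounded plane (infinite mean hitting times), particles
   are placed directly on an inner artificial boundary with the exact
   first-hit distribution (harmonic measure) seen from the source — a wrapped
   Cauchy angle for a circle, its mirror-folded variants for the half-plane
   and strip.  Euler stepping happens only in a small working region; on
   crossing the outer boundary the particle is re-injected exactly.
   Near-boundary absorption uses segment-crossing tests plus a
   Brownian-bridge wall-touch correction.

3. **Source recovery.**  One window pair constrains the source to a
   one-dimensional locus (`P_2 = α` level set); with three or more windows
   the `N−1` independent fluxes are inverted by multi-start least squares to
   the unique source position, with uncertainty regions under multiplicative
   flux perturbations and distance-over-flux maps.

## Worked example

```python
import numpy as np
from gradsense import (HalfPlane, WindowSet, SourceSpec, HybridConfig,
                       splitting_two_windows, run_splitting,
                       forward_fluxes, recover_source, RecoveryProblem)

hp = HalfPlane()                               # domain x > 0, wall at x = 0
windows = WindowSet.on_line([0.5, -0.5], 0.1)  # two windows, d = 1, eps = 0.1
src = SourceSpec((2.0 * np.cos(0.5), 2.0 * np.sin(0.5)))   # L = 2

ana = splitting_two_windows(hp, windows, src)
sim = run_splitting(hp, windows, src, HybridConfig(n=100_000, seed=3))
print(ana.probabilities)          # [0.53112 0.46888]
print(sim.probabilities)          # [0.52931 0.47069]
print(sim.stderr)                 # [0.00158 0.00158]
```

The analytic and simulated window-1 probabilities (0.5311 vs 0.5293 ± 0.0016)
agree within statistical error; the window nearer the source receives the
larger flux.  Recovering a source from three windows:

```python
geom = HalfPlane(side=-1)
win3 = WindowSet.on_line([-1.0, 0.0, 1.0], 0.1)
fluxes = forward_fluxes(geom, win3, (-2.0, 8.0))
print(fluxes)                     # [0.32929 0.28753 0.38318]
res = recover_source(RecoveryProblem(geom, win3, fluxes[:2]))
print(res.position)               # [-2.  8.]
```

The first two fluxes alone pin the source back to `(-2, 8)` to below 1e-6.

A JSON-configured CLI wraps the same library:

```bash
gradsense fixture fig4_three_windows --out cfg.json
gradsense recover --config cfg.json --out results/
gradsense simulate --config cfg.json --seed 7 --out results/ --format both
```

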