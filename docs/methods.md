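# Methods

This note records the model conventions, the numerical choices and the
problem sizes behind `gradsense`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Model and scope

Steady-state diffusion from a point source in an unbounded planar domain
with a reflecting obstacle carrying `N` small absorbing windows.  The
stationary density solves a mixed Neumann–Dirichlet problem for the Poisson
equation with a delta source; the observable is the vector of splitting
probabilities (per-window shares of the total flux, which is one by
recurrence of planar Brownian motion).  Supported domains: the half-plane
(windows on the boundary line), the exterior of a disk (windows as arcs),
and a disk centred in a reflecting strip (simulation only — no closed-form
Neumann Green's function is implemented for that domain).  Time-dependent
transport, 3D domains, receptor kinetics and clustered/overlapping windows
are out of scope.

Units are nondimensional: injection rate `Q = 1`, diffusivity `D = 1` in the
analytic formulas (`D` is kept as a simulation parameter; splitting
probabilities are independent of it).

## Matched asymptotics

The outer solution is `G(x, x0) + Σ_k A_k (ln|x−x_k| − ln ε̂) + C` with the
image-method Neumann Green's functions

* half-plane: `G = −(1/2π)(ln|x−x0| + ln|x−x̄0|)`, mirror image across the
  boundary line;
* disk exterior: `G = −(1/2π)(ln|x−x0| + ln|(R²/|x|²)x − x0|)`.

Matching at each window centre yields the bordered linear system with
off-diagonal entries `ln(d_ij/ε̂)`, a border of ones, right side
`(−G(x_i,x0), 1/π)`; it is solved by LU with a condition-number guard
(`cond > 1e12` raises a degenerate-configuration error).  For `N = 2` and
`N = 3` the closed-form reductions are implemented and tested to agree with
the generic solve to 1e-12 / 1e-10.

**Orientation.**  Subtracting the two-window matching conditions gives
`A_1 − A_2 = (G_1 − G_2)/ln(d/ε̂)`: the window nearer the source (larger
`G`) receives the larger flux.  The hybrid simulator independently
confirms this sign.

**Matching constant (window capacity).**  The inner problem at a window is
an absorbing segment of length `ε` on a reflecting line; its exact exterior
solution `A·Re arccosh(2z/ε)` has far field `A(ln|z| − ln(ε/4))`.  The
logarithmic capacity `ε̂ = ε/4` is therefore used in every logarithm
(`capacity_factor = 4` by default).  This constant is what closes the gap
between the asymptotics and exact Brownian statistics at finite `ε`: with
`ε = 0.1`, `d = 1` the leading-log convention (`ε̂ = ε`,
`capacity_factor=1`, also exposed because the printed forms of the theory
are usually written that way) overestimates `|P−1/2|` by roughly
`ln 4 / ln(d/ε)` ≈ 60% relative, while the capacity-corrected forms agree
with the simulator to well under one percent of `|P−1/2|`.  Arc windows on
the disk use the same flat-segment capacity; the curvature correction is
`O((ε/R)²)` and is visible only as a small residual in the disk agreement
tests.  Remaining differences are genuine higher-order terms of the matched
expansion (next order in `1/ln(d/ε̂)`), a fraction of a standard error at
the problem sizes used below.

**Validity guards.**  Window separations below `ε` raise an error;
below `5ε` a `RegimeWarning` is emitted (the threshold is a package choice,
not derived).

## Hybrid analytic–stochastic simulator

Each trajectory alternates exact analytic placement with local Euler
stepping:

1. **Injection.**  If the source lies outside the inner artificial boundary
   (circle `Re`, half-circle `Re`, or strip cross-section `|x| = d_e`), the
   particle starts on that boundary with the exact first-hit density:
   a wrapped Cauchy angle with parameter `q = Re/r` (circle; sampled by the
   closed-form inverse CDF `Δ = 2 atan(((1−q)/(1+q)) tan(π(u−1/2)))`), its
   reflection-folded image for the half-plane, and the accordion-folded
   Cauchy density for the strip.  Folding an exactly sampled unfolded
   variable is itself exact (method of images), so no rejection sampling is
   needed anywhere.  Otherwise the trajectory starts at the source.
2. **Stepping.**  Gaussian increments with RMS displacement
   `δ(dist) = clip(dist/4, δ0, 18 δ0)` where `dist` is the obstacle
   distance and `δ0 = ε/6` (`dt = ε²/144` at `D = 1`).  Distance scaling is
   admissible because re-injection (below) is exact from any point outside
   the inner boundary; steps only need to resolve geometry near the
   obstacle.  Strip walls are handled by exact Gaussian folding.
3. **Absorption and reflection.**  A step segment crossing the obstacle is
   absorbed if the crossing lies in a window, otherwise specularly
   reflected (iterated for multiple reflections).  Non-crossing steps apply
   the Brownian-bridge touch correction: the true path still reaches the
   boundary with probability `exp(−d₁d₂/(D dt))`; when it does, the touch
   location is the segment interpolated at the expected touch time plus a
   tangential bridge fluctuation, and a touch inside a window absorbs.
   Without this correction the effective window capacity is visibly too
   small (a single-window benchmark against the exactly solvable
   segment-capacity problem measures 0.015 instead of `ε/4 = 0.025` at
   `δ0 = ε/3`); with it the benchmark is step-size converged from
   `δ0 = ε/6` on, which fixed the default.
4. **Re-injection.**  Crossing the outer boundary (`Ro`, or `|x| > d_o`)
   terminates the excursion; the particle is re-injected onto the inner
   boundary with the exact first-hit density seen from the escape point.
   This is the exact renewal distribution because the obstacle lies inside
   the inner boundary, and it is insensitive to how far the step overshot
   the outer boundary.  Absolute time is deliberately not tracked.

Defaults: `Re = 1.5×` and `Ro = 3×` the obstacle extent; a safety cap of
1e4 re-injections per trajectory (never approached in the reference
scenarios) raises a diagnostic error.  Estimates are per-window absorption
frequencies; they sum to one exactly, with binomial standard errors
`sqrt(p(1−p)/n)`.  Runs are deterministic for a fixed seed (a NumPy PCG64
generator drives the compiled kernels).

## Source recovery

The forward map is the window system above.  `recover_source` runs
Levenberg–Marquardt least squares on the first `N−1` flux residuals from a
polar multi-start grid (8 angles × 6 log-spaced radii up to 50 window
separations — a solver guard, configurable), reparametrised so iterates
cannot enter the obstacle; converged roots with residual below 1e-9 are
deduped at 1e-4 and any surviving multiplicity is reported as an ambiguity
(for three windows the intersection is generically unique; spurious
pairwise candidates fail the remaining flux conditions).  Uncertainty
regions map a `grid×grid` sample (default 21×21) of the multiplicative
perturbation box `obs_i(1+η_i)`, `η_i ∈ [−η, η]`, through recovery and take
the convex hull; sampling both signs independently is a superset of
perturbing both fluxes by a common factor.  The distance–flux map inverts
each admissible `(P_1, P_3)` pair of the flux simplex with warm starts from
neighbouring cells.

## Synthetic scenarios (fixtures)

The package generates its reference scenarios in code
(`gradsense.config.make_fixture`): two windows one separation apart on the
half-plane boundary with the source on polar grids `L ∈ {2, 5, 10}` ×
9 angles in `[−1.2, 1.2]` rad; three windows at `y = −1, 0, 1` with the
source at `(−2, 8)` (and a five-window variant at unit spacing); a disk
with two windows for the `Re ∈ {1.3, 2, 3} × Ro ∈ {3.5, 5}` stability
sweep; a disk in a strip (`R = 1`, half-width `a = 2`).  The window size is
`ε = 0.1` throughout — a choice, documented here, since the reference
scenarios are ε-consistent in both directions of the round trip.  These
fixtures emulate idealised receptors: perfectly absorbing, equal-size,
well-separated windows and a noiseless steady state.  Passing tests show
internal consistency of asymptotics, simulation and inversion under these
conditions; they do not address receptor kinetics, finite measurement time
or extrinsic noise in real gradient sensing.

## Problem sizes and tolerances in the test suite

* Analytic–stochastic agreement sweep: n = 1e5 trajectories per grid point
  (27 points), acceptance band 3 binomial SE per point.
* Artificial-boundary stability: n = 2e4 per `(Re, Ro)` combination,
  deviations from the grand mean bounded by 3 SE.
* Conservation: 1e-12 on analytic sums (100 random configurations,
  N ∈ {1, 2, 3, 5}); simulated frequencies sum to one exactly.
* Exit densities: quadrature normalisation to 1e-8; samplers pass
  chi-square against the densities at n = 1e5, p > 0.01 (fixed seeds).
* Recovery round trips: 1e-6 in position; uncertainty regions contain the
  noiseless solution and grow monotonically with η.
* Strip Green's function: closed form vs 1e4-mode Fourier series to 1e-8.

## Known limitations

* The asymptotic formulas degrade gracefully but are not accurate for
  window separations approaching `ε` (they still return numbers, with a
  warning).
* The bridge touch correction uses a flat-boundary approximation near the
  disk (exact for the half-plane wall); residual bias is below a standard
  error at the reference sizes but grows with `ε/R`.
* Recovery assumes observations generated by a consistent forward model;
  strongly inconsistent fluxes raise a no-solution error rather than
  returning a best-effort point.
* The strip geometry has no analytic splitting route here; it is validated
  through simulator invariants (conservation, determinism, wall folding)
  rather than against a closed form.
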