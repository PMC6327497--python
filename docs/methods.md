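# Methods

## Growth maximization

A ME model's constraints `S(μ)v = 0`, `l(μ) ≤ v ≤ u(μ)` are linear for fixed
μ and the feasible set of growth rates is an interval `[0, μ*]`, so the
global optimum is found by bisection on LP feasibility over `[0, μ_max]`
(default bracket ceiling 2.0 1/h, termination when the bracket is narrower
than `tol`, default 1e-6). μ-dependence is restricted to three serializable
forms — constant `a`, linear `a + b·μ` (dilution, enzyme coupling), and
hyperbolic `a·μ/(b+μ)` with `b > 0` (translation-rate saturation) — which
keeps the fixed-μ instantiation trivially safe and the JSON round trip exact.

All LPs are solved in double precision with HiGHS at a 1e-9 feasibility
tolerance. This is a deliberate departure from the quad-precision
(1e-20-tolerance) solvers genome-scale ME models require: the desk-scale
fixtures here have coefficient ranges below 1e6 and are well-conditioned.
Genome-scale reconstructions are out of scope and would not be reliable under
this arithmetic.

**Solution polishing.** At the converged μ the flux vector returned by a pure
feasibility solve is an arbitrary interior point, which makes assertions like
"the expensive substrate is untouched" ill-defined. We therefore re-solve at
μ* with a parsimonious secondary objective — minimize total complex-formation
flux (base mode) or total complex concentration Σp (inertia mode) — and fall
back to the plain feasibility point if that LP fails. This is a
determinism/reporting choice; it does not affect μ*.

**Degenerate outcomes.** A model feasible at μ = 0 but at no μ > 0 returns
`status="optimal"` with `mu_opt=0` (a consistent, non-growing state);
`infeasible-at-zero` is reserved for genuinely inconsistent constraints. One
such case worth knowing: in inertia mode an initial proteome exceeding the
proteome budget is infeasible at μ = 0, because without active degradation
excess protein can only be removed by dilution, which requires growth. For
such initial states the feasible μ-set is not an interval and bisection's
precondition fails; initial proteomes must respect the budget.

## Enzyme coupling and the proteome budget

In the base (free re-allocation) formulation, enzyme amounts are implicit:
each complex contributes a synthesized constraint row with `+1` on its
formation reaction and `−μ/keff_ij` on every catalyzed reaction, i.e.
formation balances growth dilution of the enzyme demanded by the flux
(`e_ij = v_j/keff_ij`). An optional model-level `enzyme_budget` adds the
single inequality `Σ_i Σ_j v_j/keff_ij ≤ e_max`, capping the total implied
enzyme concentration; in inertia mode the same budget caps `Σ_i p_i`
directly. Making the budget first-class (rather than baking `1/keff` into
ordinary stoichiometry) is what lets keff perturbations and calibration
multipliers propagate into the capacity constraint.

## Protein inertia

At each step the optimizer anticipates over a horizon `H` (default 2 h,
independent of the simulation step): variables `(v, p, δ)` with
`v_form_i − μ·p_i = δ_i`, `p_i = p0_i + δ_i·H`, capacity
`Σ_j v_j/keff_ij ≤ p_i`, `p, v_form ≥ 0`, and the complex mass-balance rows
removed. After the solve, the realized step advances `p ← p0 + δ·dt`.

A consequence of this formulation worth stating explicitly: starting *at* the
steady-state proteome with a short horizon, the planned growth rate can
transiently **exceed** the sustainable optimum — the cell shuts enzyme
formation off (`v_form = 0`, `δ < 0`), lets the complex dilute, and spends the
saved synthesis cost on growth. On the single-substrate toy the overshoot
branch has the closed form `μ_o = (−1 + √(1 + 4·H·k·p0/g))/(2H)`, versus the
sustained branch `μ_s = (k·E − w·(E − p0)/H)/(g + w·E)`; the optimum is
`max(0, μ_s, μ_o)`. The overshoot is a real property of the horizon
formulation (a plan, not a sustainable state), and the dynamic loop corrects
it on subsequent steps as `p` declines.

## Batch integration

- Biomass: `X' = X·exp(μ·dt)` (exact for constant μ). Concentrations:
  forward-Euler with start-of-step biomass, `c' = c + v_ex·X·dt + feed·dt`.
  The literature leaves the integration rule unspecified; this is the
  simplest consistent scheme, and its O(dt) error is what the conservation
  test measures (the defect halves when dt halves).
- A substrate is *depleted* when `c < 1e-9` mmol/L (then clamped to exactly
  0); the availability set is `{c_i > threshold} ∪ {feed active}`.
- Re-solve triggers: availability changes (depletion, secretion crossing the
  threshold, feed making a metabolite available) and feed-window boundaries.
  Steps are clipped so they never straddle a feed boundary.
- Variable step: `dt = min(dt0, Δt_M, Δt_P)` with
  `Δt_M = min{c_i/(−r_i)}` over species whose net rate `r_i = v_ex_i·X +
  feed_i` would drive them negative within `dt0`, and
  `Δt_P = min{p_i/(−δ_i) : δ_i < 0}` (the depletion reading of the protein
  term; for δ > 0 no bound is needed). Because the concentration update is
  linear in dt, the limiting species lands at zero exactly.
- Uptake kinetics are deliberately *not* concentration-dependent: bounds are
  0/finite by availability only (default −1000 mmol/gDW/h when available,
  with per-reaction fixed overrides, e.g. an oxygen-style cap of −20).
  Between-solve propagation of the last fluxes is therefore exact, which is
  what makes the event-driven loop valid.
- Recording convention: the flux/μ stored at grid point `t_k` is the solution
  active over `[t_k, t_{k+1})`; trajectory integrals in tests use
  left-Riemann sums with the realized steps.
- Proteome trajectories record translation (formation) fluxes in base mode
  and `p` in inertia mode. Mass-fraction trajectories forward-fill time
  points with an all-zero proteome (e.g. after total substrate exhaustion),
  since composition physically persists when no synthesis occurs.

## Toy fixtures and their oracles

Fixtures are hand-derived so every optimum has a closed form independent of
the LP code (one internal currency metabolite `m`; biomass cost `g` = 10 mmol
m per unit growth flux; enzyme cost `w` = 100 mmol m per mmol complex; budget
`e_max` = 0.01 mmol/gDW):

- single substrate: `μ* = y·k·e_max/(g + w·e_max)`; the canonical values
  (k = 10/h) give `μ* = 1/110`, and doubling the budget gives `1/60`;
- inertia from an empty proteome: `μ*(H) = (k·E − w·E/H)/(g + w·E)`, zero
  when H is too short to amortize enzyme construction (H = 2 h);
- two substrates with keff 10 vs 2 share the budget: the LP provably uses
  only the five-fold cheaper enzyme while its substrate lasts (desk-scale
  diauxie);
- the five-substrate fixture adds transporter caps on substrates 2–5 (forcing
  a mixed phase) and couples 0.4 mmol of a re-consumable byproduct to each
  unit of preferred-substrate uptake (overflow), with the byproduct's keff
  the worst; this yields the single → mixed → byproduct-reuse phase ordering.

Initial concentrations (0.002–0.05 mmol/L at X0 = 0.1 gDW/L) are sized so
depletions occur mid-batch at these growth rates (~3 h for the preferred
substrate); they are scale parameters of the fixture, not biological claims.

**Synthetic measurements** simulate the model, shift every profile by a
planted lag (edge-held interpolation), add i.i.d. Gaussian noise, and clamp
concentrations at zero. Gaussian i.i.d. noise is the simplest testable
stand-in and is *not* a claim about microarray error structure; the
clamping truncates the noise when concentrations are at the σ scale, so
noise-calibration checks use fixtures with concentrations ≫ σ. A green
planted-lag test establishes that the lag scan recovers a known shift on
smooth, noise-controlled profiles — not that real expression data have a
single common lag.

## Ensemble and archetypes

keff perturbation factors are log-uniform on [0.1, 10] (the stated range;
the distribution is this package's choice — symmetric in log space, median
1), i.i.d. across couplings, reproducible by seed. Fit error is the SSE
between simulated and measured extracellular concentration profiles after
linear resampling to a common grid; the default ensemble cut is 1.5× the
best SSE (no literature value exists).

Archetypal analysis factorizes the (timepoint × metabolite)-by-sample matrix
as `X ≈ ZA`, `Z = XB`, with columns of A and B on the probability simplex.
Fitting is block-coordinate descent: per-sample simplex least squares for A,
then one archetype at a time for B against the residual with the others
fixed (which keeps rss non-increasing); simplex least squares is NNLS with a
sum-to-one penalty row (penalty 20·max|X|, accurate to ~1e-8 after
normalization). Initialization selects well-separated data columns, starting
from the column furthest from the data mean — an interior start can trap the
descent in a visibly suboptimal hull. Defaults: tol 1e-6 relative rss
change, max 500 sweeps. Columns are not standardized before factorization
(exposed as a caller-side preprocessing choice). The archetype count is the
interior scree point with the largest perpendicular distance to the chord
joining the scree endpoints — an explicit, testable reading of the
otherwise-visual elbow method; ties go to the smaller count. Recovery has a
structural limit: since `Z = XB`, planted archetypes are recoverable only
when some samples lie near each vertex (the test generator plants near-pure
samples deliberately).

## Calibration (list-based threshold accepting)

The objective (simulation SSE) is gradient-free and non-smooth, so
calibration uses threshold accepting with an adaptive list: a warm-up random
walk of `5·L` moves collects the `L` largest *relative* worsenings
`(Z_new − Z_cur)/Z_cur` as the initial thresholds (L = 8 by default); the
main loop accepts a move when its relative worsening is below the list
maximum `T_max`, and each accepted worsening replaces `T_max` with the
smaller realized value, annealing toward greedy search. Moves perturb one
coordinate, multiplicatively in log space with reflection when the bounds
are positive (the keff-multiplier case, bounds [0.1, 10]), additively
otherwise. Evaluations are memoized on the log-multiplier vector rounded at
1e-10. All hyperparameters (list size, warm-up multiplier, neighborhood
scale 2.0, iteration budget) are package defaults exposed in `LTAConfig`;
the literature defers them to the cited metaheuristic.

Multi-walker mode is a *synchronization contract*, not a threading mandate:
walker 0 never restarts; walkers 1..W−1 may adopt the global best at sync
points every `restart_period` (default 50) iterations. The schedule runs
serially and deterministically; a concurrent executor honoring the same sync
points would reproduce it exactly. The canonical configuration is 7 walkers
(1 local + 6 restarting).

## Expression validation

Simulated proteomes become mass fractions `f_j = v_trsl_j·w_j/Σ` (base) or
`f_j = p_j·w_j/Σ` (inertia), log2-transformed with a floor of 1e-6 (simulated
fractions can be exactly zero). Both sides are linearly interpolated onto the
overlap of their supports at the smaller *median* native interval (median,
because event-clipped simulation grids contain occasional short steps that
would otherwise dictate an absurdly fine grid); the canonical grid is 0.1 h.
The cross-correlation convention is pinned explicitly: for lag ℓ, the plain
Pearson correlation of `(x_t, y_{t+ℓ})` with means and variances computed on
the overlapping window; zero-variance windows yield a missing value, never
0, and missing proteins are ignored in the per-lag median. The common lag is
the grid lag in [−1.7, +1.7] h maximizing the median per-protein
correlation (ties: smallest |lag|, then the negative one). A positive best
lag means the measurements trail the simulation.

## Known limitations

- Double precision bounds the achievable feasibility tolerance; genome-scale
  ME models are out of scope.
- No active protein degradation, product inhibition, or
  concentration-dependent uptake kinetics; no chemostat mode.
- The event-driven loop's exactness relies on availability-only bounds; any
  concentration-dependent mechanism would require solving every step.
- Archetype fitting is a local method; pathological initializations can
  still converge to suboptimal hulls for adversarial data.
- The inertia-mode proteome budget makes over-budget initial proteomes
  infeasible rather than relaxing them (see above).
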