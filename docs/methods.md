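# Methods

## Model

The metabolism is the minimal mass-action autocatalysis `2A + F ⇌ 3A`
with first-order decay of `A`:

```
dA/dt = k_f·F·A² − k_b·A³ − k_d·A
```

This is the lowest-order scheme with the required phase portrait: a
stable dead state at the origin for every resource level, and a
saddle-node bifurcation at `F_bif = 2√(k_b·k_d)/k_f` above which a
stable viable branch and an unstable separatrix branch coexist (the
positive equilibria solve `k_b·A² − k_f·F·A + k_d = 0`).  Two
assumptions make the system mortal and keep the model minimal:

* **Closed, absorbing death set.** Touching `A_low` (starvation) or
  `A_high` (osmotic burst) at any instant is death; dead states are
  frozen.  A strictly positive `A_low` makes death by decay reachable
  in finite time.
* **Buffered environment.** In the non-spatial model the behavior ODE
  is the sole driver of `F`; metabolic consumption of the resource is
  not fed back.  In the spatial model `F` is pinned to position.
  Concentrations are clamped at zero.

Viability is decided analytically: a living state is *viable* iff the
stable branch exists, lies strictly between the death boundaries, and
`A` is above the separatrix — the frozen-`F` dynamics are monotone
between equilibria, so no integration is needed.  The classifier is
nevertheless checked against brute-force frozen-`F` integration on a
41×41 grid (excluding a 1e-3 band around the separatrix, where fate is
numerically undecidable).

Behaviors are bounded saturating controllers,
`r_max·tanh(gain·(target − signal))`; the motor limit `r_max`
captures the finite rate at which a cell can change its local
resource level, and the gain is the sensitivity inside that bound.
The hybrid's sigmoid takes `k_σ` as the equal-influence point in `A`
and `k_r` as the steepness.  (The opposite assignment was evaluated;
on the default preset it yields a cell-for-cell identical 51×51
survival partition, so nothing in the headline comparison hinges on
this choice.)  The rate input to the derivative-sensitive controllers
is the analytic `dA/dt` at the current state — an idealised,
noise-free sensor with no lag.

## Parameters and calibration

Frozen default preset (all configurable):

| parameter | value | units | role |
|-----------|-------|-------|------|
| `k_f` | 0.8 | conc⁻²·t⁻¹ | autocatalytic forward rate |
| `k_b` | 0.2 | conc⁻²·t⁻¹ | backward rate |
| `k_d` | 0.8 | t⁻¹ | decay rate |
| `A_low` | 0.5 | conc | starvation boundary |
| `A_high` | 8.0 | conc | osmotic-crisis boundary |
| `r_max` | 1.0 | conc·t⁻¹ | motor limit |

This gives `F_bif = 1.0`, well inside the explored resource window
`F ∈ [0, 4]`, with the viable branch spanning `A ≈ 2–8` over that
window — so the shipped controller targets (`θ_F = 1.12` just above
the bifurcation knee, `θ_A = 4.0` near the inter-boundary midpoint of
4.25) sit where their parameter ranges suggest.

The preset is a single frozen calibration chosen so that the shipped
controller presets reproduce the qualitative survivability ranking
B4 > B3 > B1 > B2 on the default 51×51 grid.  Two properties of the
calibration matter and are worth stating honestly:

* The kinetic time scale (uniform factor on the three rates) sets how
  fast the metabolism races relative to the fixed actuator; the
  bifurcation diagram is invariant under this factor.
* The rate-of-change controller (B3) with a high gain is a very strong
  baseline in this model family: it can null `dA/dt` anywhere,
  including *on the unstable branch*, parking systems in states that
  are precarious but formally alive.  With a starvation boundary near
  zero this lets B3 edge out the shipped hybrid by a few grid cells.
  At `A_low = 0.5` the low-`A` sliver of such parking states is
  outside the living range and the hybrid ranks first, but the B4–B3
  survival margin remains small (≈2 of 2601 cells); the hybrid's
  clearer advantages are the *robustness* ones below.

## Simulation and numerics

* Single trajectories: adaptive RK45 (`scipy.integrate.solve_ivp`,
  rtol 1e-8 / atol 1e-10) with terminal events at both death
  boundaries; event times are solver-localised.
* Survivability maps, fitness lattices, spatial populations: a
  vectorised fixed-step classical RK4 stepper advancing all systems in
  lockstep (step 1e-3 for reporting runs), freezing each system in the
  step where it first touches a boundary.  The 51×51 survival
  proportions are step-size-converged: they are identical at dt =
  2e-3, 1e-3 and 5e-4.
* Ties: exact contact with a boundary counts as death (closed death
  set); `dF/dt = 0` counts as up-gradient in the spatial motion rule.
* Reported problem sizes: 51×51 initial-condition grids integrated to
  t = 100 for maps; the optimisation stage evaluates fitness on an
  11×11 lattice integrated to t = 50 at dt = 0.05 (coarser but
  self-consistent between the exhaustive search and the GA it is
  compared with); GA: population 40, 2000 tournaments, recombination
  0.5, mutation sd 1 % of range, modular wrap.

## Spatial model

Agents live on `x ∈ [0, 1]` with a linear resource ramp `F = 0 → 4`
(a logistic ramp is available) and hard walls.  Each step: read the
local `F`, evaluate the controller, move `±v·dt` by the sign of
(controller output + the agent's fixed bias ε), relocate onto the wall
if overshot, then advance `A` one RK4 step at the pre-move resource
level.  Agent speed defaults to `v = 0.25`, chosen so that the maximal
rate of resource change along the gradient, `v·dF/dx = 1.0`, equals
the abstract model's motor limit — the spatial model then probes the
same actuation regime as the maps.  Initial positions and metabolite
levels are uniform (positions between the walls, `A` between the death
boundaries); ε is 0 or normal with sd `0.05·r_max`.  Each agent draws
from its own random substream keyed by (seed, agent index), so runs
are reproducible and enlarging the population leaves existing agents'
trajectories unchanged.

The per-agent error bias is where the hybrid distinguishes itself:
with ε = 0 the hybrid and the rate-of-change controller survive
essentially the same set of agents (their abstract basins nearly
coincide under this calibration), while under biased actuation the
hybrid's survival drops less — its high-`A` resource-homeostat branch
parks agents at a genuine attractor, which tolerates a constant push,
whereas bias slowly walks the rate-of-change controller's
marginally-held states into a boundary.  The spatial survival ranking
is therefore asserted on the biased runs.

## What the synthetic experiments do and do not show

All data are generated by the simulator; there is no external input.
The model is a caricature: one lumped metabolite, one lumped resource,
noise-free sensors, deterministic bang-bang motility with no
run-and-tumble stochasticity, no agent interaction or resource
depletion, and mortality thresholds imposed by fiat.  Passing tests
show that the implemented dynamical mechanisms behave as analysed —
they say nothing quantitative about real *E. coli* or *R. sphaeroides*
chemotaxis.  Conclusions that are robust in this family (blindness of
single-signal controllers, the indirect dual sensitivity of the
rate-of-change signal, switching as a sufficient integration
mechanism) are qualitative.

## Known limitations

* The B4 > B3 survival margin on the frozen preset is small (see
  above); under other calibrations of the kinetic constants the
  rate-of-change controller can rank first on raw survival.
* Fitness totals (`S + V`) do not rank the behaviors in the same
  order as survival alone (the metabolite homeostat scores a high
  closeness `V` by construction); the package reports both.
* The fixed-step stepper resolves death times only to one step;
  adaptive event detection is available per-trajectory.
* `classify_state` treats a stable branch exactly on a death boundary
  as precarious; trajectories converging asymptotically to such a
  branch never formally die in finite time.  The measure of such
  states is zero and no default grid cell hits one.
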