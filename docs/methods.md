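# Methods

## The model

`undiag` analyses chronic diseases with a prolonged sub-clinical phase —
hypertension, type 2 diabetes, coronary heart disease — through a four-state
illness-death model on the Lexis plane (calendar time *t* × age *a*, both in
years):

```
        lambda0          lambda1
  0 ──────────────▶ 1 ──────────────▶ 2
 healthy        undiagnosed       diagnosed
   │ mu0            │ mu1            │ mu2
   ▼                ▼                ▼
                  dead
```

All transition intensities are per person-year and may depend on both *t*
and *a*. Writing `N_j(t, a)` for the number of persons in state *j* aged *a*
at time *t*, and assuming a closed population (no migration), the counts
satisfy a linear transport system in the directional derivative
`∂t + ∂a` — the rate of change seen while following a birth cohort:

    (∂t + ∂a) N0 = -(mu0 + lambda0) N0
    (∂t + ∂a) N1 = -(mu1 + lambda1) N1 + lambda0 N0
    (∂t + ∂a) N2 = -mu2 N2 + lambda1 N1

Epidemiology works with the age-specific prevalences `p_j = N_j / N`,
`N = N0 + N1 + N2`. With the overall mortality
`mu = mu0 p0 + mu1 p1 + mu2 p2`, the two disease-state prevalences satisfy

    (∂t + ∂a) p1 = -(lambda0 + lambda1 + mu1 - mu) p1 - lambda0 p2 + lambda0
    (∂t + ∂a) p2 = lambda1 p1 - (mu2 - mu) p2

and `p0 = 1 - p1 - p2`. The `+lambda0` constant term is essential: at
`p = (0, 0)` the right-hand side must reduce to `(lambda0, 0)` so that
positive incidence raises the undiagnosed prevalence from zero (a sign
worth stating explicitly because it is easy to get wrong when assembling
the affine form).

Two *mortality modes* reflect what data are available:

* **general-mu** — the overall mortality `mu(t, a)` is an input (life-table
  data); state mortalities come as surfaces or as proportional ratios
  `mu_j = R_j · mu`. The system is then affine-linear in `(p1, p2)`.
* **state-specific** — `mu0, mu1, mu2` are inputs and `mu` is closed through
  the mixture identity, making the system quadratic. The nonlinearity is
  purely local (it involves only the state at the evaluation point), so it
  is evaluated inside each integrator stage; no outer iteration exists or
  is needed. Ratio shortcuts in this mode apply to `mu0`, the only
  prevalence-independent baseline present.

The package deliberately does **not** estimate `lambda0`, `lambda1` from
aggregated data, add migration terms, or propagate input uncertainty;
rates are inputs.

## Solution by characteristics

The transport operator differentiates along slope-1 *life lines*
`(t0 + s, s)` of the Lexis diagram, so the PDE system restricted to a life
line is an ODE initial-value problem, and the surface solution is obtained
by integrating from the point where each life line enters the domain. Two
geometries are supported:

* **half-plane** — data `p(t, 0)` on the whole age-0 axis; every life line
  enters at `(t - a, 0)` after an arc of length `a`.
* **first-quadrant** — a time window starting at `t_min` with data
  `p(t, 0)` for `t ≥ t_min` plus an age profile `p(t_min, a)`; cohorts born
  before `t_min` enter through the left edge. A continuously differentiable
  solution requires the two data curves to agree at the corner
  `(t_min, 0)` in value and first one-sided derivative; `check_compatibility`
  measures both gaps and `solve_surface` refuses (configurably: warn/skip)
  to integrate incompatible data. Analytic corner slopes can be attached to
  the boundary data; otherwise slopes are estimated by one-sided finite
  differences (the first table interval for gridded data, a step of 1e-5
  year for callables).

### Numerical choices

* Integrator: classical fixed-step RK4 along each life line; global error
  `O(step^4)` for continuously differentiable rates. The default step is
  `min(Δt, Δa, 0.25 yr)`. The final partial step is shortened to land
  exactly on the target node — the solution itself is never interpolated.
* Nodes sharing a life line are integrated sequentially along it when every
  node arc is a whole multiple of the step (the step sequence is then
  identical to solving each node independently); otherwise the solver falls
  back to per-node integration.
* Integration proceeds in increasing age only — the model's transport
  direction; there is no backward solving.
* Gridded rate tables are interpolated bilinearly and reproduce node values
  exactly; evaluation outside a table's rectangle raises an error naming
  the surface and the point. No extrapolation, ever: out-of-domain
  evaluation almost always means the input data do not cover the intended
  window. Piecewise-bilinear rates are accepted with the caveat that the
  formal fourth order degrades at grid creases.
* Solved states are checked against the prevalence simplex
  `{p1, p2 ≥ -ε, p1 + p2 ≤ 1 + ε}` with ε = 1e-8. Violations raise a
  diagnostic naming the worst node; the check can be downgraded to a
  warning for general-mu inputs whose `mu` is inconsistent with
  `mu1`/`mu2` (such inputs cannot guarantee the simplex and the diagnostic
  is then informative rather than fatal). Nothing is clamped silently.
* Degenerate inputs: a zero arc returns the boundary value; zero rates
  freeze the state; an all-zero scenario yields an identically zero surface.

### Independent validation routes

Three cross-checks, each with different numerics, guard the solver:

1. **Matrix exponential** — for constant rates the affine system is solved
   exactly via `expm` of the augmented 3×3 matrix (no special-casing of
   singular coefficient matrices, no time stepping).
2. **Upwind finite differences** — a first-order explicit scheme on the
   Lexis plane (forward in *t*, backward in *a*, CFL 0.5) that never looks
   at characteristics; its solution converges linearly in the mesh width to
   the characteristics solution.
3. **Microsimulation** — see below.

`convergence_order` fits the log–log slope of final-state error against
step size (at least three sizes, against a closed form or a 16×-finer
reference); RK4 lands near 4, and an explicit-Euler toggle near 1 as a
control. With zero rates all errors vanish and the order is reported as
undefined (NaN) rather than fitted to noise.

## The synthetic scenario

`make_hypertension_like_scenario` builds a fully self-contained problem
emulating a national blood-pressure survey setting: window 1999–2010 ×
ages 0–70, first-quadrant geometry, `p(t, 0) = (0, 0)` (nobody is born
hypertensive), mortality ratios R1 = 1.1 (undiagnosed) and R2 = 1.2
(diagnosed). Its parameter constants live in one dictionary
(`HYPERTENSION_PARAMS`), all illustrative:

* `mu0` — Gompertz `5e-5 · exp(0.095 a)` per year with a mild secular
  decline (×0.92 by 2010), a stylized life table for an adult population;
* `lambda0` (incidence) — logistic in age (plateau 0.042/yr, midpoint 45,
  width 10), time factor falling to 0.85 by 2010;
* `lambda1` (detection) — logistic in age (plateau 0.15/yr, midpoint 35,
  width 12), time factor rising to 1.5 by 2010.

Both logistic age factors are shifted to vanish exactly at age 0 (smoothly,
by subtracting the logistic's value at 0). This has two consequences:
rates near birth are negligible, as they should be for an adult-onset
condition, and the corner compatibility conditions hold *exactly* — both
boundary curves have value (0, 0) and one-sided slope (0, 0) at
`(1999, 0)`, and the generator attaches those slopes analytically, so the
scenario passes `check_compatibility` at tolerance 1e-10.

All time factors are flat before 1999, making the pre-window system
autonomous; the 1999 age profile `p(1999, a)` is therefore obtained exactly
by pre-solving along a single life line (RK4 at step 0.02 yr, stored as a
dense table with linear interpolation; the interpolation error,
~`h²/8 · |p''|` ≈ 1e-7, is far below every tolerance used against it).
The same flatness means the microsimulation, which must simulate cohorts
from birth (as early as 1929), sees exactly the dynamics the pre-solved
boundary encodes.

The magnitudes were chosen once so that the solved surface reproduces the
qualitative pattern expected of US-style hypertension data — roughly 14%
undiagnosed and 49% total prevalence at age 60 early in the window, with
awareness around 70% and the diagnosed share rising over the decade. The
generator emulates *structure*, not any particular survey's values: it
uses simple binomial sampling (no survey weights, strata or clusters),
simulates no blood-pressure measurements (the 140/90 mm Hg case definition
is narrative context only), and its incidence/detection values are not
estimates. Passing tests therefore demonstrate the correctness of the
numerics and the internal consistency of the model — not that any
particular real population follows these rates.

## The microsimulation oracle

`microsimulate` is the package's independent stochastic check. Each person
starts healthy at birth; in each step of length `dt` the transitions out of the
current state compete with exponential probabilities (`1 - exp(-rate·dt)`,
split among competing exits in proportion to their rates). Rates are
evaluated at the midpoint of each step along the person's life line, which
keeps the frozen-rate part of the discretization bias at `O(dt²)`; the
remaining `O(dt)` bias comes from forbidding two transitions within one
step and is bounded by roughly `a · max(lambda0·lambda1) · dt` ≈ 1e-3 at
`dt = 0.05` over 70 years. The validation suite therefore compares
empirical and PDE prevalences cell by cell against
`3 binomial SE + 1.5e-3`.

Birth cohorts are chosen so life lines cross grid nodes (with integer
grids: one cohort per birth year, optionally thinned); cohorts born before
the window populate the left-edge boundary empirically. State occupancy is
tallied whenever a life line crosses a node; nodes no cohort crosses are
NaN, and covered nodes where everyone has died yield flagged, undefined
prevalence. Everything is reproducible from a single seed
(`numpy.random.SeedSequence` spawning one stream per cohort).

Count-level shortcuts (binomial/multinomial aggregation) were deliberately
not used: the per-person implementation keeps the oracle's semantics
transparently independent of the PDE machinery it checks.

## Problem sizes used in the validation suite

The shipped tests and the acceptance script use: the full scenario grid
(12 × 71 nodes) with one 100,000-person cohort per birth year (82 cohorts)
at `dt = 0.05` for the microsimulation comparison (~1,700 cell/state
checks); ten randomized smooth state-specific scenarios on a
4 × 7-node half-plane grid for the counts↔prevalence and simplex checks;
and a 10-year × 30-age window with meshes down to `h = 1/32` year for the
upwind cross-check. These sizes give sampling errors and mesh gaps
comfortably below the tolerances they are compared against.

## Known limitations

* Fixed-step RK4 only; no adaptive error control (rates in this domain are
  smooth and cheap, and the fourth-order error at 0.25-year steps is
  orders of magnitude below data uncertainty).
* The upwind reference solver is implemented for general-mu (affine)
  rates; the characteristics solver itself handles both modes.
* The microsimulation needs state-specific mortalities — a general-mu
  scenario does not determine `mu0` without the prevalence it is being
  used to compute.
* Boundary tables and gridded rates are interpolated linearly/bilinearly;
  supplying coarse tables degrades the solver's formal order.
* No estimation, no migration, no uncertainty propagation (see scope
  above); the CLI reads no external survey or life-table formats — gridded
  CSV is the ingestion boundary.
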