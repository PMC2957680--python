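# Methods

## Model class

`ddesens` treats autonomous or time-forced systems of delay differential
equations with *fixed, discrete* delays,

    dx/dt = f(x(t), x(t−τ₁), …, x(t−τᵣ); θ, t),      x ∈ ℝⁿ, θ ∈ ℝᵖ,

with a **constant initial history** x(t) = x(0) for t ≤ t₀.  The right-hand
sides are supplied as text in a small sectioned model-file format and parsed
into expression graphs over the operators `+ − * / ^`, the intrinsics
`sin cos tan exp log sqrt abs tanh`, and primitives (constants, states,
delayed states written `state@label`, parameters, and the time symbol `t`).
A model with no delays is handled by the identical code path with no history
lookups — the plain ODE special case.

Out of scope by design: state-dependent or distributed delays, non-constant
initial history functions, and sensitivities with respect to a delay
*duration* as such.  A delay duration can still be analysed when it also
appears as an algebraic parameter inside the equations (as in the bundled
cardiovascular model, whose delay is fixed at one dimensionless unit while
the physical delay τ enters the respiration phase through the product
f_r·τ); differentiating through the history-lookup time itself is not
attempted because the variational system below contains no such term.

## Automatic differentiation

All Jacobians are computed by forward-mode AD on the expression graphs: one
bottom-up sweep per equation carries a (value, gradient) pair per node and
applies the chain rule at every elementary operation.  Derivatives are
therefore exact up to floating-point round-off; the value channel performs
bit-identical arithmetic to plain evaluation (tested).  Details that matter:

* `u^v` with an *inactive* integer exponent uses the integer power rule,
  valid for any sign of `u` — necessary because Hill terms with large even
  exponents may see transiently non-positive bases.  A fractional or active
  exponent with `u ≤ 0` is a domain error, as are `log`/`sqrt` outside
  their domains, division by zero, and `0^negative`.
* `abs` at exactly 0 uses the subgradient 0 and emits a `RuntimeWarning`.
* Constant folding is not performed; graphs evaluate exactly as written.

## Integration scheme

Each sampling interval [tᵢ₋₁, tᵢ] is covered by internal steps of size η:

1. **Step control.**  At the current point the Jacobian over current and
   delayed states, A = [∂f/∂x, ∂f/∂y] (n×(n+m)), gives the norm bound
   μ = n(m+n)·maxᵢⱼ|aᵢⱼ| ≥ ‖A‖₂.  If μ·ε ≥ 1 the system is declared stiff
   and the run aborts (ε defaults to 1e-3); if μ·η > 1 the step is clipped
   to η = 0.9/μ, which keeps the fixed-point corrector below a contraction
   constant of ~0.45.  With delays present η is additionally capped at the
   smallest delay — the standard method-of-steps constraint that guarantees
   every delayed lookup lands in already-accepted history.  The parameter
   Jacobian C plays no role in step control.
2. **State step.**  Implicit trapezoidal rule
   x(t+η) = x(t) + η/2·[f(t) + f(t+η)], solved by fixed-point iteration
   from an explicit Euler predictor.  The iteration stops when every
   component changes by less than atol + rtol·|x| (defaults 1e-12 and 1e-8)
   and then applies **one additional sweep** before returning, so the
   returned iterate sits within O(L·tol) of the implicit solution rather
   than O(tol), L being the contraction constant.  Reaching the iteration
   limit (default 20) without convergence aborts the run.
3. **Sensitivity step** (direct-decoupled).  With the state step accepted,
   the n×q sensitivity matrix Φ (q = p + n: parameter columns, then
   initial-condition columns) advances through the linear delayed
   variational system Φ̇ = AΦ + Σₖ Bₖ·Φ(t−τₖ)|rowₖ + C by the same
   trapezoidal rule, same η, same stopping rule including the polishing
   sweep.  Left-endpoint Jacobians are shared with step control;
   right-endpoint Jacobians are evaluated once per step (not per corrector
   sweep).  C's initial-condition columns are zero because f has no
   explicit x₀ dependence; Φ(t₀) is [0 | I].  Step control never reads Φ,
   so disabling sensitivities leaves the state trajectory bit-identical.

Delayed values come from an append-only history buffer holding every
accepted node; lookups interpolate linearly between bracketing nodes (found
by binary search), return stored values exactly when the lookup time hits a
node, and return the constant past (x₀, Φ₀) for t ≤ t₀.  Sensitivity
history uses the same linear interpolation as state history for order
consistency.  The final step of each sampling interval is the exact
remaining width, so output times are hit without output interpolation.

The trapezoidal rule is second order; on the linear test DDE
dx/dt = −x(t−1) with constant history the scheme is *exact* up to round-off
for t ≤ 2 (piecewise-quadratic solution, linear integrands) and shows the
expected ~4× error reduction per step halving beyond that.

`eval_count` reports the number of full right-hand-side passes — value
sweeps and AD Jacobian sweeps alike — as the method's cost diagnostic.

## Sensitivity measures and ranking

Absolute sensitivities s(xᵢ,θⱼ) = ∂xᵢ/∂θⱼ are converted to the
dimensionless relative form S = (θⱼ/xᵢ)·s, or to the semi-relative form
S̃ = θⱼ·s when a state passes near zero (relative conversion raises, or
warns under an explicit override, when any |xᵢ| drops below 1e-12 of its
trajectory maximum).  Initial-condition columns are scaled by x₀.  Column
importance over a run is the time-averaged magnitude
S̄ = (1/(t_f−t_start))·∫|S|dt, evaluated by the trapezoid rule on the
sampling grid; the averaging window defaults to the full run (no burn-in is
discarded) and is exposed as an option because on oscillatory systems the
choice visibly matters (below).  Ranking tables sort all q columns by S̄
with ties kept in declaration order, and report percentages of the total
over *all* columns, so a printed top-k subset does not sum to 100%.

## Validation oracles

The solver is never validated against itself:

* closed-form method-of-steps solutions of dx/dt = −θ·x(t−τ)
  (piecewise polynomials of growing degree);
* an independent reference integrator — method of steps over scipy's
  adaptive Runge-Kutta with dense output, segment length = smallest delay;
* forward-difference sensitivities obtained by re-solving perturbed models
  with that reference integrator (perturbation Δ = spacing_ratio·θ, with an
  absolute fallback of 1e-6 at θ = 0);
* central finite differences on 200 deterministic fuzzed expression graphs
  for the AD sweep.  The fuzz generator draws operators and intrinsics with
  bounded integer exponents and rejects (graph, binding) pairs near domain
  or conditioning edges (small divisors, log/sqrt arguments < 0.1, tangent
  near its pole, any node value above 50) so that the finite-difference
  oracle itself is well posed; it is deterministic in its seed.

## The bundled cardiovascular model

The two-state baroreflex model couples heart rate x1 (bpm) and arterial
pressure x2 (mmHg) through Hill-type feedback with exponent 8, a unit
sympathetic delay in dimensionless time, and a weak sinusoidal respiration
forcing (amplitude 0.003, frequency 2π·f_r·τ).  All 16 parameters use their
published nominal values.  Two quantities are *not* part of the published
set and are fixture choices, recorded in the fixture's notes: the initial
conditions, taken as the uncontrolled operating point x1(0) = h₀ = 100,
x2(0) = p₀ = 100, and the simulation horizon, taken as t* ∈ [0, 200] with
sampling step 0.02.

Two structural identities make good end-to-end checks and are asserted in
the tests: f_r and τ enter the equations only through their product, so the
relative sensitivities with respect to the two coincide pointwise; and with
the respiration amplitudes zeroed the sensitivities to f_r, τ and the phase
vanish identically.

**Caveat on time-averaged values.**  Under the fixture's initial conditions
the model sits on a growing Mayer-wave-like oscillation of the heart rate
(verified against the independent reference integrator to ~2·10⁻⁴ relative
at t = 50, so this is a property of the model, not of the solver).  On an
oscillatory orbit, parameter sensitivities grow secularly — a parameter
that shifts the oscillation frequency produces a sensitivity whose envelope
grows linearly in time — so time-averaged magnitudes depend strongly on the
averaging horizon and on how the orbit was entered.  The blood-pressure
averages are robust (S̄(x2, p₀) ≈ 0.96–1.09 across horizons from 10 to 200
time units, with p₀ always the top-ranked parameter for both states), but
the heart-rate averages and the ordering below rank 1 are not
horizon-stable.  Results for this model should therefore be compared at
matched initial conditions and horizons only.

**Finite-difference concordance window.**  Forward differences at spacing
ratio Δθ/θ = 0.01 agree with the propagated sensitivities to better than 2%
(where |S| > 0.05) over the first two delay intervals; beyond that the
O(Δθ) phase-drift bias of the forward quotient dominates, which the tests
demonstrate directly: the 0.1-spacing run deviates more than the
0.01-spacing run at over 90% of grid points over [0, 10], and 0.001 spacing
is closer still.  The propagated sensitivities are the Δθ → 0 limit.

## Problem sizes used in the tests

Analytic checks use grids of step 0.01 over one to three time units; the
structural-identity checks run the cardiovascular model over [0, 30]; the
finite-difference concordance uses [0, 2] (2% band) and [0, 10] (bias
ordering); the ranking computation in `scripts/acceptance.py` uses the full
fixture horizon [0, 200] at step 0.02 (10,000 sampling points, ~2·10⁵
right-hand-side passes, well under a minute).

## The TNF-α apoptosis model

The 31-species, 29-parameter TNF-α signalling model with 20-minute delayed
transcription terms is referenced by the fixture API but not bundled: its
equations and nominal values exist only in supplementary material that this
package does not redistribute.  `tnf_model()` raises an error carrying
transcription instructions; once transcribed into the model-file format it
runs through the identical pipeline (semi-relative mode is the appropriate
choice there, since many concentrations start at zero).

## Known limitations

* Explicit fixed-point correction limits the method to non-stiff systems;
  the μ·ε ≥ 1 exit makes that boundary explicit rather than silent.
* μ = n(m+n)·max|aᵢⱼ| is a conservative norm bound; steps can be smaller
  than an error-per-step controller would choose, trading efficiency for
  simplicity and auditability.
* Linear history interpolation limits global order to two; no discontinuity
  tracking beyond the step cap at the smallest delay is performed.
* A failed corrector aborts the run rather than retrying with a smaller
  step, surfacing the location of the failure to the caller.
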