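# Methods

## Model

`ctdynet` models a p-variate process Y(t) as a first-order linear stochastic
differential equation (an Ornstein–Uhlenbeck process):

    dY(t)/dt = A (Y(t) − μ) + W(t)

The drift matrix `A` holds the direct moment-to-moment dependencies:
`A[j, i]` is the effect of variable i on the instantaneous rate of change of
variable j. Its off-diagonal pattern is a weighted local dependence graph —
the continuous-time network. Diagonal auto-effects are typically negative
(mean reversion); the process is stable iff every eigenvalue of `A` has
negative real part. `W(t)` is white noise with covariance rate `Q` (the
diffusion matrix). The default convention is centered data, μ = 0.

The integral form is the CT-VAR: for any pair of occasions separated by an
interval Δt,

    Y(t_τ) = e^{A Δt_τ} Y(t_{τ−1}) + ε(Δt_τ),   ε ~ N(0, Σ(Δt_τ)).

So the lagged (VAR) matrix at interval Δt is Φ(Δt) = e^{A Δt}, and a lag-one
VAR fitted to equally spaced data is the exact discretization of the CT model
at that interval. Because Φ(Δt) mixes all paths through the continuum of
latent intermediate states, any lagged parameter is a *total* effect; only
the drift entries are direct effects. This is the time-interval problem that
motivates the package: DT-VAR edge estimates and the centrality rankings
computed from them change with the sampling interval.

`Σ(Δt)` is taken as the standard OU discretization
`Γ − e^{AΔt} Γ e^{A'Δt}`, where Γ solves the continuous Lyapunov equation
`AΓ + ΓA' + Q = 0`. This choice is validated empirically in the test suite:
the covariance of simulated one-step transition errors at a fixed interval
matches `Σ(Δt)` within Monte-Carlo error, and for unstable drifts the
simulator falls back to the Van Loan block-exponential integral, which needs
no stationary distribution.

## Path-specific effects and centrality

All effects are expected-value contrasts under do-interventions on a linear
system, reported as functions of the time-interval:

* **Total effect** TE_{i→j}(Δt) = [e^{AΔt}]_{j,i}: the response of j to a
  unit pulse do(Y_i = 1) against the equilibrium baseline.
* **Direct effect** DE relative to a mediator set M: the same pulse while M
  is press-held at equilibrium. Operationally the drift is modified by
  zeroing every off-diagonal entry in the rows *and* columns of M (inputs to
  the mediators are severed; their clamped zero values contribute nothing),
  keeping the diagonal; DE is the corresponding entry of the modified matrix
  exponential. Zeroing full rows and columns — rather than only the entries
  on cause→mediator→effect paths — is the faithful rendering of "hold the
  mediators fixed" for arbitrary drift matrices; the two coincide whenever
  the remaining mediator entries are zero, as in the canonical 4-variable
  example. The arbiter is behavioral: a clamped RK4 integration of the
  *unmodified* drift with the mediator coordinates forcibly pinned at zero
  must reproduce DE, and does so to 1e−6 across random models in the tests.
* **Indirect effect** IE = TE − DE, exactly, by construction. A negative IE
  means the press *amplifies* the pulse's effect — the signature of a
  compensating negative feedback loop through the mediators.

Two interval-resolved centrality measures summarize these effects:

* **TEC_i(Δt) = Σ_{j≠i} TE_{i→j}(Δt)** ranks pulse targets. It is
  numerically identical to one-step expected influence computed on Φ(Δt)
  (asserted to 1e−12), which is why classical EI rankings inherit the
  interval dependence.
* **IEC_i(Δt) = Σ_{j≠k, j,k≠i} IE_{j→k | M={i}}(Δt)** ranks press targets;
  a node with negative IEC at short intervals should *not* be pressed —
  clamping it disables a stabilizing feedback.

The classical DT measures (EI1, EI2, out-strength, betweenness) are provided
for any lagged matrix. EI1 is the signed off-diagonal column sum; EI2 adds
the off-diagonal column sums of Φ² (note that as Δt → 0 this makes
EI2 → 3·EI1, since the lag-two sums approach twice the lag-one sums).
Betweenness uses the standard weighted-network convention: edge distance
1/|weight|, Dijkstra shortest paths, fractional counting of ties, self-loops
ignored, validated against exhaustive simple-path enumeration. Since the
classical literature specifies betweenness for lagged networks only loosely,
this convention choice is the main point where reasonable implementations
could differ.

## Interventions

Trajectories are expected values (noise averages out of a linear model).
A pulse from equilibrium follows e^{At} y₀. An indefinite press clamps the
target set S at values v; the free block relaxes along
`y(t) = e^{A_ff t}(y₀ − y*) + y*` toward the press equilibrium
`y* = −A_ff⁻¹ A_fs v`. Stability under a press is governed by the
eigenvalues of the free-subsystem block A_ff, not of A — pressing can
destabilize an otherwise stable system. Finite-duration presses (release
followed by unpressed dynamics) are supported as an extension and are off by
default. Press trajectories start from equilibrium unless an explicit
initial state is given. Every closed-form trajectory has an `rk4` route — a
classical fixed-step 4th-order integration with automatic step halving until
successive answers agree to 1e−8 — used as an independent oracle in tests.

## Estimation

The CT likelihood conditions on the first observation and factors over
consecutive fully observed pairs; pairs broken by missing values are dropped
listwise. Each pair contributes the exact Gaussian transition density with
mean e^{AΔt}y_prev and covariance Σ(Δt), so unequal intervals need no
special treatment and overnight gaps are naturally downweighted (Φ(Δt) ≈ 0
there). Parameters are unconstrained: p² drift entries plus a Cholesky
factor of Q with log-transformed diagonal; equilibria are handled by
centering the data at the sample means by default (optionally estimated as
free means). No correction is applied for the pre-standardization /
centering step when computing standard errors.

Unstable trial drifts are rejected through the likelihood (−∞, smoothed to
a large penalty inside the optimizer) rather than by hard constraints, so
the inverse numerical Hessian at the optimum is an undistorted covariance
estimate. Optimization is multi-start L-BFGS-B (default 10 starts): start 1
is warm — the principal matrix logarithm of the DT-OLS lagged matrix at the
median interval, with Q recovered through the discrete Lyapunov equation —
and the remaining starts are random perturbations given a short exploratory
budget, the winner being polished in full. In practice the warm start lands
in the basin of the global optimum for well-specified simulations, which is
why a small number of starts suffices in the simulation studies. Likelihood
evaluations compute every e^{AΔt} and the Lyapunov solution from a single
eigendecomposition of A (with a scipy `expm` fallback for nearly defective
drifts).

The DT-VAR baseline is per-equation OLS pooling *all* consecutive pairs
regardless of interval — deliberately reproducing the common practice the CT
model corrects. On mixed-interval data its estimate is a blend of the lagged
relations at the intervals present, matching neither Φ(median Δt) nor any
single-interval matrix; this qualitative behavior is asserted in the tests.

Uncertainty in any derived curve (Φ(Δt) entries, effect curves, TEC/IEC) is
propagated by resampling parameter vectors from N(θ̂, vcov) and taking
pointwise percentile bands; a fixed seed makes bands reproducible, and
non-PSD covariance estimates are repaired by eigenvalue clipping with a
warning.

## Synthetic data

The simulator draws from the exact transition density (first state from the
stationary distribution unless an initial state is given), so simulator
error never contaminates estimator checks on any grid. The ESM schedule
generator places a fixed number of beeps per day by stratified-uniform
placement inside a waking window (defaults: 239 days, 6 beeps/day, 13.5 h
window — a design whose interval distribution is right-skewed with an
overnight mode and a median interval of about two hours, matching published
single-subject ESM designs). It emulates the *timing* structure of ESM data
only: responses are continuous Gaussian, with no Likert discretization,
floors/ceilings, time-of-day effects, or informative missingness (only an
optional missing-completely-at-random drop fraction). Passing recovery tests
therefore demonstrate correctness of the likelihood machinery under the
model, not robustness to those real-data features.

Named fixtures: `chain3` (pure causal chain, closed-form effects),
`negfeedback4` (one node carries the network's only negative feedback loop,
giving it negative IEC at short intervals), and `stress_discomfort_partial`,
a 4-variable Stress/Anxiety/Self-Consciousness/Discomfort system in which
only four drift entries (−6, −2.5, −7.3, 0) follow the published worked
example; all other entries are synthetic fill-ins chosen once to make the
system stable and qualitatively faithful (exactly one sign switch in the
Anxiety→Discomfort lagged parameter; a negative feedback loop through
Discomfort). Entry provenance is recorded on the fixture, and the synthetic
entries are never used to assert published outputs.

## Numerical choices

* Symmetry/PSD tolerance for model matrices: 1e−8 relative; PSD eigenvalue
  floor −1e−10.
* Default Δt grid: 0–5 time units in steps of 0.05 (hours, by convention —
  the time unit is always declared, never guessed).
* Sign-switch detection: grid scan for adjacent sign changes, refined by
  bisection to a bracket of width 1e−4; curves are analytic so grid-adjacent
  brackets suffice at the default resolution.
* Matrix logarithm (DT→CT): principal branch only. Eigenvalues of Φ on the
  closed negative real axis mean no real CT representation exists (negative
  auto-regression); an imaginary residual above 1e−8 is reported as aliasing
  (several real drifts consistent with the same lagged matrix) rather than
  silently resolved.
* RK4 oracle: initial step 1e−2, halved (up to 8 times) until successive
  trajectories agree to 1e−8 in sup norm.
* Hessian for standard errors: central differences with relative step 1e−3.

## Problem sizes in the simulation studies

The recovery study uses a fixed hours-scale 4-variable drift (auto-effects
−0.6 to −0.9, cross-effects 0.1–0.3) with unit diffusion, observed on an
ESM schedule of 6 beeps/day in a 13.5-h window; series lengths are n = 2000
and n = 500, with 20 replications in the test suite and 10 in the
acceptance script. Drifts much faster than the sampling rate are
intentionally avoided there: modes that decay within a fraction of the
median interval are weakly identified from such designs (their Φ(Δt)
footprint is almost zero), which inflates standard errors without reflecting
an implementation defect. The scaled-down coverage and likelihood-dominance
checks use 2-variable systems for the same reason.

## Known limitations

* Single-subject, stationary, linear-Gaussian models only: no multilevel
  structure, time-varying parameters, measurement error/latent filtering, or
  nonlinear/multi-attractor dynamics.
* DT models with negative auto-regression have no real CT counterpart and
  are rejected at the matrix logarithm rather than handled.
* Press-intervention effects computed from observational fits inherit all
  causal caveats (modularity, no unobserved confounding, correct model);
  the package computes consequences of the fitted model, nothing more.
* The likelihood drops any transition pair with missingness; partial-row
  conditioning would use more information but is not implemented.
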