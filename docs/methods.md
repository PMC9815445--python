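# Methods

## Models

**Lotka-Volterra (LV).** `dX_i/dt = X_i (a_i + Σ_j b_ij X_j)`. `a_i` is a
per-time growth-rate constant; `b_ij` (per abundance per time) is the effect
of species j on species i, with `b_ii` the self-limitation (crowding) term.
The deterministic simulator integrates the ODE with adaptive RK45 at
rtol 1e-10 / atol 1e-12 — tight enough that the conservative predator-prey
cycles in the dynamics suite hold their amplitude to ~1e-5 over 500 time
units. Any state magnitude beyond 1e12 is treated as a blow-up and raised as
a `DivergenceError` carrying the last valid time, never returned as data.

**Process noise.** The stochastic LV simulator iterates the Euler map and
multiplies the *whole updated state*, per species and per step, by an
i.i.d. gamma(k, scale 1/(k−1)) factor:

    X_{t+h} = [X_t + h · X_t · (a + B X_t)] · g,   g ~ Gamma(k, 1/(k−1)).

The scale choice puts the factor's mode exactly at 1 (mode = (k−1)·scale),
so the perturbation is a small positive "environment multiplier" rather than
additive measurement error; it compounds across steps, which is what
distinguishes process from observational noise. Applying `g` to the whole
state (not just the increment) is deliberate: only then does the noise keep
fluctuating near a steady state, where the increment vanishes. A
`noise_on_increment` switch provides the alternative reading. Noise is drawn
independently per species; the factor's analytic sd is `sqrt(k)/(k−1)`
(≈0.01 at k = 10,000), and `shape_for_noise_sd` inverts that relation — the
high-noise variant solves sd = 0.03, giving k ≈ 1113. Note the sd implied by
k = 10,000 is ≈0.01, not 0.005; we treat k as the authoritative parameter
and document the mapping rather than forcing agreement. Euler overshoots
below zero are clipped at 0 and flagged in `Trajectory.clipped_steps` so
high-noise runs complete while flagged runs can be excluded from recovery
statistics.

**MAR(1).** `x_{t+1} = α + β x_t + w_t`, `w_t ~ MVN(0, δ)`. Values live in
model space; under the Gompertz interpretation they are log-abundances and
the synthetic-data layer exponentiates before presenting "observed"
abundances. No stationarity is imposed on β (free-run extrapolations may
legitimately explode; the 1e12 overflow guard reports where). Higher-order
lags are out of scope: MAR(1) is the standard choice in the ecological
literature and the memoryless form is the fair counterpart to an ODE.

**Steady-state equivalence.** Euler-discretizing LV at unit step and
dividing by the (positive) state shows LV and MAR share fixed-point
equations when `α = a`, `β = B + I` (off-diagonals equal, diagonals shifted
by one). `lv_to_mar_steady_map` implements the map; the identity
`mar_steady_state(map(p)) = lv_steady_state(p)` is exercised on random
nonsingular systems in the tests and the acceptance script.

## Estimation

**ALVI.** Dividing the LV equation by `X_i > 0` makes each species' equation
linear in `[a_i, b_i1 … b_in]` with response `s_i/X_i`, where slopes `s_i`
come from the smoothing spline. ALVI-LR solves each species' K×(n+1) system
by OLS; ALVI-MI solves exactly on n+1 points. Because each species' system
is independent, cost scales linearly in n, and permuting species permutes
the estimates. ALVI-MI systems with condition number above 1e10 are rejected
("insufficient datapoints or almost-linear dependence") with the condition
number reported rather than returning garbage. The subsample search draws
(n+1)-point subsets from a pool of spline samples (default: the distinct
observation times), scores each candidate by the SSE of the ODE integrated
from the first smoothed observation over the full window — one-step
objectives are not used for LV — and returns all candidates ranked, keeping
singular/diverging ones with infinite SSE and their failure reason.
Exhaustive enumeration is capped at 20,000 subsets, beyond which the seeded
Monte-Carlo strategy is forced. `refine_gradient` polishes a parameter set
by L-BFGS-B (numerically estimated gradients) on the trajectory SSE and
never returns something worse than its start.

**Smoothing splines.** Cubic smoothing splines parameterized by *effective
degrees of freedom* (trace of the linear smoother): df = 2 is the weighted
least-squares line, df = number of distinct times is the natural
interpolating spline. Internally the natural-spline roughness penalty K is
assembled from the Green–Silverman band matrices; df(λ) = Σ 1/(1 + λ·e_i)
with e_i the generalized eigenvalues of K against the weight matrix, and λ
is found by bisection on log λ (the two boundary cases are handled exactly).
The penalized minimizer is the natural cubic spline through the fitted knot
values, so the curve is reconstructed exactly with a natural-boundary cubic
interpolant; derivatives come from the spline's analytic derivative.
Replicates (duplicate times) enter as weighted per-time means — algebraically
identical to the joint penalized fit over all rows, so replication genuinely
weights the fit. Each species is smoothed independently with its own df; df
is a required modeling input (no automatic cross-validation), with 8 as the
package-wide default. Evaluation outside the fitted interval is refused:
extrapolated spline slopes are untrustworthy by construction.

**MAR estimation.** Conditional least squares: regress `x_{t+1}` on
`[1, x_t]` over all observed consecutive pairs; δ is the residual covariance
with denominator (pairs − parameters per equation), eigenvalue-clipped to
PSD. CLS is the exact Gaussian MLE for fully observed, equally spaced MAR(1)
without observation error, and it is closed-form and deterministic — a
state-space EM (with estimated observation error, constrained structures,
bootstrap intervals) is a possible extension point but is intentionally not
implemented; observation-error variance is fixed at zero and the
process-noise focus is carried entirely by δ (full symmetric by default).
Irregular observation times are snapped to the nearest multiple of the
scenario's step (MAR(1) is defined on a fixed step); only index-consecutive
pairs enter, so gaps simply contribute no pairs. Data handling applies, in
order: replicate averaging, replacement of exact zeros by 1e-5 (recorded;
only when a log transform is requested), log, optional spline smoothing
resampled at the observation times, optional z-scoring — all recorded in a
`TransformRecord` sufficient to map predictions back to abundance scale.
Free-run SSEs for MAR fits are computed after back-transformation, so all
methods are compared on the same scale. Prediction intervals propagate
`V_{t+1} = β V_t βᵀ + δ` from V_0 = 0 and report Gaussian quantiles of the
free-run mean.

## Synthetic benchmarks

The generators stand in for real community data and define the study
conditions; their defaults are hard-coded and version-pinned.

- **LV benchmark** (4 species): species 1–3 interact with mixed signs and
  settle at (1.2, 0.8, 1.5); species 4 is a decoupled logistic (zero row-4
  and column-4 cross-terms, K = 2) started at 0.05, far below its carrying
  capacity — a built-in probe for whether a method detects detachment, and a
  strongly non-linear trajectory that linear recursions struggle with. Grid:
  100 points over t ∈ [0, 10]. Noise: k = 10,000 (low) or sd 0.03 (high).
- **MAR benchmark** (4 species): dense β (16 nonzero entries, spectral
  radius 0.70), fixed point (1.5, 1.0, 2.0, 1.2) in log space so abundances
  stay positive, δ = 0.01·I, series length 31 — deliberately far below the
  sign-recovery rule 5 × nnz(β) = 80, making it the canonical short-series
  case.
- **Sampling**: "noisy" draws 40 random points (without replacement, order
  preserved) from the 100-point stochastic run; "replicate" harvests 15
  fixed times — local extrema of the noise-free course plus equispaced fill,
  endpoints always kept — from 5 independent stochastic runs, labelled by
  replicate.
- **Dynamics suite**: six noise-free LV systems (stable point, damped
  oscillation, limit-cycle convergence via an asymmetric rock-paper-scissors
  competition, conservative sustained oscillation, and two chaotic
  4-species competitive systems in the style of published chaotic LV
  parameter sets, rescaled ×10 in abundance and ×2–3 in time so that
  1e-6-perturbed twins separate beyond unit distance inside the t ≤ 500
  window). Each carries a fit window t ∈ [1, 100], extrapolation to t = 500,
  and five default slope-sample times. The regimes are verified by property
  tests (steady-state arrival, amplitude stability, twin divergence), not by
  specific attractor coordinates.
- **Initial-condition grid**: the steady state scaled elementwise by
  (0.001, 0.01, 0.1, 1.9, 10, 100).

A `ScenarioSpec` serializes to/from a plain dict (YAML/JSON-able) and, with
its seed, regenerates its dataset byte-identically.

What the generators do *not* emulate: observational (measurement) noise,
compositionality, zero inflation from detection limits, and irregular
real-world sampling cadences. Passing tests therefore demonstrate
correctness of the estimators under multiplicative process noise and the two
sampling schemes — not robustness to every artefact of field data.

## Evaluation harness

SSE is summed over observation rows (each replicate counts individually);
`normalized_sse` divides residuals by the species' observed mean to balance
species of different magnitudes; `tail_sse` restricts to the last five grid
points to ask whether a fit lands on the right steady regime. Sign flips
count entries with strictly opposite signs — zeros are sign-neutral — and
signs are compared via `sign()` products (a raw value product can underflow
for tiny coefficients). The Wilcoxon comparison is two-sided, drops zero
differences, and uses the exact null up to 25 nonzero pairs. The comparison
runner fits all six pipelines (alvi-lr, alvi-mi, mar, mar-log, mar-smooth,
mar-log-smooth), scores them against an *explicit* per-scenario reference
(sampled data or noise-free truth — never implicit), marks the per-row
minimum, records failures as infinite cells with reasons, and is bitwise
reproducible from its recorded seeds. The initial-condition sweep refits
every method after scaling the start away from the steady state and reports
SSE-vs-truth, tail SSE, and sign flips (the latter only where estimate and
generating system are commensurable).

## Numerical choices and limitations

- Default spline df = 8; default Monte-Carlo search size 200–300 subsets;
  benchmark problem sizes (100-point grids, 200 replicate fits in the
  sign-recovery experiment, 10^6 noise draws) are chosen so the full suite
  and the acceptance script each run in well under a few minutes.
- Every stochastic operation takes an explicit seed (`numpy`
  `default_rng`); derived seeds stay below 2^31.
- ALVI requires strictly positive abundances (the transformation divides by
  `X_i`); exact zeros are handled upstream by the recorded 1e-5 replacement.
- The CLS estimator is consistent but, unlike a state-space EM, cannot
  separate observation from process noise; on data with substantial
  measurement error δ will absorb both.
- Chaotic-regime inference is intrinsically fragile: sensitive dependence
  means even near-perfect parameter estimates diverge from the reference
  trajectory; the suite treats divergence as the property under test, not a
  failure.
- Real-data ingestion is generic (wide CSV; any window can be fitted by
  subsetting rows); no external datasets are bundled.
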