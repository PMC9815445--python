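# lvmar

Side-by-side **Lotka-Volterra (LV)** and **multivariate autoregressive
(MAR(1))** network inference from community abundance time series.

Ecologists and systems biologists routinely want the *interaction network* of
a mixed community — which species promotes or suppresses which — from nothing
but observed abundance trajectories. Two frameworks with very different
mathematics are used for this job:

- the LV system of ODEs
  `dX_i/dt = X_i (a_i + Σ_j b_ij X_j)`,
  whose coefficients `b_ij` are directed, signed interaction strengths, and
- the MAR(1) recursion
  `x_{t+1} = α + β x_t + w_t`, `w_t ~ MVN(0, δ)`,
  usually read on log-abundances (multispecies Gompertz competition), whose
  transition matrix `β` plays the same role and whose `δ` explicitly models
  process noise.

Though they look incomparable, the two families share their steady-state
equations: discretizing LV with Euler's method and dividing by the (positive)
state shows the fixed points coincide when `α = a` and `β = B + I`. This
package implements both simulators (including multiplicative gamma process
noise with mode exactly 1), both estimators, and an evaluation harness that
pits them against each other on synthetic benchmarks.

**LV estimation** uses slope-based algebraic inference (ALVI): smooth each
species with a cubic spline of chosen effective degrees of freedom, read off
values and slopes, and note that `s_i/X_i = a_i + Σ_j b_ij X_j` is *linear* in
the unknowns. Solve per species by least squares over many points (ALVI-LR)
or exactly on n+1 points (ALVI-MI), with a seeded Monte-Carlo search over
point subsets ranked by trajectory SSE and an optional quasi-Newton
refinement. **MAR estimation** uses conditional least squares over observed
consecutive pairs — the exact Gaussian MLE for a fully observed MAR(1) — with
the four standard data-handling variants (raw/log × unsmoothed/smoothed).

## Worked example

Compare all six methods on the two built-in 4-species benchmarks (an LV
system with a deliberately decoupled logistic species, and a dense-β MAR
system, both with process noise and 40-point random sampling):

```sh
$ lvmar compare --seed 7 --iters 200 --out cmp
             alvi-lr    alvi-mi         mar    mar-log  mar-smooth  mar-log-smooth
lv-noisy    4.260887   0.265806  199.739624  74.907196    0.749533        1.253396
mar-noisy  82.575508  16.019389   29.682146  31.506900   19.339103       19.632073
```

Each cell is the sum of squared errors between a method's fitted trajectory
and the sampled data; `cmp/sse_minima.csv` marks the per-row winner and
`cmp/manifest.json` records every seed and setting needed to regenerate the
table bit-for-bit. Here ALVI-MI wins both rows: the LV benchmark's decoupled
logistic species is strongly non-linear (hard for a linear recursion), and
with only 31 points the MAR benchmark sits far below the ~80-point
series-length rule for reliable sign recovery
(`min_series_length(β) = 5 × nnz(β) = 80`).

On noise-free data with exact slopes the algebraic inference is essentially
perfect:

```python
>>> import numpy as np
>>> from lvmar import *
>>> spec = make_lv_benchmark()
>>> truth = spec.lv_params
>>> traj = noise_free_trajectory(spec)
>>> idx = np.linspace(2, 80, 12).astype(int)
>>> X = traj.values[idx]
>>> slopes = X * (truth.growth_rates + X @ truth.interactions.T)
>>> est = alvi_lr(SlopePointSet(traj.times[idx], X, slopes))
>>> np.max(np.abs(est.interactions - truth.interactions))
8.104628079763643e-15
```

Other entry points: `lvmar generate` (benchmark datasets as wide CSV),
`lvmar fit-lv` / `lvmar fit-mar` (single fits on your own CSV, one `time`
column plus one column per species, optional `replicate` column),
`lvmar sweep` (refits after scaling the initial state away from the steady
state, reporting SSE, tail SSE, and sign-flip counts). Library API mirrors
the CLI one-to-one; see `docs/methods.md` for the model details and design
choices.

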