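"""Algebraic Lotka-Volterra Inference (ALVI).

Dividing the LV equation ``dX_i/dt = X_i (a_i + sum_j b_ij X_j)`` by the
(strictly positive) abundance turns each species' equation into a relation
that is *linear* in the unknown parameters:

    s_i(t) / X_i(t) = a_i + sum_j b_ij X_j(t)

where ``s_i`` is the slope, estimated from a smoothing spline.  Collecting K
sampled points gives a K x (n+1) linear system per species, solved either by
ordinary least squares over all points (ALVI-LR) or exactly on n+1 points
(ALVI-MI).  Because each species' system is independent, the method scales
linearly in the number of species.  A subsample search ranks candidate
(n+1)-point subsets by the SSE of the integrated trajectory, and an optional
quasi-Newton refinement polishes the best candidate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .models import (DivergenceError, LVParameters, SimulationGrid,
                     SingularMatrixError, Trajectory, simulate_lv_ode)
from .smoothing import (Dataset, SlopePointSet, SmoothedTrajectory,
                        eval_smooth, resample_spline)

__all__ = [
    "SlopePointSet",
    "FitResult",
    "CONDITION_LIMIT",
    "EXHAUSTIVE_CAP",
    "build_regression_system",
    "alvi_lr",
    "alvi_mi",
    "subsample_search",
    "refine_gradient",
]

#: ALVI-MI systems with condition number beyond this are rejected as
#: near-singular ("insufficient datapoints or almost-linear dependence").
CONDITION_LIMIT = 1e10

#: Above this many candidate subsets, exhaustive search is refused and the
#: Monte-Carlo strategy is forced.
EXHAUSTIVE_CAP = 20_000


@dataclass
class FitResult:
    """An estimated model with its predicted trajectory and SSE bookkeeping."""

    method: str
    parameters: object | None
    predicted: Trajectory | None
    sse_per_species: np.ndarray | None
    sse_total: float
    settings: dict = field(default_factory=dict)
    failure: str | None = None

    def __post_init__(self):
        if self.sse_per_species is not None:
            total = float(np.sum(self.sse_per_species))
            if np.isfinite(self.sse_total) and not math.isclose(
                    total, self.sse_total, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("sse_total must equal the sum of sse_per_species")


def build_regression_system(points: SlopePointSet, species_index: int):
    """Design matrix and response of one species' linearized LV equation.

    Rows are ``[1, X_1(t), ..., X_n(t)]``; the response is ``s_i(t)/X_i(t)``;
    the unknowns are ``[a_i, b_i1, ..., b_in]``.
    """
    values = points.values
    bad = np.argwhere(values <= 0)
    if bad.size:
        p, j = bad[0]
        raise ValueError(
            f"non-positive abundance at point {p} (t={points.times[p]:g}, "
            f"species {points.species[j]!r}): ALVI requires X > 0")
    design = np.column_stack([np.ones(points.n_points), values])
    response = points.slopes[:, species_index] / values[:, species_index]
    return design, response


def alvi_lr(points: SlopePointSet) -> LVParameters:
    """ALVI by multivariate linear regression: OLS per species equation."""
    n = points.n_species
    if points.n_points < n + 1:
        raise ValueError(f"need at least {n + 1} points for {n} species")
    a = np.empty(n)
    B = np.empty((n, n))
    for i in range(n):
        design, response = build_regression_system(points, i)
        coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
        if rank < n + 1:
            raise SingularMatrixError(
                f"rank-deficient regression design (rank {rank} < {n + 1}); "
                "supply more, or more varied, sample points", rank=int(rank))
        a[i], B[i] = coef[0], coef[1:]
    return LVParameters(growth_rates=a, interactions=B)


def alvi_mi(points: SlopePointSet) -> LVParameters:
    """ALVI by matrix inversion: exact solve on exactly n+1 points."""
    n = points.n_species
    if points.n_points != n + 1:
        raise ValueError(f"ALVI-MI needs exactly {n + 1} points for {n} species")
    a = np.empty(n)
    B = np.empty((n, n))
    for i in range(n):
        design, response = build_regression_system(points, i)
        cond = np.linalg.cond(design)
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise SingularMatrixError(
                f"ALVI-MI system is singular or near-singular (condition "
                f"number {cond:.3g}): insufficient datapoints or "
                "almost-linear dependence", condition_number=float(cond))
        coef = np.linalg.solve(design, response)
        a[i], B[i] = coef[0], coef[1:]
    return LVParameters(growth_rates=a, interactions=B)


def _trajectory_sse(params: LVParameters, eval_times: np.ndarray,
                    x0: np.ndarray, ref_times: np.ndarray,
                    ref_values: np.ndarray) -> tuple[float, Trajectory | None, str | None]:
    """Integrate from x0 over eval_times; SSE against the reference rows."""
    grid = SimulationGrid.over_span(eval_times[0], eval_times[-1],
                                    max(eval_times.size, 2))
    try:
        traj = simulate_lv_ode(params, x0, grid)
    except DivergenceError as exc:
        return np.inf, None, f"divergence: {exc}"
    # reference rows may repeat times (replicates); interpolate predictions
    pred = np.column_stack([
        np.interp(ref_times, traj.times, traj.values[:, j])
        for j in range(traj.n_species)])
    resid = pred - ref_values
    return float(np.nansum(resid ** 2)), traj, None


def _reference_series(objective: str, data: Dataset,
                      smoothed: SmoothedTrajectory,
                      truth: Trajectory | None):
    if objective == "data":
        return data.times, data.values
    if objective == "smooth":
        values, _ = eval_smooth(smoothed, data.times)
        return data.times, values
    if objective == "truth":
        if truth is None:
            raise ValueError("objective 'truth' requires a noise-free trajectory")
        return truth.times, truth.values
    raise ValueError(f"unknown objective {objective!r}")


def subsample_search(smoothed: SmoothedTrajectory, data: Dataset,
                     strategy: Literal["exhaustive", "monte_carlo"] = "monte_carlo",
                     n_iter: int = 300, seed: int | None = None,
                     objective: Literal["data", "smooth", "truth"] = "data",
                     truth: Trajectory | None = None,
                     pool: SlopePointSet | None = None) -> list[FitResult]:
    """Rank (n+1)-point ALVI-MI candidates by integrated-trajectory SSE.

    The candidate pool defaults to the spline resampled at the distinct
    observation times.  Each candidate subset is solved with ALVI-MI, the LV
    ODE is integrated from the first smoothed observation, and the SSE against
    the chosen reference (raw data | smoothed trend | noise-free truth) is
    recorded.  Singular or diverging candidates receive infinite SSE and are
    retained with their failure reason.
    """
    if pool is None:
        pool_times = np.unique(data.times)
        lo, hi = smoothed.fit_interval
        pool_times = pool_times[(pool_times >= lo) & (pool_times <= hi)]
        pool = resample_spline(smoothed, times=pool_times)
    if pool.n_points == 0:
        raise ValueError("empty candidate pool")
    n = pool.n_species
    size = n + 1
    if pool.n_points < size:
        raise ValueError("candidate pool smaller than n+1")

    n_total = math.comb(pool.n_points, size)
    if strategy == "exhaustive" and n_total > EXHAUSTIVE_CAP:
        strategy = "monte_carlo"
    if strategy == "exhaustive":
        subsets = list(itertools.combinations(range(pool.n_points), size))
    else:
        if seed is None:
            raise ValueError("monte_carlo search requires a seed")
        rng = np.random.default_rng(seed)
        seen = set()
        subsets = []
        for _ in range(n_iter):
            cand = tuple(sorted(rng.choice(pool.n_points, size, replace=False)))
            if cand not in seen:
                seen.add(cand)
                subsets.append(cand)

    ref_times, ref_values = _reference_series(objective, data, smoothed, truth)
    x0, _ = eval_smooth(smoothed, [data.times.min()])
    results = []
    for subset in subsets:
        settings = {"subset_times": pool.times[list(subset)].tolist(),
                    "objective": objective, "seed": seed,
                    "df": smoothed.degrees_of_freedom.tolist()}
        try:
            params = alvi_mi(pool.subset(list(subset)))
        except (SingularMatrixError, ValueError) as exc:
            results.append(FitResult("alvi-mi", None, None, None, np.inf,
                                     settings, failure=str(exc)))
            continue
        sse, traj, failure = _trajectory_sse(params, ref_times, x0[0],
                                             ref_times, ref_values)
        per_species = None
        if traj is not None:
            pred = np.column_stack([
                np.interp(ref_times, traj.times, traj.values[:, j])
                for j in range(traj.n_species)])
            per_species = np.nansum((pred - ref_values) ** 2, axis=0)
        results.append(FitResult("alvi-mi", params, traj, per_species, sse,
                                 settings, failure=failure))
    results.sort(key=lambda r: (not np.isfinite(r.sse_total), r.sse_total))
    return results


def refine_gradient(start: LVParameters, data: Dataset,
                    objective: Literal["data", "smooth", "truth"] = "data",
                    smoothed: SmoothedTrajectory | None = None,
                    truth: Trajectory | None = None,
                    x0: np.ndarray | None = None,
                    maxiter: int = 200) -> LVParameters:
    """Polish LV parameters by local minimization of the trajectory SSE.

    Gradients are estimated numerically inside a quasi-Newton line search
    (L-BFGS-B).  The returned parameters never score worse than the input;
    a non-finite starting SSE is an error.
    """
    n = start.n_species
    if objective == "smooth" and smoothed is None:
        raise ValueError("objective 'smooth' requires the smoothed trajectory")
    if smoothed is not None:
        ref_times, ref_values = _reference_series(objective, data, smoothed, truth)
        start_x0 = eval_smooth(smoothed, [data.times.min()])[0][0]
    else:
        ref_times, ref_values = _reference_series(
            objective, data, smoothed, truth) if objective == "truth" else (
            data.times, data.values)
        start_x0 = data.values[np.argmin(data.times)]
    if x0 is not None:
        start_x0 = np.asarray(x0, dtype=float)

    def unpack(theta):
        return LVParameters(growth_rates=theta[:n],
                            interactions=theta[n:].reshape(n, n))

    def loss(theta):
        sse, _, _ = _trajectory_sse(unpack(theta), ref_times, start_x0,
                                    ref_times, ref_values)
        return sse if np.isfinite(sse) else 1e18

    theta0 = np.concatenate([start.growth_rates, start.interactions.ravel()])
    sse0 = loss(theta0)
    if sse0 >= 1e18:
        raise ValueError("objective SSE is not finite at the starting parameters")
    res = minimize(loss, theta0, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return unpack(res.x) if res.fun <= sse0 else start
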