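"""Spline smoothing of (possibly replicated) abundance time series.

Each species is smoothed independently with a cubic smoothing spline whose
flexibility is specified as *effective degrees of freedom* (df): the trace of
the linear smoother matrix.  df = 2 is the weighted least-squares line,
df = (number of distinct times) is the natural interpolating spline.  The
penalized criterion is

    sum_i w_i (y_i - f(t_i))^2 + lambda * integral f''(t)^2 dt

over the unique observation times; replicate observations at the same time
enter as weights on the pooled mean, which yields exactly the same minimizer
as the joint fit over all rows.  Smoothed curves expose values and first
derivatives, the raw material for slope-based LV inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = [
    "Dataset",
    "SmoothedTrajectory",
    "SlopePointSet",
    "fit_spline",
    "eval_smooth",
    "resample_spline",
    "average_replicates",
]


@dataclass(frozen=True)
class Dataset:
    """Observed abundance series: times, values, optional replicate labels.

    ``values`` is (n_obs, n_species) with NaN marking missing entries.  Within
    each replicate, times must be strictly increasing; across replicates the
    same times typically recur.
    """

    times: np.ndarray
    values: np.ndarray
    species: tuple[str, ...] = ()
    replicate: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != t.size:
            raise ValueError("values must have one row per time point")
        species = tuple(self.species) or tuple(f"X{i + 1}" for i in range(v.shape[1]))
        if len(species) != v.shape[1]:
            raise ValueError("species labels must match the number of columns")
        rep = self.replicate
        if rep is not None:
            rep = np.asarray(rep)
            if rep.size != t.size:
                raise ValueError("replicate labels must match the number of rows")
        groups = [np.arange(t.size)] if rep is None else [
            np.flatnonzero(rep == r) for r in pd.unique(rep)]
        for idx in groups:
            if np.any(np.diff(t[idx]) <= 0):
                raise ValueError("times must be strictly increasing within a replicate")
        for j, name in enumerate(species):
            if np.sum(np.isfinite(v[:, j])) < 2:
                raise ValueError(f"species {name!r} has fewer than 2 observed points")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "replicate", rep)

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.species))
        df.insert(0, "time", self.times)
        if self.replicate is not None:
            df.insert(1, "replicate", self.replicate)
        return df


@dataclass(frozen=True)
class SlopePointSet:
    """Paired (value, slope) samples used by the algebraic LV inference."""

    times: np.ndarray
    values: np.ndarray
    slopes: np.ndarray
    species: tuple[str, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        s = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        if v.shape[0] == 1 and t.size > 1:
            v, s = v.T, s.T
        if v.shape != s.shape or v.shape[0] != t.size:
            raise ValueError("values and slopes must share shape (n_points, n_species)")
        species = tuple(self.species) or tuple(f"X{i + 1}" for i in range(v.shape[1]))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "slopes", s)
        object.__setattr__(self, "species", species)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "SlopePointSet":
        idx = np.asarray(idx)
        return SlopePointSet(self.times[idx], self.values[idx],
                             self.slopes[idx], self.species)


@dataclass(frozen=True)
class SmoothedTrajectory:
    """Per-species smooth curves with their effective degrees of freedom."""

    splines: tuple
    degrees_of_freedom: np.ndarray
    fit_interval: tuple[float, float]
    species: tuple[str, ...]
    fitted_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_species(self) -> int:
        return len(self.splines)


def _pooled_unique(times: np.ndarray, y: np.ndarray):
    """Pool replicates: unique times, per-time means, replicate counts."""
    mask = np.isfinite(y)
    t, y = times[mask], y[mask]
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    ut, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    means = np.bincount(inverse, weights=y) / counts
    return ut, means, counts.astype(float)


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Green-Silverman natural-spline roughness penalty K (integral f''^2)."""
    n = x.size
    h = np.diff(x)
    delta = np.zeros((n - 2, n))
    for i in range(n - 2):
        delta[i, i] = 1.0 / h[i]
        delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        delta[i, i + 2] = 1.0 / h[i + 1]
    W2 = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W2[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W2[i, i + 1] = W2[i + 1, i] = h[i + 1] / 6.0
    return delta.T @ np.linalg.solve(W2, delta)


def _df_for_lambda(eigs: np.ndarray, lam: float) -> float:
    return float(np.sum(1.0 / (1.0 + lam * eigs)))


def _fit_one_species(t: np.ndarray, y: np.ndarray, w: np.ndarray, df: float):
    """Smoothing spline at the requested effective df (trace of smoother)."""
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 distinct time points for a cubic fit")
    if not 2 <= df <= n:
        raise ValueError(f"degrees of freedom must lie in [2, {n}], got {df}")
    if df >= n - 1e-8:
        fitted = y.copy()
    elif df <= 2 + 1e-8:
        # lambda -> infinity limit: the weighted least-squares line
        X = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                   y * np.sqrt(w), rcond=None)
        fitted = X @ coef
    else:
        K = _penalty_matrix(t)
        Wc = 1.0 / np.sqrt(w)
        # df(lam) = tr[(W + lam K)^{-1} W] = sum 1/(1 + lam * eig_i(W^-1/2 K W^-1/2))
        eigs = np.linalg.eigvalsh(Wc[:, None] * K * Wc[None, :])
        eigs = np.maximum(eigs, 0.0)

        def gap(log_lam):
            return _df_for_lambda(eigs, 10.0 ** log_lam) - df

        lo, hi = -14.0, 14.0
        while gap(lo) < 0 and lo > -300:
            lo -= 10
        while gap(hi) > 0 and hi < 300:
            hi += 10
        log_lam = brentq(gap, lo, hi, xtol=1e-12)
        lam = 10.0 ** log_lam
        fitted = np.linalg.solve(np.diag(w) + lam * K, w * y)
    # the penalized minimizer is the natural cubic spline through the fitted
    # knot values, so interpolating them reproduces it exactly
    return CubicSpline(t, fitted, bc_type="natural"), fitted


def fit_spline(data: Dataset, df) -> SmoothedTrajectory:
    """Smooth each species with a cubic spline of the given effective df.

    ``df`` is a scalar (shared) or per-species sequence.  Replicate rows all
    enter the penalized criterion (as weights on pooled per-time means, which
    is algebraically the same fit).
    """
    dfs = np.broadcast_to(np.asarray(df, dtype=float), (data.n_species,)).copy()
    splines, fitted_cols, intervals = [], [], []
    times_ref = None
    for j in range(data.n_species):
        t, ybar, w = _pooled_unique(data.times, data.values[:, j])
        spline, _ = _fit_one_species(t, ybar, w, dfs[j])
        splines.append(spline)
        intervals.append((t[0], t[-1]))
        if times_ref is None or t.size > times_ref.size:
            times_ref = t
    lo = max(i[0] for i in intervals)
    hi = min(i[1] for i in intervals)
    return SmoothedTrajectory(splines=tuple(splines), degrees_of_freedom=dfs,
                              fit_interval=(lo, hi), species=data.species,
                              fitted_times=times_ref)


def eval_smooth(smoothed: SmoothedTrajectory, times):
    """Evaluate curve values and first derivatives at ``times``.

    Extrapolation requests raise: slopes outside the fitted window are
    untrustworthy by construction.
    """
    t = np.asarray(times, dtype=float).ravel()
    lo, hi = smoothed.fit_interval
    eps = 1e-9 * max(1.0, abs(hi - lo))
    if np.any(t < lo - eps) or np.any(t > hi + eps):
        raise ValueError(
            f"requested times outside the fit interval [{lo:g}, {hi:g}]")
    values = np.column_stack([s(t) for s in smoothed.splines])
    slopes = np.column_stack([s.derivative()(t) for s in smoothed.splines])
    return values, slopes


def resample_spline(smoothed: SmoothedTrajectory, times=None,
                    count: int | None = None) -> SlopePointSet:
    """Sample the smoothed curves (values + slopes) at given times or count.

    Requesting ``count`` yields that many equispaced times across the fit
    interval.
    """
    if (times is None) == (count is None):
        raise ValueError("provide exactly one of times or count")
    if times is None:
        times = np.linspace(*smoothed.fit_interval, count)
    t = np.asarray(times, dtype=float).ravel()
    values, slopes = eval_smooth(smoothed, t)
    return SlopePointSet(times=t, values=values, slopes=slopes,
                         species=smoothed.species)


def average_replicates(data: Dataset) -> Dataset:
    """Collapse replicates: one row per distinct time, per-species means.

    Missing entries are excluded from each mean; a time observed in only one
    replicate passes through unchanged.
    """
    frame = data.to_frame().drop(columns="replicate", errors="ignore")
    averaged = frame.groupby("time", sort=True).mean()
    return Dataset(times=averaged.index.to_numpy(),
                   values=averaged.to_numpy(), species=data.species)
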