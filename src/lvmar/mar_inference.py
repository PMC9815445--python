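"""MAR(1) estimation with the four data-handling variants.

Fits the recursion ``x_{t+1} = alpha + beta x_t + w_t`` by conditional least
squares (CLS): each species' next value is regressed on an intercept and the
full current state, over every observed consecutive pair.  CLS is the exact
Gaussian maximum-likelihood estimator for a fully observed, equally spaced
MAR(1) with no observation error; the process-noise covariance ``delta`` is
the residual covariance with a degrees-of-freedom-corrected denominator.
Gaps in the series simply contribute no pairs.  (An EM estimator over a
state-space form is a possible extension; the interface leaves room for it
but only CLS is implemented.)

Data handling mirrors common ecological practice: replicate averaging, a
recorded replacement of exact zeros before a log transform (the Gompertz
reading works on log-abundances), optional spline smoothing, and optional
z-scoring.  Every transform is recorded so predictions can be mapped back to
the abundance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.stats import norm

from .models import MARParameters, SingularMatrixError, Trajectory
from .smoothing import Dataset, average_replicates, eval_smooth, fit_spline

__all__ = [
    "TransformRecord",
    "prepare_transform",
    "fit_mar",
    "predict_mar",
    "back_transform",
    "prediction_interval",
]

DEFAULT_ZERO_REPLACEMENT = 1e-5


@dataclass(frozen=True)
class TransformRecord:
    """Everything applied to the data before a MAR fit, enough to invert it.

    The zero replacement is lossy (original zeros are gone) and is therefore
    recorded rather than inverted.
    """

    log_applied: bool = False
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT
    zscore_applied: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    smoothing_df: np.ndarray | None = None


def prepare_transform(data: Dataset, log: bool = False,
                      zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
                      smooth_df=None, zscore: bool = False
                      ) -> tuple[Dataset, TransformRecord]:
    """Apply, in order: replicate averaging, zero replacement, log,
    smoothing (resampled at the observation times), z-scoring.

    Returns the transformed dataset and a :class:`TransformRecord` describing
    exactly what was applied.
    """
    out = average_replicates(data) if data.replicate is not None else data
    values = out.values.copy()
    if log:
        if np.nanmin(values) < 0:
            raise ValueError("log transform requested but data contain "
                             "negative abundances")
        values = np.where(values == 0, zero_replacement, values)
        values = np.log(values)
    smoothing_df = None
    if smooth_df is not None:
        smoothing_df = np.broadcast_to(
            np.asarray(smooth_df, dtype=float), (out.n_species,)).copy()
        smoothed = fit_spline(Dataset(out.times, values, out.species),
                              smoothing_df)
        values, _ = eval_smooth(smoothed, out.times)
    means = sds = None
    if zscore:
        means = np.nanmean(values, axis=0)
        sds = np.nanstd(values, axis=0, ddof=0)
        if np.any(sds == 0):
            raise ValueError("cannot z-score a constant species column")
        values = (values - means) / sds
    record = TransformRecord(log_applied=log, zero_replacement=zero_replacement,
                             zscore_applied=zscore, means=means, sds=sds,
                             smoothing_df=smoothing_df)
    return Dataset(out.times, values, out.species), record


def _grid_indices(times: np.ndarray, step: float | None = None):
    """Snap observation times to the nearest integer multiple of the grid step."""
    if step is None:
        diffs = np.diff(np.unique(times))
        diffs = diffs[diffs > 0]
        if diffs.size == 0:
            raise ValueError("need at least two distinct times")
        step = float(np.min(diffs))
    idx = np.rint((times - times.min()) / step).astype(int)
    return idx, step


def fit_mar(data: Dataset, step: float | None = None) -> MARParameters:
    """Conditional least squares on all observed consecutive pairs.

    ``step`` is the recursion's time unit; by default the smallest positive
    spacing in the data.  Observations are snapped to the nearest integer
    grid index, and only index-consecutive pairs enter the regression.
    """
    if data.replicate is not None:
        data = average_replicates(data)
    n = data.n_species
    idx, step = _grid_indices(data.times, step)
    order = np.argsort(idx)
    idx, values = idx[order], data.values[order]
    complete = np.all(np.isfinite(values), axis=1)
    pair_mask = (np.diff(idx) == 1) & complete[:-1] & complete[1:]
    X = values[:-1][pair_mask]
    Y = values[1:][pair_mask]
    n_pairs = X.shape[0]
    if n_pairs < n + 2:
        raise ValueError(
            f"need at least {n + 2} consecutive-pair observations for "
            f"{n} species, found {n_pairs}")
    design = np.column_stack([np.ones(n_pairs), X])
    rank = np.linalg.matrix_rank(design)
    if rank < n + 1:
        raise SingularMatrixError(
            f"collinear CLS design (rank {rank} < {n + 1}); the series does "
            "not separate intercept from lagged state", rank=int(rank))
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    alpha, beta = coef[0], coef[1:].T
    resid = Y - design @ coef
    dof = max(n_pairs - (n + 1), 1)
    delta = resid.T @ resid / dof
    delta = 0.5 * (delta + delta.T)
    # guard against tiny negative eigenvalues from exactly-fitting data
    w, V = np.linalg.eigh(delta)
    delta = V @ np.diag(np.maximum(w, 0.0)) @ V.T
    return MARParameters(intercepts=alpha, transition=beta,
                         process_covariance=0.5 * (delta + delta.T))


def predict_mar(params: MARParameters, data: Dataset,
                mode: Literal["free_run", "one_step"] = "free_run",
                step: float | None = None) -> Trajectory:
    """Noise-free MAR predictions on the data's snapped grid.

    ``free_run`` iterates the recursion from the first observation over the
    full index range; ``one_step`` predicts each observed state from the
    previous observation (undefined where the predecessor index is absent,
    in which case the last available state is propagated forward).
    """
    if data.replicate is not None:
        data = average_replicates(data)
    if data.n_species != params.n_species:
        raise ValueError("dataset and parameters disagree on species count")
    idx, step = _grid_indices(data.times, step)
    order = np.argsort(idx)
    idx, values = idx[order], data.values[order]
    alpha, beta = params.intercepts, params.transition
    t0 = data.times.min()
    full_idx = np.arange(idx.max() + 1)
    if mode == "free_run":
        out = np.empty((full_idx.size, params.n_species))
        out[0] = values[0]
        for i in range(1, full_idx.size):
            out[i] = alpha + beta @ out[i - 1]
        return Trajectory(times=t0 + step * full_idx, values=out)
    if mode == "one_step":
        obs = {int(i): v for i, v in zip(idx, values)}
        out = np.empty((full_idx.size, params.n_species))
        out[0] = values[0]
        prev = values[0]
        for i in range(1, full_idx.size):
            prev = obs.get(i - 1, prev)
            out[i] = alpha + beta @ prev
        return Trajectory(times=t0 + step * full_idx, values=out)
    raise ValueError(f"unknown mode {mode!r}")


def back_transform(traj: Trajectory, record: TransformRecord) -> Trajectory:
    """Invert z-scoring, then exponentiate if a log transform was applied."""
    values = traj.values.copy()
    if record.zscore_applied:
        if record.means is None or record.sds is None:
            raise ValueError("incomplete transform record: z-scoring applied "
                             "but means/sds missing")
        values = values * record.sds + record.means
    if record.log_applied:
        values = np.exp(values)
    return Trajectory(times=traj.times, values=values, species=traj.species)


def prediction_interval(params: MARParameters, traj: Trajectory,
                        level: float = 0.95):
    """Gaussian intervals for the free-run mean with propagated variance.

    Variance recursion: ``V_{t+1} = beta V_t beta' + delta`` with ``V_0 = 0``
    at the (known) initial state.  Returns (lower, upper) arrays shaped like
    ``traj.values``.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    beta, delta = params.transition, params.process_covariance
    eigs = np.linalg.eigvalsh(0.5 * (delta + delta.T))
    if eigs.min() < -1e-10 * max(1.0, abs(eigs).max()):
        raise ValueError("process covariance must be positive semi-definite")
    z = norm.ppf(0.5 + level / 2.0)
    n_t = traj.times.size
    half = np.zeros((n_t, params.n_species))
    V = np.zeros_like(delta)
    for i in range(1, n_t):
        V = beta @ V @ beta.T + delta
        half[i] = z * np.sqrt(np.maximum(np.diag(V), 0.0))
    return traj.values - half, traj.values + half
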