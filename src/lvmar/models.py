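"""Lotka-Volterra and MAR(1) community models.

Parameterizations, simulators (deterministic and with multiplicative gamma
process noise), steady states, and the Euler-discretization mapping that makes
the two frameworks comparable at steady state.

The LV model is the system of ODEs

    dX_i/dt = X_i * (a_i + sum_j b_ij X_j)

with growth-rate constants ``a_i`` (per time) and interaction coefficients
``b_ij`` (per abundance per time).  The MAR(1) model is the linear recursion

    x_{t+1} = alpha + beta @ x_t + w_t,      w_t ~ MVN(0, delta)

usually read on log-abundances (Gompertz density dependence).  Although the
two look incomparable, an Euler discretization of LV divided through by the
(positive, near-steady) state shows both satisfy the same steady-state
equations when ``alpha = a`` and ``beta = B + I`` on the diagonal and
``beta_ij = b_ij`` off it; :func:`lv_to_mar_steady_map` implements that map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OVERFLOW_BOUND",
    "LVParameters",
    "MARParameters",
    "SimulationGrid",
    "NoiseSpec",
    "Trajectory",
    "DivergenceError",
    "SingularMatrixError",
    "simulate_lv_ode",
    "simulate_lv_discrete",
    "draw_process_noise",
    "shape_for_noise_sd",
    "simulate_mar",
    "lv_steady_state",
    "mar_steady_state",
    "lv_to_mar_steady_map",
]

#: Any state magnitude beyond this is treated as a blow-up, not a trajectory.
OVERFLOW_BOUND = 1e12


class DivergenceError(RuntimeError):
    """A simulation left the representable regime (blow-up or NaN).

    Carries ``last_valid_time`` (ODE path) or ``step_index`` (discrete path)
    so callers can report where the system exploded.
    """

    def __init__(self, message: str, *, last_valid_time: float | None = None,
                 step_index: int | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time
        self.step_index = step_index


class SingularMatrixError(np.linalg.LinAlgError):
    """A linear solve failed: singular or numerically rank-deficient matrix."""

    def __init__(self, message: str, *, rank: int | None = None,
                 condition_number: float | None = None):
        super().__init__(message)
        self.rank = rank
        self.condition_number = condition_number


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _as_square(m, n: int, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(m, dtype=float))
    if arr.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class LVParameters:
    """Growth rates ``a`` and interaction matrix ``B`` of an LV system."""

    growth_rates: np.ndarray
    interactions: np.ndarray

    def __post_init__(self):
        a = _as_1d(self.growth_rates, "growth_rates")
        B = _as_square(self.interactions, a.size, "interactions")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(B))):
            raise ValueError("LV parameters must be finite")
        object.__setattr__(self, "growth_rates", a)
        object.__setattr__(self, "interactions", B)

    @property
    def n_species(self) -> int:
        return self.growth_rates.size


@dataclass(frozen=True)
class MARParameters:
    """Intercepts ``alpha``, transition matrix ``beta``, noise covariance ``delta``.

    No stationarity requirement is imposed: the spectral radius of ``beta``
    may exceed 1 (transients and exploding free runs are legitimate regimes).
    """

    intercepts: np.ndarray
    transition: np.ndarray
    process_covariance: np.ndarray | None = None

    def __post_init__(self):
        alpha = _as_1d(self.intercepts, "intercepts")
        beta = _as_square(self.transition, alpha.size, "transition")
        delta = self.process_covariance
        if delta is None:
            delta = np.zeros((alpha.size, alpha.size))
        delta = _as_square(delta, alpha.size, "process_covariance")
        if not np.allclose(delta, delta.T, atol=1e-10):
            raise ValueError("process_covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(0.5 * (delta + delta.T))
        if eigvals.min() < -1e-10 * max(1.0, abs(eigvals).max()):
            raise ValueError("process_covariance must be positive semi-definite")
        object.__setattr__(self, "intercepts", alpha)
        object.__setattr__(self, "transition", beta)
        object.__setattr__(self, "process_covariance", delta)

    @property
    def n_species(self) -> int:
        return self.intercepts.size


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid: ``n_steps`` steps of size ``step`` from ``start_time``.

    The grid carries ``n_steps + 1`` time points (including the start).
    """

    start_time: float = 0.0
    step: float = 1.0
    n_steps: int = 99

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.step * np.arange(self.n_steps + 1)

    @classmethod
    def over_span(cls, t0: float, t1: float, n_points: int = 100) -> "SimulationGrid":
        """Grid of ``n_points`` equispaced points spanning [t0, t1]."""
        if n_points < 2:
            raise ValueError("need at least two points")
        return cls(start_time=t0, step=(t1 - t0) / (n_points - 1), n_steps=n_points - 1)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative gamma process noise: per-step factor ~ Gamma(k, 1/(k-1)).

    The scale 1/(k-1) puts the gamma's mode exactly at 1, so the factor is a
    small positive perturbation around no change.  ``shape`` may be a scalar
    (shared k) or a per-species vector.  Requires k > 1 (the scale is
    undefined otherwise).
    """

    shape: float | np.ndarray = 10_000.0
    enabled: bool = True

    def __post_init__(self):
        k = np.asarray(self.shape, dtype=float)
        if np.any(k <= 1):
            raise ValueError("gamma shape must exceed 1 (scale 1/(k-1) undefined)")
        object.__setattr__(self, "shape", k if k.ndim else float(k))

    def per_species(self, n: int) -> np.ndarray:
        k = np.asarray(self.shape, dtype=float)
        return np.broadcast_to(k, (n,)).astype(float)


@dataclass(frozen=True)
class Trajectory:
    """A simulated or predicted multi-species time course."""

    times: np.ndarray
    values: np.ndarray
    species: tuple[str, ...] = ()
    #: indices of steps where a deterministic Euler overshoot below zero was
    #: clipped to 0 (empty for clean runs); flagged trajectories should be
    #: excluded from parameter-recovery statistics.
    clipped_steps: tuple[int, ...] = ()

    def __post_init__(self):
        t = _as_1d(self.times, "times")
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != t.size:
            raise ValueError("values must have one row per time point")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trajectory values must be finite")
        species = tuple(self.species) or tuple(f"X{i + 1}" for i in range(v.shape[1]))
        if len(species) != v.shape[1]:
            raise ValueError("species labels must match the number of columns")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "clipped_steps", tuple(self.clipped_steps))

    @property
    def n_species(self) -> int:
        return self.values.shape[1]


def lv_rhs(params: LVParameters):
    """Right-hand side ``f(t, x)`` of the LV ODE, for integrators."""
    a, B = params.growth_rates, params.interactions

    def f(t, x):
        return x * (a + B @ x)

    return f


def simulate_lv_ode(params: LVParameters, x0, grid: SimulationGrid,
                    rtol: float = 1e-10, atol: float = 1e-12) -> Trajectory:
    """Integrate the LV ODE on ``grid`` with an adaptive solver.

    Raises :class:`DivergenceError` (with the last valid time) if the solution
    blows up past :data:`OVERFLOW_BOUND` before the end of the grid.
    """
    x0 = _as_1d(x0, "x0")
    if x0.size != params.n_species:
        raise ValueError("x0 dimension does not match parameters")

    def overflow(t, x):
        return OVERFLOW_BOUND - np.max(np.abs(x))

    overflow.terminal = True
    overflow.direction = -1

    times = grid.times
    sol = solve_ivp(lv_rhs(params), (times[0], times[-1]), x0, t_eval=times,
                    rtol=rtol, atol=atol, events=overflow, method="RK45")
    if sol.status == 1:  # overflow event fired
        raise DivergenceError(
            f"LV integration blew up past |x| = {OVERFLOW_BOUND:g} "
            f"at t = {sol.t_events[0][0]:.6g}",
            last_valid_time=float(sol.t_events[0][0]))
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise DivergenceError(f"LV integration failed: {sol.message}",
                              last_valid_time=last_t)
    return Trajectory(times=sol.t, values=sol.y.T)


def draw_process_noise(shape: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. gamma(k, scale=1/(k-1)) factors (mode exactly 1)."""
    if np.any(np.asarray(shape) <= 1):
        raise ValueError("gamma shape must exceed 1")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.asarray(shape, dtype=float)
    return rng.gamma(k, 1.0 / (k - 1.0), size=n)


def shape_for_noise_sd(sd: float) -> float:
    """Gamma shape k whose mode-1 parameterization has the requested sd.

    The factor Gamma(k, 1/(k-1)) has sd sqrt(k)/(k-1); this inverts that
    relation (e.g. sd 0.03 -> k ~= 1113).
    """
    if not 0 < sd < 1:
        raise ValueError("sd must be in (0, 1)")
    s2 = sd * sd
    # k satisfies k / (k-1)^2 = s2  ->  s2 k^2 - (2 s2 + 1) k + s2 = 0
    b = 2 * s2 + 1
    return float((b + np.sqrt(b * b - 4 * s2 * s2)) / (2 * s2))


def simulate_lv_discrete(params: LVParameters, x0, grid: SimulationGrid,
                         noise: NoiseSpec | None = None,
                         seed: int | np.random.Generator | None = None,
                         noise_on_increment: bool = False) -> Trajectory:
    """Euler-discretized LV with optional multiplicative gamma process noise.

    One step is ``X_{t+h} = [X_t + h * X_t * (a + B X_t)] * g`` where ``g`` is
    a per-species gamma(k, 1/(k-1)) draw when noise is enabled and 1 otherwise.
    With ``noise_on_increment=True`` the gamma factor multiplies only the Euler
    increment (the alternative reading of the update rule).

    Deterministic Euler overshoots below zero are clipped at 0 and recorded in
    ``Trajectory.clipped_steps``; non-finite or overflowing states raise
    :class:`DivergenceError` with the offending step index.
    """
    x0 = _as_1d(x0, "x0")
    if x0.size != params.n_species:
        raise ValueError("x0 dimension does not match parameters")
    noisy = noise is not None and noise.enabled
    if noisy:
        if seed is None:
            raise ValueError("seed is required when noise is enabled")
        if np.any(x0 <= 0):
            raise ValueError("x0 must be strictly positive when noise is enabled")
        k = noise.per_species(params.n_species)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    a, B, h = params.growth_rates, params.interactions, grid.step
    values = np.empty((grid.n_steps + 1, x0.size))
    values[0] = x0
    clipped: list[int] = []
    x = x0.copy()
    for step in range(1, grid.n_steps + 1):
        increment = h * x * (a + B @ x)
        if noisy:
            g = rng.gamma(k, 1.0 / (k - 1.0))
            x = x + increment * g if noise_on_increment else (x + increment) * g
        else:
            x = x + increment
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > OVERFLOW_BOUND:
            raise DivergenceError(
                f"discrete LV state became non-finite or exceeded "
                f"{OVERFLOW_BOUND:g} at step {step}", step_index=step)
        if np.any(x < 0):
            clipped.append(step)
            x = np.maximum(x, 0.0)
        values[step] = x
    return Trajectory(times=grid.times, values=values, clipped_steps=tuple(clipped))


def simulate_mar(params: MARParameters, x0, n_steps: int,
                 seed: int | np.random.Generator | None = None,
                 deterministic: bool = False) -> Trajectory:
    """Iterate the MAR(1) recursion ``x_{t+1} = alpha + beta x_t + w_t``.

    Values live in model space: under the Gompertz reading they are
    log-abundances, and exponentiation is the caller's responsibility.
    """
    x0 = _as_1d(x0, "x0")
    if x0.size != params.n_species:
        raise ValueError("x0 dimension does not match parameters")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    alpha, beta, delta = (params.intercepts, params.transition,
                          params.process_covariance)
    stochastic = not deterministic and np.any(delta != 0)
    if stochastic:
        if seed is None:
            raise ValueError("seed is required for stochastic MAR simulation")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # symmetric PSD square root: robust for singular delta
        w, V = np.linalg.eigh(0.5 * (delta + delta.T))
        root = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
        shocks = rng.standard_normal((n_steps, x0.size)) @ root.T
    values = np.empty((n_steps + 1, x0.size))
    values[0] = x0
    x = x0.copy()
    for step in range(1, n_steps + 1):
        x = alpha + beta @ x
        if stochastic:
            x = x + shocks[step - 1]
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > OVERFLOW_BOUND:
            raise DivergenceError(
                f"MAR state became non-finite or exceeded {OVERFLOW_BOUND:g} "
                f"at step {step}", step_index=step)
        values[step] = x
    return Trajectory(times=np.arange(n_steps + 1, dtype=float), values=values)


def _checked_solve(M: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    n = M.shape[0]
    rank = np.linalg.matrix_rank(M)
    if rank < n:
        raise SingularMatrixError(
            f"{what} is singular (rank {rank} < {n}); no unique solution",
            rank=int(rank))
    return np.linalg.solve(M, rhs)


def lv_steady_state(params: LVParameters) -> np.ndarray:
    """Nontrivial LV steady state: solution of ``a + B x* = 0``."""
    return _checked_solve(params.interactions, -params.growth_rates,
                          "interaction matrix B")


def mar_steady_state(params: MARParameters) -> np.ndarray:
    """MAR fixed point ``x* = (I - beta)^{-1} alpha``."""
    n = params.n_species
    return _checked_solve(np.eye(n) - params.transition, params.intercepts,
                          "I - beta")


def lv_to_mar_steady_map(params: LVParameters) -> MARParameters:
    """Map LV parameters to the MAR model sharing its steady-state equations.

    ``alpha = a``; ``beta`` equals ``B`` off the diagonal and ``b_ii + 1`` on
    it (i.e. ``beta = B + I``).  The mapped model carries zero process
    covariance: the correspondence is about fixed points, not noise.
    """
    n = params.n_species
    return MARParameters(intercepts=params.growth_rates.copy(),
                         transition=params.interactions + np.eye(n),
                         process_covariance=np.zeros((n, n)))
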