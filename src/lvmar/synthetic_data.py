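"""Benchmark scenario generators.

Everything the experiments consume is generated here: a 4-species LV
benchmark whose fourth species is a decoupled logistic (a built-in probe for
whether an inference method detects detachment), a 4-species MAR benchmark
with a dense transition matrix, multiplicative gamma process noise in a
low-noise (k = 10,000) and a high-noise (per-step sd 0.03) flavour, the two
sampling schemes (40 random points of a 100-point series; 15 fixed times
harvested from 5 independent stochastic runs), a six-regime dynamics suite
(stable point, damped oscillation, limit-cycle convergence, sustained
oscillation, and two chaotic systems), and steady-state-scaled initial
condition grids.

All default parameter values are hard-coded and documented; a ScenarioSpec
plus its seed regenerates a Dataset deterministically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import argrelextrema

from .models import (LVParameters, MARParameters, NoiseSpec, SimulationGrid,
                     Trajectory, shape_for_noise_sd, simulate_lv_discrete,
                     simulate_lv_ode, simulate_mar, lv_steady_state,
                     mar_steady_state)
from .smoothing import Dataset

__all__ = [
    "ScenarioSpec",
    "HIGH_NOISE_SD",
    "make_lv_benchmark",
    "make_mar_benchmark",
    "generate_dataset",
    "noise_free_trajectory",
    "sample_noisy",
    "sample_replicates",
    "default_replicate_times",
    "dynamics_suite",
    "initial_condition_grid",
]

#: per-step noise-factor standard deviation of the high-noise variant
HIGH_NOISE_SD = 0.03

# ---------------------------------------------------------------------------
# default benchmark parameter sets (implementer-chosen, version-pinned)
# ---------------------------------------------------------------------------

# 4-species LV: species 1-3 interact with mixed signs and settle at
# (1.2, 0.8, 1.5); species 4 is a decoupled logistic with K = 2 started far
# below its carrying capacity, so its trajectory is strongly non-linear.
_LV_B = np.array([
    [-0.70, -0.20,  0.10,  0.00],
    [ 0.15, -0.60, -0.25,  0.00],
    [-0.10,  0.30, -0.80,  0.00],
    [ 0.00,  0.00,  0.00, -0.50],
])
_LV_A = np.array([0.85, 0.675, 1.08, 1.0])
_LV_X0 = np.array([0.3, 0.2, 0.5, 0.05])

# 4-species MAR in log-abundance space: dense transition matrix (16 nonzero
# entries), spectral radius ~0.66, fixed point (1.5, 1.0, 2.0, 1.2) in log
# space (all positive, so abundances exceed 1); diagonal process covariance.
_MAR_BETA = np.array([
    [ 0.50,  0.10, -0.10,  0.05],
    [ 0.08,  0.60,  0.10, -0.05],
    [-0.12,  0.15,  0.55,  0.08],
    [ 0.10, -0.08,  0.12,  0.45],
])
_MAR_XSTAR = np.array([1.5, 1.0, 2.0, 1.2])
_MAR_ALPHA = (np.eye(4) - _MAR_BETA) @ _MAR_XSTAR
_MAR_DELTA = 0.01 * np.eye(4)
_MAR_X0 = np.array([0.5, 0.3, 0.8, 0.4])


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified data-generating experiment.

    ``kind`` selects the simulator; for LV scenarios abundances are simulated
    on ``grid`` with optional gamma process noise, for MAR scenarios the
    recursion runs ``n_steps`` steps in log space and the dataset holds
    exponentiated (abundance-scale) values.  The spec plus ``seed`` fully
    determines the generated Dataset.
    """

    name: str
    kind: Literal["lv", "mar"]
    lv_params: LVParameters | None = None
    mar_params: MARParameters | None = None
    x0: np.ndarray = field(default_factory=lambda: np.empty(0))
    grid: SimulationGrid = field(default_factory=SimulationGrid)
    noise: NoiseSpec | None = None
    sampling: Literal["noisy", "replicate", "none"] = "none"
    n_sample_points: int = 40
    replicate_times: tuple[float, ...] | None = None
    n_replicates: int = 5
    seed: int = 0
    fit_window: tuple[float, float] | None = None
    extrapolation_end: float | None = None
    alvi_sample_times: tuple[float, ...] | None = None
    mar_log_space: bool = True

    def __post_init__(self):
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))
        if self.kind == "lv" and self.lv_params is None:
            raise ValueError("lv scenario requires lv_params")
        if self.kind == "mar" and self.mar_params is None:
            raise ValueError("mar scenario requires mar_params")

    @property
    def parameters(self):
        return self.lv_params if self.kind == "lv" else self.mar_params

    def steady_state(self) -> np.ndarray:
        if self.kind == "lv":
            return lv_steady_state(self.lv_params)
        return mar_steady_state(self.mar_params)

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind,
                   "x0": self.x0.tolist(),
                   "grid": {"start_time": self.grid.start_time,
                            "step": self.grid.step,
                            "n_steps": self.grid.n_steps},
                   "sampling": self.sampling,
                   "n_sample_points": self.n_sample_points,
                   "replicate_times": (list(self.replicate_times)
                                       if self.replicate_times else None),
                   "n_replicates": self.n_replicates, "seed": self.seed,
                   "fit_window": (list(self.fit_window)
                                  if self.fit_window else None),
                   "extrapolation_end": self.extrapolation_end,
                   "alvi_sample_times": (list(self.alvi_sample_times)
                                         if self.alvi_sample_times else None),
                   "mar_log_space": self.mar_log_space}
        if self.lv_params is not None:
            d["lv_params"] = {"growth_rates": self.lv_params.growth_rates.tolist(),
                              "interactions": self.lv_params.interactions.tolist()}
        if self.mar_params is not None:
            d["mar_params"] = {
                "intercepts": self.mar_params.intercepts.tolist(),
                "transition": self.mar_params.transition.tolist(),
                "process_covariance": self.mar_params.process_covariance.tolist()}
        if self.noise is not None:
            d["noise"] = {"shape": np.asarray(self.noise.shape).tolist(),
                          "enabled": self.noise.enabled}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        kwargs = dict(d)
        kwargs["x0"] = np.asarray(d["x0"], dtype=float)
        kwargs["grid"] = SimulationGrid(**d["grid"])
        if d.get("lv_params"):
            kwargs["lv_params"] = LVParameters(**d["lv_params"])
        if d.get("mar_params"):
            kwargs["mar_params"] = MARParameters(**d["mar_params"])
        if d.get("noise"):
            kwargs["noise"] = NoiseSpec(**d["noise"])
        for key in ("replicate_times", "fit_window", "alvi_sample_times"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def make_lv_benchmark(seed: int = 0, high_noise: bool = False,
                      sampling: str = "noisy") -> ScenarioSpec:
    """The 4-species LV benchmark with a decoupled logistic fourth species.

    Process noise defaults to gamma shape k = 10,000 (per-step factor sd
    ~0.01); ``high_noise`` switches to the shape whose factor sd is 0.03.
    """
    shape = shape_for_noise_sd(HIGH_NOISE_SD) if high_noise else 10_000.0
    return ScenarioSpec(
        name="lv-high-noise" if high_noise else "lv-benchmark",
        kind="lv",
        lv_params=LVParameters(_LV_A.copy(), _LV_B.copy()),
        x0=_LV_X0.copy(),
        grid=SimulationGrid.over_span(0.0, 10.0, 100),
        noise=NoiseSpec(shape=shape, enabled=True),
        sampling=sampling, seed=seed)


def make_mar_benchmark(seed: int = 0, sampling: str = "noisy",
                       n_points: int = 31) -> ScenarioSpec:
    """The 4-species MAR benchmark: dense beta, spectral radius < 1.

    The default series length of 31 points is deliberately far below the
    sign-recovery criterion 5 x nnz(beta) = 80, making this the canonical
    short-series test case.
    """
    return ScenarioSpec(
        name="mar-benchmark", kind="mar",
        mar_params=MARParameters(_MAR_ALPHA.copy(), _MAR_BETA.copy(),
                                 _MAR_DELTA.copy()),
        x0=_MAR_X0.copy(),
        grid=SimulationGrid(start_time=0.0, step=1.0, n_steps=n_points - 1),
        sampling=sampling, n_sample_points=min(40, n_points), seed=seed)


def noise_free_trajectory(spec: ScenarioSpec) -> Trajectory:
    """The scenario's deterministic time course on the abundance scale."""
    if spec.kind == "lv":
        return simulate_lv_ode(spec.lv_params, spec.x0, spec.grid)
    traj = simulate_mar(spec.mar_params, spec.x0, spec.grid.n_steps,
                        deterministic=True)
    values = np.exp(traj.values) if spec.mar_log_space else traj.values
    return Trajectory(times=spec.grid.times, values=values,
                      species=traj.species)


def _stochastic_run(spec: ScenarioSpec, seed: int) -> Trajectory:
    if spec.kind == "lv":
        noise = spec.noise or NoiseSpec(enabled=False)
        return simulate_lv_discrete(spec.lv_params, spec.x0, spec.grid,
                                    noise=noise, seed=seed)
    traj = simulate_mar(spec.mar_params, spec.x0, spec.grid.n_steps, seed=seed)
    values = np.exp(traj.values) if spec.mar_log_space else traj.values
    return Trajectory(times=spec.grid.times, values=values,
                      species=traj.species)


def sample_noisy(traj: Trajectory, n: int = 40,
                 seed: int | np.random.Generator = 0) -> Dataset:
    """Uniform random subset of ``n`` time points, order preserved."""
    if n > traj.times.size:
        raise ValueError(f"cannot sample {n} of {traj.times.size} points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(traj.times.size, n, replace=False))
    return Dataset(times=traj.times[idx], values=traj.values[idx],
                   species=traj.species)


def default_replicate_times(traj: Trajectory, n: int = 15) -> np.ndarray:
    """Characteristic sampling times: local extrema plus equispaced fill.

    Detects local minima/maxima of every species on the noise-free course
    (the dynamically informative points), always keeps the endpoints, and
    fills the remainder with (near-)equispaced grid times.
    """
    t = traj.times
    chosen: set[float] = {t[0], t[-1]}
    for j in range(traj.n_species):
        y = traj.values[:, j]
        for finder in (np.greater, np.less):
            for i in argrelextrema(y, finder, order=3)[0]:
                chosen.add(t[i])
    extrema = sorted(chosen)
    if len(extrema) >= n:
        keep = np.linspace(0, len(extrema) - 1, n).round().astype(int)
        return np.asarray(extrema)[keep]
    fill = [tv for tv in t[np.linspace(0, t.size - 1, n).round().astype(int)]
            if tv not in chosen]
    out = sorted(chosen | set(fill[:n - len(chosen)]))
    # pad from the remaining grid if equispaced fill collided with extrema
    for tv in t:
        if len(out) >= n:
            break
        if tv not in out:
            out.append(tv)
    return np.asarray(sorted(out[:n]))


def sample_replicates(spec: ScenarioSpec, timepoints=None,
                      n_replicates: int = 5,
                      seed: int | None = None) -> Dataset:
    """Harvest fixed time points from independent stochastic runs.

    Runs ``n_replicates`` independent simulations of the scenario and records
    each at ``timepoints`` (default: 15 extrema-plus-equispaced times of the
    noise-free course), labelling rows by replicate.
    """
    if seed is None:
        seed = spec.seed
    if timepoints is None:
        timepoints = (np.asarray(spec.replicate_times)
                      if spec.replicate_times is not None
                      else default_replicate_times(noise_free_trajectory(spec)))
    timepoints = np.asarray(timepoints, dtype=float)
    grid_times = spec.grid.times
    pos = np.searchsorted(grid_times, timepoints)
    pos = np.clip(pos, 0, grid_times.size - 1)
    # accept nearest-neighbour matches within half a step
    left = np.clip(pos - 1, 0, grid_times.size - 1)
    pos = np.where(np.abs(grid_times[left] - timepoints)
                   < np.abs(grid_times[pos] - timepoints), left, pos)
    if np.any(np.abs(grid_times[pos] - timepoints) > 0.5 * spec.grid.step + 1e-9):
        raise ValueError("requested replicate timepoints are off-grid")
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_replicates)
    rows_t, rows_v, rows_r = [], [], []
    for r, s in enumerate(rep_seeds):
        traj = _stochastic_run(spec, int(s))
        rows_t.append(traj.times[pos])
        rows_v.append(traj.values[pos])
        rows_r.append(np.full(pos.size, r))
    return Dataset(times=np.concatenate(rows_t),
                   values=np.vstack(rows_v),
                   species=noise_free_trajectory(spec).species,
                   replicate=np.concatenate(rows_r))


def generate_dataset(spec: ScenarioSpec) -> Dataset:
    """Materialize the scenario's Dataset according to its sampling scheme."""
    if spec.sampling == "none":
        traj = noise_free_trajectory(spec)
        return Dataset(times=traj.times, values=traj.values,
                       species=traj.species)
    if spec.sampling == "noisy":
        traj = _stochastic_run(spec, spec.seed)
        return sample_noisy(traj, spec.n_sample_points,
                            np.random.default_rng(spec.seed + 1))
    if spec.sampling == "replicate":
        return sample_replicates(spec, n_replicates=spec.n_replicates,
                                 seed=spec.seed)
    raise ValueError(f"unknown sampling scheme {spec.sampling!r}")


# ---------------------------------------------------------------------------
# six-regime dynamics suite
# ---------------------------------------------------------------------------

# Vano-style 4-species competitive chaotic system, rescaled in abundance
# (x10) and time so the attractor's sensitive dependence is visible within
# the t <= 500 window.  dx/dt = c r x (1 - A x / 10).
_CHAOS_R = np.array([1.0, 0.72, 1.53, 1.27])
_CHAOS_A = np.array([
    [1.00, 1.09, 1.52, 0.00],
    [0.00, 1.00, 0.44, 1.36],
    [2.33, 0.00, 1.00, 0.47],
    [1.21, 0.51, 0.35, 1.00],
])
_CHAOS_X0 = 10.0 * np.array([0.3013, 0.4586, 0.1307, 0.3557])


def _chaos_params(time_scale: float, A: np.ndarray) -> LVParameters:
    a = time_scale * _CHAOS_R
    B = -(time_scale * _CHAOS_R)[:, None] * A / 10.0
    return LVParameters(a, B)


def dynamics_suite() -> dict[str, ScenarioSpec]:
    """Six noise-free LV systems spanning qualitatively distinct regimes.

    Each scenario carries a fit window t in [1, 100], an extrapolation end of
    t = 500, and default slope-sample times (5, 10, 20, 30, 50) — the chaotic
    systems use (4, 6, 10, 15, 35) instead, where their fast dynamics live.
    """
    default_times = (5.0, 10.0, 20.0, 30.0, 50.0)
    chaos_times = (4.0, 6.0, 10.0, 15.0, 35.0)

    def spec(name, params, x0, sample_times=default_times):
        return ScenarioSpec(
            name=name, kind="lv", lv_params=params, x0=np.asarray(x0),
            grid=SimulationGrid.over_span(0.0, 500.0, 2000),
            sampling="none", fit_window=(1.0, 100.0),
            extrapolation_end=500.0, alvi_sample_times=sample_times)

    stable_B = np.array([[-0.9, -0.2, -0.1],
                         [-0.1, -0.8, -0.2],
                         [-0.2, -0.1, -1.0]])
    stable = LVParameters(-stable_B @ np.array([1.0, 1.5, 0.8]), stable_B)
    damped = LVParameters(np.array([0.8, -0.4]),
                          np.array([[-0.08, -0.35], [0.25, -0.03]]))
    # asymmetric rock-paper-scissors competition: orbits spiral out of the
    # unstable interior point onto a planar limit cycle
    lc_r = np.array([1.0, 1.2, 0.8])
    lc_A = np.array([[1.0, 1.3, 0.7], [0.7, 1.0, 1.3], [1.3, 0.7, 1.0]])
    limit_cycle = LVParameters(lc_r, -lc_r[:, None] * lc_A)
    # conservative predator-prey: closed orbits, amplitude never decays
    sustained = LVParameters(np.array([0.6, -0.4]),
                             np.array([[0.0, -0.3], [0.2, 0.0]]))
    chaos1 = _chaos_params(2.0, _CHAOS_A)
    A2 = _CHAOS_A.copy()
    A2[0, 1] += 0.02
    chaos2 = _chaos_params(3.0, A2)

    return {
        "stable": spec("stable", stable, [0.2, 0.3, 0.1]),
        "damped": spec("damped", damped, [0.5, 0.3]),
        "limit_cycle": spec("limit_cycle", limit_cycle, [0.2, 0.5, 0.9]),
        "sustained": spec("sustained", sustained, [1.0, 1.0]),
        "chaos1": spec("chaos1", chaos1, _CHAOS_X0.copy(), chaos_times),
        "chaos2": spec("chaos2", chaos2, _CHAOS_X0.copy(), chaos_times),
    }


def initial_condition_grid(params, multipliers=(0.001, 0.01, 0.1, 1.9, 10, 100)):
    """Initial states: the nontrivial steady state scaled by each multiplier."""
    if isinstance(params, LVParameters):
        xstar = lv_steady_state(params)
    elif isinstance(params, MARParameters):
        xstar = mar_steady_state(params)
    else:
        raise TypeError("params must be LVParameters or MARParameters")
    return [m * xstar for m in multipliers]
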