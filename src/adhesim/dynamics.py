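"""Time integration of the coupled cell-center ODEs.

The cell centers obey a set of coupled, autonomous, first-order ODEs (the
overdamped force balance of :mod:`adhesim.forces`), advanced by the
classical fourth-order Runge-Kutta scheme with timestep ``dt``.  One
timestep is one synchronous movement cycle for every cell.

Randomness is handled so that each step's stage field is deterministic:
the matching tie-break priorities and trapped-site neighbor draws are
frozen at the start of the step (:class:`adhesim.forces.StepRandomness`),
the adhesion scale is evaluated at the step's start time, and site
directions never change during the four stages.  In the *dynamic* site
regimes the site sets are resampled uniformly on the sphere between
steps, turning the ODE system into a stochastic one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forces import StepRandomness, system_forces
from .geometry import CellState, sample_uniform_sphere
from .params import ModelParams

__all__ = [
    "SystemState",
    "TrajectoryRecord",
    "sigma_schedule",
    "make_state",
    "rk4_step",
    "update_sites",
    "run",
]


@dataclass
class SystemState:
    """Full simulation state: time, stacked cell arrays, and the RNG.

    ``centers`` is ``(n, 3)``; ``cc_dirs`` / ``cm_dirs`` are
    ``(n, n_cc, 3)`` / ``(n, n_cm, 3)`` body-frame unit directions.  The
    generator ``rng`` is the run's single random stream; a trajectory is a
    pure function of (initial state, params, seed).
    """

    time: float
    centers: np.ndarray
    cc_dirs: np.ndarray
    cm_dirs: np.ndarray
    rng: np.random.Generator

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    def cell(self, i: int, radius: float = 1.0) -> CellState:
        """View cell ``i`` as a :class:`~adhesim.geometry.CellState`."""
        return CellState(
            center=self.centers[i],
            radius=radius,
            cc_dirs=self.cc_dirs[i],
            cm_dirs=self.cm_dirs[i],
        )

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            centers=self.centers.copy(),
            cc_dirs=self.cc_dirs.copy(),
            cm_dirs=self.cm_dirs.copy(),
            rng=copy.deepcopy(self.rng),
        )


def make_state(
    centers: np.ndarray, params: ModelParams, rng: np.random.Generator | None = None
) -> SystemState:
    """Build a t=0 state with fresh uniform site sets on every cell."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = centers.shape[0]
    cc = np.stack([sample_uniform_sphere(params.n_cc, rng) for _ in range(n)])
    cm = np.stack([sample_uniform_sphere(params.n_cm, rng) for _ in range(n)])
    return SystemState(time=0.0, centers=centers, cc_dirs=cc, cm_dirs=cm, rng=rng)


def sigma_schedule(
    t: float, sigma0: float, t_total: float, p: float | None
) -> float:
    """Adhesion energy scale at time ``t`` under power-law depletion.

    ``sigma(t) = sigma0 * (1 - (t / t_total)**p)`` for exponent ``p > 0``,
    clamped at zero; ``p = None`` means constant adhesion.  The scale
    vanishes exactly at ``t = t_total`` for every exponent.
    """
    if p is None:
        return sigma0
    if not p > 0:
        raise ValueError(f"decay exponent must be > 0, got {p!r}")
    frac = 1.0 - (t / t_total) ** p
    return sigma0 * max(frac, 0.0)


def _velocities(
    centers: np.ndarray,
    state: SystemState,
    params: ModelParams,
    sigma_pair: float,
    step_rand: StepRandomness,
) -> np.ndarray:
    forces = system_forces(
        centers,
        state.cc_dirs,
        state.cm_dirs,
        R=params.R,
        r_cut=params.r_cut,
        sigma_pair=sigma_pair,
        eps=params.eps,
        alpha=params.alpha,
        K=params.K,
        f_lr=params.f_lr,
        wall_force_cap=params.wall_force_cap,
        step_rand=step_rand,
    )
    return forces.total / params.drag


def rk4_step(state: SystemState, params: ModelParams) -> SystemState:
    """Advance all cell centers by one classical RK4 step of size ``dt``.

    Site directions, the matching tie-break priorities, the trapped-site
    neighbor draws and the adhesion scale are frozen for all four stages;
    the geometric predicates (overlap, exposure, matching) are re-evaluated
    at each stage from the stage positions.
    """
    sigma_active = sigma_schedule(
        state.time, params.sigma0, params.t_total, params.decay_exponent
    )
    sigma_pair = sigma_active / params.n_cc if params.n_cc else 0.0
    step_rand = StepRandomness.draw(state.n_cells, params.n_cc, state.rng)
    dt = params.dt
    x0 = state.centers

    def v(x):
        return _velocities(x, state, params, sigma_pair, step_rand)

    k1 = v(x0)
    k2 = v(x0 + 0.5 * dt * k1)
    k3 = v(x0 + 0.5 * dt * k2)
    k4 = v(x0 + dt * k3)
    x1 = x0 + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(x1)):
        raise FloatingPointError(
            "non-finite cell positions after RK4 step; the wall force cap "
            "or the timestep is unsuitable for this configuration"
        )
    return SystemState(
        time=state.time + dt,
        centers=x1,
        cc_dirs=state.cc_dirs,
        cm_dirs=state.cm_dirs,
        rng=state.rng,
    )


def update_sites(state: SystemState, params: ModelParams) -> SystemState:
    """Resample site sets between steps according to the site-dynamics modes.

    In the dynamic regimes every site of the affected receptor family is
    reallocated uniformly on the sphere; static site sets are left untouched
    (bitwise) and consume no randomness.
    """
    cc, cm = state.cc_dirs, state.cm_dirs
    if params.cc_mode == "dynamic":
        cc = np.stack(
            [sample_uniform_sphere(params.n_cc, state.rng) for _ in range(state.n_cells)]
        )
    if params.cm_mode == "dynamic":
        cm = np.stack(
            [sample_uniform_sphere(params.n_cm, state.rng) for _ in range(state.n_cells)]
        )
    return SystemState(
        time=state.time, centers=state.centers, cc_dirs=cc, cm_dirs=cm, rng=state.rng
    )


@dataclass
class TrajectoryRecord:
    """Sampled cell-center time series for one run.

    ``times`` is ``(m,)`` and ``positions`` is ``(m, n_cells, 3)``.
    """

    times: np.ndarray
    positions: np.ndarray
    params: ModelParams | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self, run_id: int = 0) -> pd.DataFrame:
        """Tidy table: one row per cell per sampled time."""
        m, n, _ = self.positions.shape
        return pd.DataFrame(
            {
                "run_id": np.full(m * n, run_id),
                "t": np.repeat(self.times, n),
                "cell_id": np.tile(np.arange(n), m),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "z": self.positions[:, :, 2].ravel(),
            }
        )

    def write_csv(self, path, run_id: int = 0) -> None:
        self.to_dataframe(run_id).to_csv(path, index=False)


def run(
    initial: SystemState,
    params: ModelParams,
    thin: int = 1,
    callback=None,
) -> TrajectoryRecord:
    """Integrate from ``initial`` until ``t_total`` and record the centers.

    Frames are recorded at t=0 and after every ``thin``-th step (the final
    step is always recorded).  ``initial`` is not mutated: the state
    (including the RNG) is copied first, so the trajectory is reproducible
    from (initial, params).  ``callback(state)`` runs after every completed
    step, e.g. to accumulate cluster observables.
    """
    if params.t_total < params.dt:
        raise ValueError("t_total must be >= dt")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    state = initial.copy()
    n_steps = int(round(params.t_total / params.dt))
    times = [state.time]
    frames = [state.centers.copy()]
    for step in range(1, n_steps + 1):
        state = rk4_step(state, params)
        state = update_sites(state, params)
        if callback is not None:
            callback(state)
        if step % thin == 0 or step == n_steps:
            times.append(state.time)
            frames.append(state.centers.copy())
    return TrajectoryRecord(
        times=np.asarray(times), positions=np.stack(frames), params=params
    )
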