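"""Experiment protocols: initial conditions, sweeps, and the cluster demo.

Pair protocols start two cells on the x-axis (default: touching, center
distance ``2R``), each with a fresh uniform site distribution, and repeat
the run over independent seeds per parameter point.  The depletion
protocol is the same sweep with the power-law adhesion decay active.  The
cluster demo packs ``n`` cells at random into a ball (rejecting placements
that violate the core-exclusion distance), then evolves the same initial
configuration under several traction strengths, tracking the radius of
gyration and the mean overlapping-neighbor count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SystemState, TrajectoryRecord, make_state, run
from .observables import (
    BatchSummary,
    batch_summary,
    mean_overlapping_neighbors,
    radius_of_gyration,
    summarize_pair,
)
from .params import ExperimentSpec, ModelParams

__all__ = [
    "SweepResult",
    "ClusterDemoResult",
    "init_pair",
    "init_cluster",
    "run_pair_sweep",
    "run_depletion_sweep",
    "run_cluster_demo",
    "find_breakup_window",
    "default_traction_grid",
]

#: Default packing fraction of the cluster initialization ball.
CLUSTER_PACKING_FRACTION = 0.3

#: Placement attempts per cell before giving up on a packing.
PLACEMENT_ATTEMPTS = 10_000


def init_pair(
    params: ModelParams,
    d0: float | None = None,
    rng: np.random.Generator | None = None,
) -> SystemState:
    """Two cells on the x-axis at center separation ``d0`` (default ``2R``).

    ``d0`` must exceed the core-exclusion distance ``2R(1-alpha)``.
    """
    if d0 is None:
        d0 = 2.0 * params.R
    if d0 <= params.core_diameter:
        raise ValueError(
            f"d0={d0} lies inside the core-exclusion distance "
            f"{params.core_diameter}"
        )
    centers = np.array([[0.0, 0.0, 0.0], [d0, 0.0, 0.0]])
    return make_state(centers, params, rng)


def init_cluster(
    n: int,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    packing_fraction: float = CLUSTER_PACKING_FRACTION,
) -> SystemState:
    """Pack ``n`` cells at random into a ball, respecting the hard cores.

    Centers are drawn uniformly in a ball sized for the requested volume
    packing fraction and accepted only if every pairwise center distance
    exceeds the core diameter ``2R(1-alpha)`` (no two cells enter each
    other's impenetrable cores).  Raises after a fixed attempt budget if
    the ball is too crowded.
    """
    if n < 1:
        raise ValueError(f"cluster size must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if n == 1:
        return make_state(np.zeros((1, 3)), params, rng)
    ball_radius = params.R * (n / packing_fraction) ** (1.0 / 3.0)
    d_min = params.core_diameter
    centers = np.empty((n, 3))
    placed = 0
    for _ in range(PLACEMENT_ATTEMPTS * n):
        u = rng.random() ** (1.0 / 3.0)
        direction = rng.standard_normal(3)
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            continue
        candidate = ball_radius * u * direction / norm
        if placed == 0 or np.all(
            np.linalg.norm(centers[:placed] - candidate, axis=1) > d_min
        ):
            centers[placed] = candidate
            placed += 1
            if placed == n:
                return make_state(centers, params, rng)
    raise RuntimeError(
        f"could not place {n} cells with core exclusion {d_min} in a ball of "
        f"radius {ball_radius:.3g} within the attempt budget"
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-point batch statistics of a sweep, with seed provenance."""

    spec: ExperimentSpec
    summaries: list[BatchSummary]
    points: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per parameter point, in the summary CSV schema.

        The Gompertz coefficients of the break-fraction-vs-traction curve
        (one fit per sweep) are repeated on every row; NaN if the sweep has
        too few points or the fit fails.
        """
        try:
            fit = self.fit_breakup_curve()
            g_b, g_c = fit.b, fit.c
        except (ValueError, RuntimeError):
            g_b = g_c = float("nan")
        rows = []
        for point, summ in zip(self.points, self.summaries):
            p = self.spec.base.replace(
                **{k: v for k, v in point.items() if k != "seed"}
            )
            rows.append(
                {
                    "case": self.spec.case,
                    "f_lr": p.f_lr,
                    "sigma0": p.sigma0,
                    "eta": p.eta,
                    "alpha": p.alpha,
                    "d0": self.spec.d0 if self.spec.d0 is not None else 2 * p.R,
                    "decay_exponent": p.decay_exponent,
                    "n_runs": summ.n_runs,
                    "mean_tfb": summ.mean_tfb,
                    "sem2_tfb": summ.sem2_tfb,
                    "mean_ct": summ.mean_ct,
                    "sem2_ct": summ.sem2_ct,
                    "frac_broke": summ.frac_broke,
                    "gompertz_b": g_b,
                    "gompertz_c": g_c,
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def fit_breakup_curve(self, axis: str = "f_lr"):
        """Gompertz fit of break-up fraction against a swept parameter axis.

        The fraction of runs with at least one break-up rises sigmoidally
        with traction; following the protocol, it is fitted with the
        Gompertz form (a logistic rises too symmetrically to follow the
        slow saturation).  ``axis`` names the swept ModelParams field.
        """
        from .observables import fit_gompertz

        x = [
            float(point.get(axis, getattr(self.spec.base, axis)))
            for point in self.points
        ]
        y = [s.frac_broke for s in self.summaries]
        return fit_gompertz(np.asarray(x), np.asarray(y))

    def provenance(self) -> dict:
        return {
            "case": self.spec.case,
            "base_seed": self.spec.base_seed,
            "runs_per_point": self.spec.runs_per_point,
            "points": [
                {k: v for k, v in point.items()} for point in self.spec.points
            ],
        }

    def write_provenance(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.provenance(), fh, indent=2, default=str)


def _run_one_pair(params: ModelParams, d0: float | None) -> TrajectoryRecord:
    rng = np.random.default_rng(params.seed)
    state = init_pair(params, d0=d0, rng=rng)
    return run(state, params)


def run_pair_sweep(spec: ExperimentSpec, progress=None) -> SweepResult:
    """Run the pair protocol over every grid point of ``spec``.

    Each point runs ``spec.runs_per_point`` independent pairs (fresh random
    site distributions, seed ladder disjoint across points) and aggregates
    TFB / CT / break-fraction statistics.  Iteration order does not affect
    any batch (seeds are keyed by point index).
    """
    if spec.init_kind != "pair":
        raise ValueError("run_pair_sweep requires a pair ExperimentSpec")
    summaries = []
    for pi in range(len(spec.points)):
        batch = []
        for k in range(spec.runs_per_point):
            params = spec.params_at(pi, k)
            traj = _run_one_pair(params, spec.d0)
            batch.append(summarize_pair(traj, params.R))
            if progress is not None:
                progress()
        summaries.append(batch_summary(batch))
    return SweepResult(
        spec=spec, summaries=summaries, points=[dict(p) for p in spec.points]
    )


def run_depletion_sweep(spec: ExperimentSpec, progress=None) -> SweepResult:
    """Pair sweep with the adhesion-depletion schedule active.

    Identical to :func:`run_pair_sweep` (points carry ``decay_exponent``
    overrides); with ``decay_exponent = None`` at a point it reproduces the
    constant-adhesion result bit-for-bit at equal seeds.
    """
    return run_pair_sweep(spec, progress=progress)


# ---------------------------------------------------------------------------
# Cluster demo
# ---------------------------------------------------------------------------


@dataclass
class ClusterDemoResult:
    """Cluster trajectories and observable time series per traction value."""

    f_lr_values: list[float]
    trajectories: list[TrajectoryRecord]
    times: np.ndarray
    r_gyr: np.ndarray  # (n_values, n_frames)
    mean_neighbors: np.ndarray  # (n_values, n_frames)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for vi, f_lr in enumerate(self.f_lr_values):
            for fi, t in enumerate(self.times):
                rows.append(
                    {
                        "f_lr": f_lr,
                        "t": t,
                        "r_gyr": self.r_gyr[vi, fi],
                        "mean_neighbors": self.mean_neighbors[vi, fi],
                    }
                )
        return pd.DataFrame(rows)


def run_cluster_demo(
    n: int,
    f_lr_values,
    params: ModelParams,
    thin: int = 1,
) -> ClusterDemoResult:
    """Evolve one packed cluster under several traction strengths.

    The initial configuration — cell positions *and* both site
    distributions — is identical across all traction values (same seed),
    with sites held static (persistent regime), so differences between runs
    isolate the effect of the traction magnitude.
    """
    if n < 2:
        raise ValueError("cluster demo needs at least 2 cells")
    base = params.replace(cc_mode="static", cm_mode="static")
    initial = init_cluster(n, base)
    trajs, r_gyr, nbar = [], [], []
    for f_lr in f_lr_values:
        p = base.replace(f_lr=float(f_lr))
        traj = run(initial, p, thin=thin)
        trajs.append(traj)
        r_gyr.append([radius_of_gyration(frame) for frame in traj.positions])
        nbar.append(
            [mean_overlapping_neighbors(frame, p.R) for frame in traj.positions]
        )
    return ClusterDemoResult(
        f_lr_values=[float(v) for v in f_lr_values],
        trajectories=trajs,
        times=trajs[0].times,
        r_gyr=np.asarray(r_gyr),
        mean_neighbors=np.asarray(nbar),
    )


# ---------------------------------------------------------------------------
# Locating the break-up transition
# ---------------------------------------------------------------------------


def _frac_broke_probe(
    params: ModelParams, f_lr: float, n_runs: int, base_seed: int
) -> float:
    broke = 0
    for k in range(n_runs):
        p = params.replace(f_lr=f_lr, seed=base_seed + k)
        traj = _run_one_pair(p, None)
        broke += summarize_pair(traj, p.R).broke
    return broke / n_runs


def find_breakup_window(
    params: ModelParams,
    n_probe_runs: int = 4,
    base_seed: int = 0,
    f_lo: float = 1e-6,
    f_hi: float = 1.0,
    iters: int = 8,
) -> tuple[float, float]:
    """Bracket the traction range where pairs go from never to always breaking.

    A bisection pre-pass on small probe batches returns ``(f_low, f_high)``
    with break fraction 0 at ``f_low`` and 1 at ``f_high``; a sweep grid
    spanning this window covers the whole transition.
    """
    if _frac_broke_probe(params, f_lo, n_probe_runs, base_seed) > 0:
        raise RuntimeError(f"pairs already break at f_lr={f_lo}")
    if _frac_broke_probe(params, f_hi, n_probe_runs, base_seed) < 1:
        raise RuntimeError(f"pairs do not always break at f_lr={f_hi}")
    lo_cap, hi_cap = f_lo, f_hi  # tightest known all-bound / all-broken values
    lo, hi = f_lo, f_hi
    for _ in range(iters):
        mid = float(np.sqrt(lo * hi))
        frac = _frac_broke_probe(params, mid, n_probe_runs, base_seed)
        if frac == 0.0:
            lo_cap = max(lo_cap, mid)
            lo = mid
        elif frac == 1.0:
            hi_cap = min(hi_cap, mid)
            hi = mid
        else:
            # inside the transition: tighten both brackets toward it
            lo = mid if frac < 0.5 else lo
            hi = mid if frac >= 0.5 else hi
    return lo_cap, hi_cap


def default_traction_grid(
    params: ModelParams, n_points: int = 5, **window_kwargs
) -> np.ndarray:
    """Geometric traction grid spanning the break-up transition window."""
    lo, hi = find_breakup_window(params, **window_kwargs)
    return np.geomspace(lo, hi, n_points)
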