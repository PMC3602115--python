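"""Summary statistics for pair runs and cluster runs.

A cell pair is *bound* while its center distance is at most twice the cell
radius and *detached* beyond it.  From a pair trajectory we extract the
time of first break-up (TFB: first sampled time with distance > 2R), the
companion time (CT: total time classified bound, left-endpoint rule at the
sampling resolution), and, over a batch of independent runs, their means
with error bars of twice the standard error, the fraction of runs with at
least one break-up, and a Gompertz fit of break-up fraction versus an
experiment axis.  Cluster runs are summarized by the radius of gyration
(over all cells, regardless of connectivity) and the mean number of
overlapping neighbors per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dynamics import TrajectoryRecord

__all__ = [
    "PairSummary",
    "BatchSummary",
    "GompertzFit",
    "pair_distance_trace",
    "classify_bound",
    "time_of_first_breakup",
    "companion_time",
    "summarize_pair",
    "batch_summary",
    "gompertz",
    "fit_gompertz",
    "radius_of_gyration",
    "mean_overlapping_neighbors",
]


@dataclass(frozen=True)
class PairSummary:
    """Break-up statistics of one pair run.

    ``tfb`` is None if the pair never detached; ``ct`` counts bound time,
    so ``ct >= tfb`` whenever a break-up exists (the pre-break-up interval
    is entirely bound) and ``ct = t_total`` for a never-broken run.
    """

    tfb: float | None
    ct: float
    broke: bool
    t_total: float


@dataclass(frozen=True)
class BatchSummary:
    """Aggregates over independent runs at one parameter point.

    Never-broken runs enter the TFB mean truncated at ``t_total`` (so
    curves saturate at the maximum time); ``sem2_*`` are twice the standard
    error of the mean.
    """

    mean_tfb: float
    sem2_tfb: float
    mean_ct: float
    sem2_ct: float
    frac_broke: float
    n_runs: int


def pair_distance_trace(traj: TrajectoryRecord) -> np.ndarray:
    """Per-frame center distance of a two-cell trajectory."""
    if traj.n_cells != 2:
        raise ValueError(f"pair trace requires exactly 2 cells, got {traj.n_cells}")
    return np.linalg.norm(traj.positions[:, 0] - traj.positions[:, 1], axis=1)


def classify_bound(d, R: float):
    """Bound (True) iff center distance ``d <= 2R``; the boundary is bound."""
    return np.asarray(d) <= 2.0 * R if np.ndim(d) else d <= 2.0 * R


def _check_aligned(trace, times) -> tuple[np.ndarray, np.ndarray]:
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError(
            f"trace and times must align, got {trace.shape} vs {times.shape}"
        )
    return trace, times


def time_of_first_breakup(trace, times, R: float) -> float | None:
    """First sampled time with distance > 2R, or None if always bound."""
    trace, times = _check_aligned(trace, times)
    detached = np.nonzero(trace > 2.0 * R)[0]
    return float(times[detached[0]]) if detached.size else None


def companion_time(trace, times, R: float) -> float:
    """Total bound time, left-endpoint rule over the sample intervals.

    Interval ``[t_k, t_k+1)`` counts as bound iff frame ``k`` is bound; no
    sub-interval crossing interpolation is attempted (the model's time
    resolution is the movement cycle).
    """
    trace, times = _check_aligned(trace, times)
    if times.size < 2:
        return 0.0
    bound = classify_bound(trace[:-1], R)
    return float(np.sum(np.diff(times)[bound]))


def summarize_pair(traj: TrajectoryRecord, R: float) -> PairSummary:
    """TFB / CT / break flag for one pair trajectory."""
    trace = pair_distance_trace(traj)
    tfb = time_of_first_breakup(trace, traj.times, R)
    ct = companion_time(trace, traj.times, R)
    return PairSummary(
        tfb=tfb, ct=ct, broke=tfb is not None, t_total=float(traj.times[-1])
    )


def batch_summary(summaries: list[PairSummary]) -> BatchSummary:
    """Means, twice-SEM error bars and break fraction over a batch."""
    if not summaries:
        raise ValueError("empty batch")
    n = len(summaries)
    tfbs = np.array([s.tfb if s.tfb is not None else s.t_total for s in summaries])
    cts = np.array([s.ct for s in summaries])
    broke = np.array([s.broke for s in summaries])

    def sem2(x: np.ndarray) -> float:
        return 2.0 * float(np.std(x, ddof=1)) / math.sqrt(n) if n > 1 else 0.0

    return BatchSummary(
        mean_tfb=float(tfbs.mean()),
        sem2_tfb=sem2(tfbs),
        mean_ct=float(cts.mean()),
        sem2_ct=sem2(cts),
        frac_broke=float(broke.mean()),
        n_runs=n,
    )


# ---------------------------------------------------------------------------
# Gompertz fits of break-up fraction curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GompertzFit:
    """Fitted ``y = exp(-exp(-c * (x - b)))``.

    ``b`` is the displacement of the curve along the abscissa (the location
    of the inflection, where ``y = 1/e``) and ``c > 0`` the rate of growth
    toward the upper asymptote 1; ``rss`` is the residual sum of squares.
    """

    b: float
    c: float
    rss: float

    def __call__(self, x) -> np.ndarray:
        return gompertz(np.asarray(x, dtype=float), self.b, self.c)


def gompertz(x, b: float, c: float):
    """The Gompertz sigmoid ``exp(-exp(-c * (x - b)))``: 0 -> 1, asymmetric
    (it approaches the upper asymptote slower than the lower one, unlike a
    logistic)."""
    return np.exp(-np.exp(-c * (np.asarray(x, dtype=float) - b)))


def fit_gompertz(x, y) -> GompertzFit:
    """Least-squares Gompertz fit of fractions ``y`` in [0, 1] against ``x``.

    Deterministic initialization: ``b`` starts at the abscissa of the point
    whose ordinate is nearest ``1/e`` (the curve's inflection value) and
    ``c`` at 1.  Non-convergence raises rather than returning silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    b0 = float(x[np.argmin(np.abs(y - math.exp(-1)))])
    scale = float(np.ptp(x)) or 1.0
    result = least_squares(
        lambda p: gompertz(x, p[0], p[1]) - y,
        x0=[b0, 1.0],
        bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
        x_scale=[scale, 1.0],
    )
    if not result.success:
        raise RuntimeError(f"Gompertz fit did not converge: {result.message}")
    b, c = result.x
    return GompertzFit(b=float(b), c=float(c), rss=float(2.0 * result.cost))


# ---------------------------------------------------------------------------
# Cluster observables
# ---------------------------------------------------------------------------


def radius_of_gyration(positions: np.ndarray) -> float:
    """RMS distance of all cell centers from their centroid.

    Every cell counts, whether or not it is still attached to the main
    group; the statistic tracks cluster spreading as a whole.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size == 0:
        raise ValueError("radius_of_gyration of an empty set")
    centroid = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=1))))


def mean_overlapping_neighbors(positions: np.ndarray, R: float) -> float:
    """Average number of overlapping neighbors (center distance < 2R)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if n == 0:
        raise ValueError("mean_overlapping_neighbors of an empty set")
    if n == 1:
        return 0.0
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    overlap = (d < 2.0 * R) & ~np.eye(n, dtype=bool)
    return float(overlap.sum(axis=1).mean())
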