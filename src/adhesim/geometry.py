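"""Sphere-surface receptor placement and geometric predicates.

Cells are rigid spheres that cannot rotate, so a receptor site is stored as
a unit direction in the cell's body frame and its world position is always
``center + R * direction``.  All predicates here are pure functions of
positions and radii.

Boundary conventions (measure-zero cases, fixed once): a site is *inside*
another cell's overlap region only strictly (``< radius``); tangent cells
(center distance exactly ``2R``) are non-overlapping and their sites count
as exposed to the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellState",
    "sample_uniform_sphere",
    "site_world_positions",
    "in_overlap_region",
    "is_exposed",
    "cells_overlap",
]


@dataclass
class CellState:
    """One spherical cell: center, radius, and its two receptor site sets.

    ``cc_dirs`` / ``cm_dirs`` are ``(n, 3)`` arrays of unit vectors (cell-cell
    adhesion receptors and cell-matrix traction receptors respectively).
    """

    center: np.ndarray
    radius: float
    cc_dirs: np.ndarray
    cm_dirs: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.cc_dirs = np.asarray(self.cc_dirs, dtype=float).reshape(-1, 3)
        self.cm_dirs = np.asarray(self.cm_dirs, dtype=float).reshape(-1, 3)
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius!r}")

    @property
    def cc_positions(self) -> np.ndarray:
        return site_world_positions(self.center, self.radius, self.cc_dirs)

    @property
    def cm_positions(self) -> np.ndarray:
        return site_world_positions(self.center, self.radius, self.cm_dirs)


def sample_uniform_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` directions uniformly on the unit sphere.

    Normalizes independent standard-normal triples (redrawing the
    numerically-zero vectors), which is exactly uniform by the rotational
    invariance of the Gaussian.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    dirs = np.empty((n, 3), dtype=float)
    todo = np.arange(n)
    while todo.size:
        draw = rng.standard_normal((todo.size, 3))
        norms = np.linalg.norm(draw, axis=1)
        ok = norms > 1e-12
        dirs[todo[ok]] = draw[ok] / norms[ok, None]
        todo = todo[~ok]
    return dirs


def site_world_positions(
    center: np.ndarray, radius: float, directions: np.ndarray
) -> np.ndarray:
    """World coordinates of surface sites: ``center + radius * direction``."""
    return np.asarray(center, float) + radius * np.asarray(directions, float)


def in_overlap_region(site_pos: np.ndarray, other: CellState) -> np.ndarray | bool:
    """Whether site position(s) lie strictly inside ``other``'s sphere.

    Accepts a single position or an ``(n, 3)`` array; returns a bool or a
    boolean array accordingly.
    """
    pos = np.asarray(site_pos, dtype=float)
    d = np.linalg.norm(pos - other.center, axis=-1)
    inside = d < other.radius
    return bool(inside) if pos.ndim == 1 else inside


def is_exposed(site_pos: np.ndarray, others: list[CellState]) -> np.ndarray | bool:
    """Whether site position(s) are exposed to the matrix.

    A site is exposed iff it lies inside no other cell; only exposed C-M
    sites generate traction.
    """
    pos = np.asarray(site_pos, dtype=float)
    exposed = np.ones(pos.shape[:-1] or (), dtype=bool)
    for other in others:
        exposed &= ~np.asarray(in_overlap_region(pos, other))
    return bool(exposed) if pos.ndim == 1 else exposed


def cells_overlap(a: CellState, b: CellState) -> bool:
    """Whether two spheres interpenetrate (tangency is not overlap)."""
    d = float(np.linalg.norm(a.center - b.center))
    return d < a.radius + b.radius
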