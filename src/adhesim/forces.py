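"""The four force contributions of the overdamped force balance.

Every cell obeys, at each instant,

    F_adh + F_trac + F_rep + F_drag = 0,      F_drag = -6*pi*eta*R * v,

so the velocity is the net active force divided by the Stokes drag.  The
three active contributions are:

* **Adhesion** between paired cell-cell (C-C) receptor sites.  Sites outside
  the overlap region engage one-to-one across cells (nearest available
  partner within the cutoff ``r_cut``); each engaged pair pulls the two cell
  centers together with the linear law
  ``(sigma_pair / r_cut**2) * (r_cut - s)`` along the line of the two sites,
  where ``s`` is the site-site distance.  Sites trapped inside the
  lens-shaped overlap region of two cells instead contribute in bulk: only
  the minimum of the two trapped counts participates (sites must be paired
  to pull), with magnitude ``(sigma_pair / r_cut) * min(m_i, m_j)`` along
  the line of centers.  ``sigma_pair`` is the per-engaged-pair energy scale;
  the model's adhesion budget ``sigma0`` is shared across the ``n_cc`` sites
  of a cell, so the dynamics resolves ``sigma_pair = sigma(t) / n_cc``.
* **Traction**: each C-M receptor site exposed to the matrix (inside no
  other cell) pushes its cell radially outward with force ``K * f_lr``
  along the surface normal at the site.  A uniformly covered isolated
  sphere would feel zero net traction; the finite random site placement
  leaves an O(sqrt(n_cm)) resultant that propels the cell.
* **Repulsion** between overlapping spheres: linear in the center distance,
  ``(eps / (2R)**2) * (2R - d)`` for ``d`` between the incompressible core
  diameter ``2R(1-alpha)`` and contact ``2R``, and a large capped wall force
  inside the core.

All forces are applied at cell centers (cells cannot rotate) and every
pairwise term is applied with its exact reaction, so internal forces
conserve the center of mass to roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import CellState

__all__ = [
    "PairingSet",
    "ForceBreakdown",
    "StepRandomness",
    "SystemForces",
    "negotiate_pairings",
    "site_pair_adhesion_force",
    "overlap_adhesion_force",
    "total_adhesion",
    "traction_force",
    "repulsion_force",
    "net_velocity",
    "greedy_distance_matching",
    "system_forces",
]


# ---------------------------------------------------------------------------
# Pairing negotiation
# ---------------------------------------------------------------------------


@dataclass
class PairingSet:
    """Negotiated C-C interactions between one pair of cells.

    ``matches`` holds ``(site_on_i, site_on_j)`` index pairs engaged
    one-to-one outside the overlap region, each with site-site distance
    ``<= r_cut``; ``m_i`` / ``m_j`` count the sites of each cell trapped in
    the mutual overlap region.
    """

    matches: list[tuple[int, int]] = field(default_factory=list)
    m_i: int = 0
    m_j: int = 0


def greedy_distance_matching(
    s: np.ndarray,
    a_ids: np.ndarray,
    b_ids: np.ndarray,
    prio_a: np.ndarray | None = None,
    prio_b: np.ndarray | None = None,
) -> np.ndarray:
    """One-to-one greedy matching of candidate pairs in ascending distance.

    ``s[c]`` is the distance of candidate ``c`` joining endpoint ``a_ids[c]``
    to endpoint ``b_ids[c]`` (ids from two disjoint namespaces).  Candidates
    are taken shortest-first; a candidate is accepted iff neither endpoint is
    already engaged.  Exact distance ties are broken by the optional priority
    arrays (lower first), so a randomized priority yields an unbiased tie
    order while leaving the generic (tie-free) outcome deterministic.

    Returns the indices of accepted candidates, in acceptance order.
    """
    m = s.shape[0]
    if m == 0:
        return np.empty(0, dtype=np.intp)
    if prio_a is None:
        prio_a = np.zeros(m)
    if prio_b is None:
        prio_b = np.zeros(m)
    order = np.lexsort((prio_b, prio_a, s))
    sa = a_ids[order].tolist()
    sb = b_ids[order].tolist()
    a_taken: set[int] = set()
    b_taken: set[int] = set()
    accepted: list[int] = []
    for c in range(m):
        a, b = sa[c], sb[c]
        if a not in a_taken and b not in b_taken:
            a_taken.add(a)
            b_taken.add(b)
            accepted.append(c)
    return order[np.asarray(accepted, dtype=np.intp)] if accepted else np.empty(
        0, np.intp
    )


def negotiate_pairings(
    cell_i: CellState,
    cell_j: CellState,
    r_cut: float,
    rng: np.random.Generator | None = None,
) -> PairingSet:
    """Partition and match the C-C sites of two cells for one force epoch.

    Sites strictly inside the partner's sphere are trapped (counted into
    ``m_i`` / ``m_j``); the remaining free sites engage one-to-one by
    shortest site-site distance within ``r_cut``
    (:func:`greedy_distance_matching`), with ``rng`` supplying the random
    tie-break priorities drawn once per epoch.
    """
    if cell_i is cell_j:
        raise ValueError("negotiate_pairings requires two distinct cells")
    pos_i, pos_j = cell_i.cc_positions, cell_j.cc_positions
    trapped_i = np.linalg.norm(pos_i - cell_j.center, axis=1) < cell_j.radius
    trapped_j = np.linalg.norm(pos_j - cell_i.center, axis=1) < cell_i.radius
    free_i = np.nonzero(~trapped_i)[0]
    free_j = np.nonzero(~trapped_j)[0]
    out = PairingSet(m_i=int(trapped_i.sum()), m_j=int(trapped_j.sum()))
    if free_i.size and free_j.size:
        d = cdist(pos_i[free_i], pos_j[free_j])
        ck, cl = np.nonzero(d <= r_cut)
        if ck.size:
            if rng is not None:
                perm_i = rng.permutation(pos_i.shape[0]).astype(float)
                perm_j = rng.permutation(pos_j.shape[0]).astype(float)
            else:
                perm_i = np.arange(pos_i.shape[0], dtype=float)
                perm_j = np.arange(pos_j.shape[0], dtype=float)
            a, b = free_i[ck], free_j[cl]
            keep = greedy_distance_matching(
                d[ck, cl], a, b, perm_i[a], perm_j[b]
            )
            out.matches = [(int(a[c]), int(b[c])) for c in keep]
    return out


# ---------------------------------------------------------------------------
# Individual force laws
# ---------------------------------------------------------------------------


def site_pair_adhesion_force(
    pos_k: np.ndarray, pos_l: np.ndarray, sigma_pair: float, r_cut: float
) -> np.ndarray:
    """Attractive force on site ``k``'s cell from one engaged site pair.

    Linear in the site separation ``s``: magnitude
    ``(sigma_pair / r_cut**2) * (r_cut - s)``, pointing from ``k`` toward
    ``l``; zero at and beyond the cutoff, and zero for coincident sites
    (direction undefined, measure-zero).
    """
    delta = np.asarray(pos_l, float) - np.asarray(pos_k, float)
    s = float(np.linalg.norm(delta))
    if s == 0.0 or s > r_cut:
        return np.zeros(3)
    return (sigma_pair / r_cut**2) * (r_cut - s) / s * delta


def overlap_adhesion_force(
    m_i: int, m_j: int, sigma_pair: float, r_cut: float, n_ij: np.ndarray
) -> np.ndarray:
    """Bulk adhesion on cell ``i`` from sites trapped in the overlap region.

    Only the minimum of the two trapped counts participates (unpaired sites
    are inactive); magnitude ``(sigma_pair / r_cut) * min(m_i, m_j)`` along
    the center line toward the partner (``+n_ij``).
    """
    if m_i < 0 or m_j < 0:
        raise ValueError("trapped site counts must be nonnegative")
    return (sigma_pair / r_cut) * min(m_i, m_j) * np.asarray(n_ij, float)


def total_adhesion(
    cell_i: CellState,
    neighbors: list[CellState],
    pairings: list[PairingSet],
    sigma_pair: float,
    r_cut: float,
) -> np.ndarray:
    """Net adhesion on ``cell_i``: engaged-pair pulls plus overlap terms.

    ``pairings[k]`` must be the :class:`PairingSet` negotiated between
    ``cell_i`` (in the *i* role) and ``neighbors[k]``.
    """
    force = np.zeros(3)
    for neighbor, pairing in zip(neighbors, pairings):
        pos_i, pos_j = cell_i.cc_positions, neighbor.cc_positions
        for k, l in pairing.matches:
            force += site_pair_adhesion_force(
                pos_i[k], pos_j[l], sigma_pair, r_cut
            )
        delta = neighbor.center - cell_i.center
        d = float(np.linalg.norm(delta))
        if d > 0 and min(pairing.m_i, pairing.m_j) > 0:
            force += overlap_adhesion_force(
                pairing.m_i, pairing.m_j, sigma_pair, r_cut, delta / d
            )
    return force


def traction_force(
    cell_i: CellState, others: list[CellState], K: float, f_lr: float
) -> np.ndarray:
    """Net traction on ``cell_i`` from its matrix-exposed C-M sites.

    Each exposed site contributes ``K * f_lr`` along the outward surface
    normal at the site; sites trapped in an overlap region are inactive.
    """
    if cell_i.cm_dirs.shape[0] == 0:
        return np.zeros(3)
    pos = cell_i.cm_positions
    exposed = np.ones(pos.shape[0], dtype=bool)
    for other in others:
        if other is cell_i:
            continue
        exposed &= np.linalg.norm(pos - other.center, axis=1) >= other.radius
    return K * f_lr * cell_i.cm_dirs[exposed].sum(axis=0)


def repulsion_force(
    cell_i: CellState,
    cell_j: CellState,
    eps: float,
    R: float,
    alpha: float,
    wall_force_cap: float,
) -> np.ndarray:
    """Repulsion on ``cell_i`` from an overlapping ``cell_j``.

    Zero at and beyond contact ``d = 2R``; linear
    ``(eps / (2R)**2) * (2R - d)`` between the core and contact; the capped
    wall magnitude at or inside the core diameter ``2R(1-alpha)``.
    Directed from ``j`` toward ``i``.
    """
    delta = cell_i.center - cell_j.center
    d = float(np.linalg.norm(delta))
    if d == 0.0:
        raise ValueError("coincident cell centers: repulsion direction undefined")
    two_r = 2.0 * R
    if d >= two_r:
        return np.zeros(3)
    d_core = two_r * (1.0 - alpha)
    if d <= d_core:
        mag = wall_force_cap
    else:
        mag = eps / two_r**2 * (two_r - d)
    return mag / d * delta


@dataclass
class ForceBreakdown:
    """Per-cell force decomposition (adhesion, traction, repulsion)."""

    adhesion: np.ndarray
    traction: np.ndarray
    repulsion: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.adhesion + self.traction + self.repulsion


def net_velocity(breakdown: ForceBreakdown, eta: float, R: float) -> np.ndarray:
    """Overdamped velocity: total active force over the Stokes drag."""
    if eta <= 0 or R <= 0:
        raise ValueError("eta and R must be positive")
    return breakdown.total / (6.0 * np.pi * eta * R)


# ---------------------------------------------------------------------------
# Vectorized whole-system evaluation (used by the integrator)
# ---------------------------------------------------------------------------


@dataclass
class StepRandomness:
    """Random draws frozen for the duration of one integration step.

    ``cc_prio`` gives each C-C site a random tie-break priority for the
    matching; ``trap_u`` is one uniform per C-C site used to pick, for a
    site trapped in several cells' overlap regions at once, the neighbor it
    is counted against.  Both are drawn once per step so the four
    Runge-Kutta stage evaluations see a deterministic field.
    """

    cc_prio: np.ndarray  # (n_cells, n_cc) float priorities
    trap_u: np.ndarray  # (n_cells, n_cc) uniforms in [0, 1)

    @classmethod
    def draw(
        cls, n_cells: int, n_cc: int, rng: np.random.Generator
    ) -> "StepRandomness":
        prio = np.empty((n_cells, n_cc))
        for c in range(n_cells):
            prio[c] = rng.permutation(n_cc)
        return cls(cc_prio=prio, trap_u=rng.random((n_cells, n_cc)))

    @classmethod
    def identity(cls, n_cells: int, n_cc: int) -> "StepRandomness":
        prio = np.tile(np.arange(n_cc, dtype=float), (n_cells, 1))
        return cls(cc_prio=prio, trap_u=np.zeros((n_cells, n_cc)))


@dataclass
class SystemForces:
    """Stacked ``(n_cells, 3)`` force arrays for a whole configuration."""

    adhesion: np.ndarray
    traction: np.ndarray
    repulsion: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.adhesion + self.traction + self.repulsion


def _trapped_assignment(
    inside: np.ndarray, neighbor_ids: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Assign each trapped site to one of its enclosing neighbors.

    ``inside`` is ``(n_sites, n_neighbors)`` membership; a site inside
    several neighbors is counted against the one selected by its frozen
    uniform ``u`` (uniform over the eligible neighbors, ordered by cell
    index).  Returns the chosen neighbor cell id per site, or -1 for free
    sites.
    """
    n_sites = inside.shape[0]
    chosen = np.full(n_sites, -1, dtype=np.intp)
    counts = inside.sum(axis=1)
    for k in np.nonzero(counts)[0]:
        elig = neighbor_ids[inside[k]]
        pick = min(int(u[k] * elig.size), elig.size - 1)
        chosen[k] = elig[pick]
    return chosen


def system_forces(
    centers: np.ndarray,
    cc_dirs: np.ndarray,
    cm_dirs: np.ndarray,
    *,
    R: float,
    r_cut: float,
    sigma_pair: float,
    eps: float,
    alpha: float,
    K: float,
    f_lr: float,
    wall_force_cap: float,
    step_rand: StepRandomness | None = None,
) -> SystemForces:
    """Evaluate adhesion, traction and repulsion for every cell at once.

    ``centers`` is ``(n, 3)``; ``cc_dirs`` / ``cm_dirs`` are
    ``(n, n_cc, 3)`` / ``(n, n_cm, 3)`` body-frame unit vectors.
    ``sigma_pair`` is the per-engaged-pair adhesion scale (the cell budget
    already divided by ``n_cc``).  ``step_rand`` carries the step-frozen
    random draws; ``None`` uses deterministic site-index order (useful for
    tests).

    The decomposition matches summing the per-cell operations above, but is
    evaluated with a single global shortest-first matching so that a site
    engages at most one partner across *all* neighbors.
    """
    n, n_cc = cc_dirs.shape[0], cc_dirs.shape[1]
    n_cm = cm_dirs.shape[1]
    adhesion = np.zeros((n, 3))
    traction = np.zeros((n, 3))
    repulsion = np.zeros((n, 3))
    if n == 0:
        return SystemForces(adhesion, traction, repulsion)
    if step_rand is None:
        step_rand = StepRandomness.identity(n, n_cc)

    delta = centers[:, None, :] - centers[None, :, :]
    dist = np.linalg.norm(delta, axis=2)
    two_r = 2.0 * R
    d_core = two_r * (1.0 - alpha)

    iu, ju = np.triu_indices(n, k=1)
    pd = dist[iu, ju]

    # --- repulsion over overlapping pairs ---------------------------------
    for i, j, d in zip(iu[pd < two_r], ju[pd < two_r], pd[pd < two_r]):
        if d == 0.0:
            raise ValueError(f"coincident centers for cells {i} and {j}")
        mag = wall_force_cap if d <= d_core else eps / two_r**2 * (two_r - d)
        f = mag / d * (centers[i] - centers[j])
        repulsion[i] += f
        repulsion[j] -= f

    # --- site bookkeeping: world positions, trapping, exposure ------------
    cc_pos = centers[:, None, :] + R * cc_dirs if n_cc else None
    overlap_neighbors = [
        np.nonzero((dist[i] < two_r) & (np.arange(n) != i))[0] for i in range(n)
    ]

    trapped_by = np.full((n, n_cc), -1, dtype=np.intp) if n_cc else None
    if n_cc:
        for i in range(n):
            nbrs = overlap_neighbors[i]
            if nbrs.size == 0:
                continue
            # (n_cc, n_nbrs) strict membership in each neighbor's sphere
            d_site = np.linalg.norm(
                cc_pos[i][:, None, :] - centers[nbrs][None, :, :], axis=2
            )
            trapped_by[i] = _trapped_assignment(
                d_site < R, nbrs, step_rand.trap_u[i]
            )

    # --- traction from exposed C-M sites -----------------------------------
    if n_cm and K * f_lr != 0.0:
        for i in range(n):
            nbrs = overlap_neighbors[i]
            pos = centers[i] + R * cm_dirs[i]
            if nbrs.size:
                d_site = np.linalg.norm(
                    pos[:, None, :] - centers[nbrs][None, :, :], axis=2
                )
                exposed = (d_site >= R).all(axis=1)
            else:
                exposed = np.ones(n_cm, dtype=bool)
            traction[i] = K * f_lr * cm_dirs[i][exposed].sum(axis=0)

    # --- overlap (trapped-count) adhesion ----------------------------------
    if n_cc and sigma_pair != 0.0:
        for i, j, d in zip(iu[pd < two_r], ju[pd < two_r], pd[pd < two_r]):
            m_ij = int((trapped_by[i] == j).sum())
            m_ji = int((trapped_by[j] == i).sum())
            m = min(m_ij, m_ji)
            if m and d > 0:
                f = (sigma_pair / r_cut) * m / d * (centers[j] - centers[i])
                adhesion[i] += f
                adhesion[j] -= f

    # --- one-to-one site adhesion over the global matching -----------------
    if n_cc and sigma_pair != 0.0:
        cand_a: list[np.ndarray] = []
        cand_b: list[np.ndarray] = []
        cand_s: list[np.ndarray] = []
        reach = two_r + r_cut
        free = trapped_by < 0  # (n, n_cc)
        for i, j, d in zip(iu[pd < reach], ju[pd < reach], pd[pd < reach]):
            fi = np.nonzero(free[i])[0]
            fj = np.nonzero(free[j])[0]
            if fi.size == 0 or fj.size == 0:
                continue
            s = cdist(cc_pos[i][fi], cc_pos[j][fj])
            ck, cl = np.nonzero(s <= r_cut)
            if ck.size:
                cand_a.append(i * n_cc + fi[ck])
                cand_b.append(j * n_cc + fj[cl])
                cand_s.append(s[ck, cl])
        if cand_a:
            a_ids = np.concatenate(cand_a)
            b_ids = np.concatenate(cand_b)
            s_all = np.concatenate(cand_s)
            prio = step_rand.cc_prio.ravel()
            keep = greedy_distance_matching(
                s_all, a_ids, b_ids, prio[a_ids], prio[b_ids]
            )
            if keep.size:
                a_cell, a_site = np.divmod(a_ids[keep], n_cc)
                b_cell, b_site = np.divmod(b_ids[keep], n_cc)
                pa = cc_pos[a_cell, a_site]
                pb = cc_pos[b_cell, b_site]
                dvec = pb - pa
                s = np.linalg.norm(dvec, axis=1)
                ok = s > 0
                mag = np.zeros_like(s)
                mag[ok] = sigma_pair / r_cut**2 * (r_cut - s[ok]) / s[ok]
                fvec = mag[:, None] * dvec
                np.add.at(adhesion, a_cell, fvec)
                np.add.at(adhesion, b_cell, -fvec)

    return SystemForces(adhesion, traction, repulsion)
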