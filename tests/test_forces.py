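import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adhesim import (
    ForceBreakdown,
    StepRandomness,
    greedy_distance_matching,
    negotiate_pairings,
    net_velocity,
    overlap_adhesion_force,
    repulsion_force,
    site_pair_adhesion_force,
    system_forces,
    total_adhesion,
    traction_force,
)
from adhesim.geometry import CellState

from conftest import random_cell


def brute_force_greedy(candidates):
    """Independent oracle: shortest-first one-to-one matching, pure python.

    ``candidates`` is a list of (s, prio_a, prio_b, a, b) tuples.
    """
    taken_a, taken_b, out = set(), set(), []
    for s, pa, pb, a, b in sorted(candidates):
        if a not in taken_a and b not in taken_b:
            taken_a.add(a)
            taken_b.add(b)
            out.append((a, b))
    return sorted(out)


class TestMatching:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 25))
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = rng.integers(0, na, m)
            b = rng.integers(0, nb, m)
            s = rng.random(m)
            pa = rng.permutation(na).astype(float)
            pb = rng.permutation(nb).astype(float)
            keep = greedy_distance_matching(s, a, b, pa[a], pb[b])
            got = sorted(zip(a[keep].tolist(), b[keep].tolist()))
            want = brute_force_greedy(
                [(s[c], pa[a[c]], pb[b[c]], int(a[c]), int(b[c])) for c in range(m)]
            )
            assert got == want

    def test_one_to_one_exclusivity(self, rng):
        m = 200
        a = rng.integers(0, 10, m)
        b = rng.integers(0, 10, m)
        keep = greedy_distance_matching(rng.random(m), a, b)
        assert len(set(a[keep])) == keep.size
        assert len(set(b[keep])) == keep.size


class TestNegotiation:
    def test_single_pair_within_cutoff(self):
        ci = CellState(np.zeros(3), 1.0, np.array([[1.0, 0, 0]]), np.zeros((0, 3)))
        cj = CellState(np.array([2.4, 0, 0]), 1.0, np.array([[-1.0, 0, 0]]), np.zeros((0, 3)))
        ps = negotiate_pairings(ci, cj, r_cut=1.0)
        assert ps.matches == [(0, 0)] and ps.m_i == ps.m_j == 0

    def test_beyond_cutoff_no_matches(self):
        ci = CellState(np.zeros(3), 1.0, np.array([[1.0, 0, 0]]), np.zeros((0, 3)))
        cj = CellState(np.array([4.0, 0, 0]), 1.0, np.array([[-1.0, 0, 0]]), np.zeros((0, 3)))
        assert negotiate_pairings(ci, cj, r_cut=1.0).matches == []

    def test_trapped_sites_counted_not_matched(self, rng):
        ci = random_cell(rng, [0, 0, 0], n_cc=30)
        cj = random_cell(rng, [1.2, 0, 0], n_cc=30)
        ps = negotiate_pairings(ci, cj, r_cut=1.0, rng=rng)
        trapped_i = {
            k
            for k, pos in enumerate(ci.cc_positions)
            if np.linalg.norm(pos - cj.center) < 1.0
        }
        assert ps.m_i == len(trapped_i)
        for k, l in ps.matches:
            assert k not in trapped_i
            s = np.linalg.norm(ci.cc_positions[k] - cj.cc_positions[l])
            assert s <= 1.0

    def test_matches_are_mutually_exclusive(self, rng):
        ci = random_cell(rng, [0, 0, 0], n_cc=40)
        cj = random_cell(rng, [2.1, 0, 0], n_cc=40)
        ps = negotiate_pairings(ci, cj, r_cut=1.0, rng=rng)
        ks = [k for k, _ in ps.matches]
        ls = [l for _, l in ps.matches]
        assert len(set(ks)) == len(ks) and len(set(ls)) == len(ls)


class TestSitePairAdhesion:
    def test_cutoff_boundary_zero(self):
        f = site_pair_adhesion_force([0, 0, 0], [1.0, 0, 0], 0.004, 1.0)
        np.testing.assert_array_equal(f, np.zeros(3))

    def test_linear_law_midpoint(self):
        f = site_pair_adhesion_force([0, 0, 0], [0.5, 0, 0], 0.004, 1.0)
        np.testing.assert_allclose(f, [0.002, 0, 0], atol=1e-15)

    def test_action_reaction(self, rng):
        a, b = rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)
        f_ab = site_pair_adhesion_force(a, b, 0.004, 1.5)
        f_ba = site_pair_adhesion_force(b, a, 0.004, 1.5)
        np.testing.assert_allclose(f_ab, -f_ba, atol=1e-16)

    def test_coincident_sites_zero(self):
        f = site_pair_adhesion_force([1, 2, 3], [1, 2, 3], 0.004, 1.0)
        np.testing.assert_array_equal(f, np.zeros(3))


class TestOverlapAdhesion:
    def test_unpaired_sites_inactive(self):
        f = overlap_adhesion_force(0, 7, 0.004, 1.0, np.array([1.0, 0, 0]))
        np.testing.assert_array_equal(f, np.zeros(3))

    def test_min_rule_magnitude(self):
        f = overlap_adhesion_force(3, 5, 0.004, 1.0, np.array([0, 1.0, 0]))
        np.testing.assert_allclose(f, [0, 0.012, 0], atol=1e-15)

    def test_swap_negates(self):
        n = np.array([0.6, 0.8, 0.0])
        f_ij = overlap_adhesion_force(3, 5, 0.004, 1.0, n)
        f_ji = overlap_adhesion_force(5, 3, 0.004, 1.0, -n)
        np.testing.assert_allclose(f_ij, -f_ji, atol=1e-16)


class TestTraction:
    def test_single_site_exact(self):
        u = np.array([0.0, 0.0, 1.0])
        cell = CellState(np.zeros(3), 1.0, np.zeros((0, 3)), u[None, :])
        f = traction_force(cell, [], K=1.0, f_lr=0.01)
        assert np.array_equal(f, 0.01 * u)

    def test_antipodal_pair_cancels(self):
        dirs = np.array([[0.0, 0, 1], [0.0, 0, -1]])
        cell = CellState(np.zeros(3), 1.0, np.zeros((0, 3)), dirs)
        np.testing.assert_allclose(
            traction_force(cell, [], 1.0, 0.01), np.zeros(3), atol=1e-15
        )

    def test_trapped_sites_generate_no_traction(self, rng):
        cell = CellState(
            np.zeros(3), 1.0, np.zeros((0, 3)), np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        )
        neighbor = random_cell(rng, [1.5, 0, 0])
        # the +x site sits inside the neighbor; only the -x site remains
        f = traction_force(cell, [neighbor], 1.0, 0.01)
        np.testing.assert_allclose(f, [-0.01, 0, 0], atol=1e-15)


class TestRepulsion:
    def setup_method(self):
        self.kw = dict(eps=0.025, R=1.0, alpha=0.5, wall_force_cap=1e3)

    def cells(self, d, rng=None):
        mk = lambda c: CellState(np.array(c, float), 1.0, np.zeros((0, 3)), np.zeros((0, 3)))
        return mk([0, 0, 0]), mk([d, 0, 0])

    def test_contact_boundary_zero(self):
        a, b = self.cells(2.0)
        np.testing.assert_array_equal(repulsion_force(a, b, **self.kw), np.zeros(3))

    def test_linear_regime_magnitude(self):
        a, b = self.cells(1.5)
        f = repulsion_force(a, b, **self.kw)
        np.testing.assert_allclose(f, [-0.025 * 0.5 / 4.0, 0, 0], atol=1e-15)

    def test_wall_regime_capped(self):
        a, b = self.cells(0.9)  # core diameter is 1.0
        f = repulsion_force(a, b, **self.kw)
        np.testing.assert_allclose(np.linalg.norm(f), 1e3)
        assert f[0] < 0  # pushes a away from b

    def test_coincident_centers_error(self):
        a, b = self.cells(0.0)
        with pytest.raises(ValueError):
            repulsion_force(a, b, **self.kw)


class TestNetVelocity:
    def test_zero_force_zero_velocity(self):
        bd = ForceBreakdown(np.zeros(3), np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(net_velocity(bd, 0.0016, 1.0), np.zeros(3))

    def test_stokes_arithmetic(self):
        f = np.array([6 * np.pi * 0.0016, 0, 0])
        bd = ForceBreakdown(f, np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(net_velocity(bd, 0.0016, 1.0), [1, 0, 0], rtol=1e-14)

    @given(scale=st.floats(0.5, 4.0))
    def test_linearity_in_viscosity(self, scale):
        bd = ForceBreakdown(np.array([1.0, 2, 3]), np.zeros(3), np.zeros(3))
        v1 = net_velocity(bd, 0.0016, 1.0)
        v2 = net_velocity(bd, 0.0016 * scale, 1.0)
        np.testing.assert_allclose(v2 * scale, v1, rtol=1e-12)


class TestTotalAdhesionAndSystem:
    def test_no_neighbors_zero(self, rng):
        cell = random_cell(rng, [0, 0, 0])
        np.testing.assert_array_equal(
            total_adhesion(cell, [], [], 0.004, 1.0), np.zeros(3)
        )

    def test_pair_adhesion_sums_to_zero(self, rng):
        for _ in range(20):
            d = rng.uniform(1.2, 3.0)
            ci = random_cell(rng, [0, 0, 0], n_cc=12)
            cj = random_cell(rng, [d, 0, 0], n_cc=12)
            ps_ij = negotiate_pairings(ci, cj, 1.0)
            ps_ji = negotiate_pairings(cj, ci, 1.0)
            f_i = total_adhesion(ci, [cj], [ps_ij], 0.004, 1.0)
            f_j = total_adhesion(cj, [ci], [ps_ji], 0.004, 1.0)
            assert np.linalg.norm(f_i + f_j) <= 1e-12

    def test_system_forces_match_per_cell_composition(self, rng):
        """Dual route: the vectorized whole-system evaluation must agree with
        composing the per-cell operations, on a 3-cell chain whose candidate
        sets do not straddle more than one neighbor."""
        centers = np.array([[0.0, 0, 0], [2.2, 0, 0], [4.4, 0, 0]])
        cells = [random_cell(rng, c, n_cc=20, n_cm=15) for c in centers]
        cc = np.stack([c.cc_dirs for c in cells])
        cm = np.stack([c.cm_dirs for c in cells])
        kw = dict(R=1.0, r_cut=1.0, sigma_pair=4e-5, eps=0.025, alpha=0.5,
                  K=1.0, f_lr=0.01, wall_force_cap=1e3)
        sf = system_forces(centers, cc, cm,
                           step_rand=StepRandomness.identity(3, 20), **kw)
        for i, cell in enumerate(cells):
            others = [c for j, c in enumerate(cells) if j != i]
            pairings = [negotiate_pairings(cell, o, 1.0) for o in others]
            adh = total_adhesion(cell, others, pairings, 4e-5, 1.0)
            trac = traction_force(cell, others, 1.0, 0.01)
            np.testing.assert_allclose(sf.adhesion[i], adh, atol=1e-14)
            np.testing.assert_allclose(sf.traction[i], trac, atol=1e-14)

    def test_distant_cells_exert_no_force(self, rng):
        centers = np.array([[0.0, 0, 0], [3.0 + 1e-9, 0, 0]])
        cells = [random_cell(rng, c, n_cc=20, n_cm=10) for c in centers]
        sf = system_forces(
            centers,
            np.stack([c.cc_dirs for c in cells]),
            np.stack([c.cm_dirs for c in cells]),
            R=1.0, r_cut=1.0, sigma_pair=4e-5, eps=0.025, alpha=0.5,
            K=1.0, f_lr=0.0, wall_force_cap=1e3,
        )
        np.testing.assert_array_equal(sf.adhesion, np.zeros((2, 3)))
        np.testing.assert_array_equal(sf.repulsion, np.zeros((2, 3)))
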