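"""Hines tree solver: dense-oracle equivalence, orderings, O(n) contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cajal.errors import SingularSystemError
from cajal.solver import (TreeSystem, assemble_voltage_system, hines_solve,
                          make_ordering, permute_system)


def random_tree_system(rng, n):
    parent = np.array([-1] + [int(rng.integers(0, i)) for i in range(1, n)])
    d = rng.uniform(2.0, 4.0, n)
    a = -rng.uniform(0.1, 1.0, n)
    b = -rng.uniform(0.1, 1.0, n)
    a[0] = b[0] = 0.0
    rhs = rng.standard_normal(n)
    return TreeSystem(parent=parent, d=d, a=a, b=b, rhs=rhs)


class TestHinesSolve:
    def test_identity_system(self):
        sys = TreeSystem(parent=np.array([-1, 0, 0]), d=np.ones(3),
                         a=np.zeros(3), b=np.zeros(3),
                         rhs=np.array([3.0, -1.0, 2.0]))
        x = hines_solve(sys)
        np.testing.assert_allclose(x, [3.0, -1.0, 2.0])

    def test_three_node_chain_matches_dense(self):
        sys = TreeSystem(parent=np.array([-1, 0, 1]),
                         d=np.array([2.0, 2.0, 2.0]),
                         a=np.array([0.0, -1.0, -1.0]),
                         b=np.array([0.0, -1.0, -1.0]),
                         rhs=np.array([1.0, 0.0, 1.0]))
        dense = sys.dense()
        x = hines_solve(sys)
        np.testing.assert_allclose(x, np.linalg.solve(dense, [1.0, 0.0, 1.0]),
                                   atol=1e-12)

    def test_hundred_random_trees_vs_dense_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 257))
            sys = random_tree_system(rng, n)
            dense = sys.dense()
            rhs0 = sys.rhs.copy()
            x = hines_solve(sys)
            x_dense = np.linalg.solve(dense, rhs0)
            scale = np.max(np.abs(x_dense))
            assert np.max(np.abs(x - x_dense)) <= 1e-9 * scale
            assert sys.division_count == n

    def test_exactly_n_divisions(self, rng):
        sys = random_tree_system(rng, 57)
        hines_solve(sys)
        assert sys.division_count == 57

    def test_zero_pivot_raises(self):
        sys = TreeSystem(parent=np.array([-1, 0]), d=np.array([1.0, 0.0]),
                         a=np.array([0.0, -0.5]), b=np.array([0.0, -0.5]),
                         rhs=np.ones(2))
        with pytest.raises(SingularSystemError):
            hines_solve(sys)

    def test_unbranched_cable_reduces_to_thomas(self, rng):
        """On a chain the method is the Thomas algorithm: same solution as
        scipy's banded tridiagonal solver."""
        from scipy.linalg import solve_banded

        n = 64
        parent = np.arange(-1, n - 1)
        d = rng.uniform(2.0, 3.0, n)
        a = -rng.uniform(0.1, 1.0, n)
        a[0] = 0.0
        rhs = rng.standard_normal(n)
        sys = TreeSystem(parent=parent, d=d, a=a, b=a.copy(), rhs=rhs.copy())
        ab = np.zeros((3, n))
        ab[0, 1:] = a[1:]
        ab[1] = d
        ab[2, :-1] = a[1:]
        expected = solve_banded((1, 1), ab, rhs)
        np.testing.assert_allclose(hines_solve(sys), expected, rtol=1e-12)

    def test_parent_ordering_enforced(self):
        with pytest.raises(ValueError):
            TreeSystem(parent=np.array([1, -1]), d=np.ones(2),
                       a=np.zeros(2), b=np.zeros(2), rhs=np.ones(2))


class TestOrdering:
    def test_identity_permutation(self):
        parent = np.array([-1, 0, 1])
        o = make_ordering(parent, scheme="identity")
        np.testing.assert_array_equal(o.perm, [0, 1, 2])

    def test_two_chains_interleaved_level_order(self):
        parent = np.array([-1, 0, 1, -1, 3, 4])
        cells = np.array([0, 0, 0, 1, 1, 1])
        o = make_ordering(parent, cells, "cell_interleaved")
        # roots first (0,3), then depth-1 (1,4), then depth-2 (2,5)
        np.testing.assert_array_equal(o.perm, [0, 3, 1, 4, 2, 5])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_ordering(np.array([-1]), scheme="zigzag")

    def test_permuted_solve_equals_unpermuted(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 64))
            sys = random_tree_system(rng, n)
            cells = rng.integers(0, 3, n)
            # cell ids must be constant within each tree of the forest
            cells = np.zeros(n, dtype=int)
            rhs0 = sys.rhs.copy()
            x = hines_solve(TreeSystem(sys.parent, sys.d.copy(), sys.a,
                                       sys.b, rhs0.copy()))
            o = make_ordering(sys.parent, cells, "cell_interleaved")
            psys = permute_system(
                TreeSystem(sys.parent, sys.d.copy(), sys.a, sys.b, rhs0.copy()), o)
            xp = o.scatter(hines_solve(psys))
            assert np.max(np.abs(xp - x)) <= 1e-9 * max(1.0, np.max(np.abs(x)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 80), st.integers(0, 2 ** 31 - 1))
    def test_permutation_preserves_parent_before_child(self, n, seed):
        rng = np.random.default_rng(seed)
        parent = np.array([-1] + [int(rng.integers(0, i)) for i in range(1, n)])
        # label each connected tree as one cell
        cells = np.zeros(n, dtype=int)
        for i in range(1, n):
            cells[i] = cells[parent[i]]
        o = make_ordering(parent, cells, "cell_interleaved")
        new_parent = o.permute_parent(parent)
        assert np.all(new_parent < np.arange(n))
        assert sorted(o.perm) == list(range(n))


class TestAssemble:
    def test_single_passive_compartment_equilibrium(self):
        # at V = E_leak with no stimulus the implicit solve is a fixed point
        c, g, e, dt = 0.01, 0.005, -70.0, 0.025
        v = np.array([e])
        sys = assemble_voltage_system(np.array([-1]), np.array([c]),
                                      np.array([0.0]), dt, np.array([g]),
                                      np.array([g * e - 0.0]), v)
        # i_rhs = g*v - i(v); at v = e, i = 0 so i_rhs = g*e
        x = hines_solve(sys)
        np.testing.assert_allclose(x, [e], rtol=1e-12)

    def test_two_compartment_cable_matches_dense(self):
        parent = np.array([-1, 0])
        c = np.array([0.01, 0.02])
        g_ax = np.array([0.0, 0.4])
        g_mech = np.array([0.003, 0.001])
        i_rhs = np.array([0.05, -0.02])
        v = np.array([-65.0, -60.0])
        dt = 0.1
        sys = assemble_voltage_system(parent, c, g_ax, dt, g_mech, i_rhs, v)
        A = np.array([[c[0] / dt + g_mech[0] + g_ax[1], -g_ax[1]],
                      [-g_ax[1], c[1] / dt + g_mech[1] + g_ax[1]]])
        b = c / dt * v + i_rhs
        np.testing.assert_allclose(hines_solve(sys), np.linalg.solve(A, b),
                                   rtol=1e-12)

    def test_diagonal_dominance_for_passive_systems(self, rng):
        n = 30
        parent = np.array([-1] + [int(rng.integers(0, i)) for i in range(1, n)])
        c = rng.uniform(0.001, 0.1, n)
        g_ax = rng.uniform(0.1, 2.0, n)
        g_ax[0] = 0.0
        g_mech = rng.uniform(0.0, 0.01, n)
        sys = assemble_voltage_system(parent, c, g_ax, 0.025, g_mech,
                                      np.zeros(n), np.full(n, -65.0))
        child_b = np.zeros(n)
        for i in range(n):
            if parent[i] >= 0:
                child_b[parent[i]] += abs(sys.b[i])
        assert np.all(sys.d >= np.abs(sys.a) + child_b - 1e-12)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            assemble_voltage_system(np.array([-1]), np.array([1.0]),
                                    np.array([0.0]), 0.0, np.array([0.0]),
                                    np.array([0.0]), np.array([-65.0]))
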