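"""O(n) direct solver for tree-structured (Hines) linear systems.

The cable equation discretized on a neuronal tree yields, per timestep, a
sparse symmetric-pattern system whose graph is the compartment tree.  With
compartments numbered parent-before-child, Gaussian elimination from the
leaves to the root fills in nothing and needs exactly one division (one
pivot reciprocal) per node; back-substitution from the root to the leaves
completes the solve.  This is Hines' algorithm, the linear-time core of
implicit compartmental simulation.

Node renumbering ("cell permutations") changes memory layout and grouping
but must not change results; :func:`make_ordering` provides the identity
scheme and a level-interleaved scheme that packs same-depth nodes across
cells contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingularSystemError


@dataclass
class TreeSystem:
    """A x = rhs with A supported on a forest.

    Row i holds ``d[i]`` on the diagonal, ``a[i]`` in column ``parent[i]``
    (upper coupling) and, for each child c of i, ``b[c]`` in column c
    (lower coupling).  ``parent[i] < i`` with -1 for roots.
    """

    parent: np.ndarray
    d: np.ndarray
    a: np.ndarray  # coupling of node to its parent (entry in the node's row)
    b: np.ndarray  # coupling of parent to node (entry in the parent's row)
    rhs: np.ndarray
    division_count: int = 0
    _levels: list = field(default=None, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        n = len(self.parent)
        for name in ("d", "a", "b", "rhs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if np.any(self.parent >= np.arange(n)):
            raise ValueError("parent[i] < i violated")

    @property
    def n(self) -> int:
        return len(self.parent)

    def levels(self) -> list[np.ndarray]:
        """Node index groups by tree depth (cached; topology-only)."""
        if self._levels is None:
            depth = np.zeros(self.n, dtype=np.int64)
            for i in range(self.n):
                p = self.parent[i]
                depth[i] = 0 if p < 0 else depth[p] + 1
            self._levels = [np.flatnonzero(depth == lv)
                            for lv in range(int(depth.max(initial=0)) + 1)]
        return self._levels

    def dense(self) -> np.ndarray:
        """Dense matrix (for oracles and residual checks)."""
        A = np.diag(self.d.copy())
        for i in range(self.n):
            p = self.parent[i]
            if p >= 0:
                A[i, p] = self.a[i]
                A[p, i] = self.b[i]
        return A


def _hines_core(parent, d, a, b, rhs, pivot):
    """Sequential elimination + back-substitution.

    Returns the division count (one pivot reciprocal per node; all other
    updates are multiplications) or ``-(i+1)`` on a zero pivot at node i.
    """
    n = parent.shape[0]
    divisions = 0
    for i in range(n - 1, -1, -1):
        if d[i] == 0.0:
            return -(i + 1)
        pivot[i] = 1.0 / d[i]
        divisions += 1
        p = parent[i]
        if p >= 0:
            f = b[i] * pivot[i]
            d[p] -= f * a[i]
            rhs[p] -= f * rhs[i]
    for i in range(n):
        p = parent[i]
        if p < 0:
            rhs[i] = rhs[i] * pivot[i]
        else:
            rhs[i] = (rhs[i] - a[i] * rhs[p]) * pivot[i]
    return divisions


try:  # optional kernel acceleration; the pure-Python path is authoritative
    import numba as _numba

    _hines_core_fast = _numba.njit(cache=True)(_hines_core)
except Exception:  # pragma: no cover
    _hines_core_fast = _hines_core


def hines_solve(sys: TreeSystem) -> np.ndarray:
    """Solve the tree system in place on ``rhs`` and return it.

    Elimination runs from the leaves to the root (descending index is
    sufficient since parent[i] < i), then back-substitution root to leaves.
    Exactly one division per node (the pivot reciprocal);
    ``sys.division_count`` records the count.
    """
    n = sys.n
    d = sys.d.copy()
    pivot = np.empty(n)
    result = _hines_core_fast(sys.parent, d, sys.a, sys.b, sys.rhs, pivot)
    if result < 0:
        raise SingularSystemError(f"zero pivot at node {-result - 1}")
    sys.division_count = int(result)
    return sys.rhs


# ---------------------------------------------------------------------------
# node orderings (cell permutations)


@dataclass
class Ordering:
    """Bijective renumbering of nodes; ``perm[new] = old``."""

    scheme: str
    perm: np.ndarray  # new index -> old index
    inv: np.ndarray  # old index -> new index

    @property
    def n(self) -> int:
        return len(self.perm)

    def permute_parent(self, parent: np.ndarray) -> np.ndarray:
        parent = np.asarray(parent)
        new_parent = np.empty_like(parent)
        for new_i, old_i in enumerate(self.perm):
            p = parent[old_i]
            new_parent[new_i] = -1 if p < 0 else self.inv[p]
        return new_parent

    def gather(self, values: np.ndarray) -> np.ndarray:
        """Old-order array -> new-order array."""
        return np.asarray(values)[self.perm]

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """New-order array -> old-order array."""
        out = np.empty_like(np.asarray(values))
        out[self.perm] = values
        return out


def make_ordering(parent: np.ndarray, cell_ids=None, scheme: str = "identity") -> Ordering:
    """Build a node ordering for a forest.

    ``identity`` keeps the original numbering.  ``cell_interleaved`` sorts
    nodes by (tree depth, cell id, original index), so that same-depth nodes
    of different cells are contiguous — the layout contract of production
    cell permutations, with results required to be invariant.
    """
    parent = np.asarray(parent, dtype=np.int64)
    n = len(parent)
    if cell_ids is None:
        cell_ids = np.zeros(n, dtype=np.int64)
    cell_ids = np.asarray(cell_ids)
    if scheme == "identity":
        perm = np.arange(n, dtype=np.int64)
    elif scheme == "cell_interleaved":
        depth = np.zeros(n, dtype=np.int64)
        for i in range(n):
            depth[i] = 0 if parent[i] < 0 else depth[parent[i]] + 1
        perm = np.array(sorted(range(n), key=lambda i: (depth[i], cell_ids[i], i)),
                        dtype=np.int64)
    else:
        raise ValueError(f"unknown ordering scheme: {scheme!r}")
    inv = np.empty(n, dtype=np.int64)
    inv[perm] = np.arange(n)
    ordering = Ordering(scheme=scheme, perm=perm, inv=inv)
    if np.any(ordering.permute_parent(parent) >= np.arange(n)):
        raise ValueError("ordering broke parent-before-child numbering")
    return ordering


def permute_system(sys: TreeSystem, ordering: Ordering) -> TreeSystem:
    """Renumber a tree system under an ordering (same solution, reindexed)."""
    return TreeSystem(
        parent=ordering.permute_parent(sys.parent),
        d=ordering.gather(sys.d), a=ordering.gather(sys.a),
        b=ordering.gather(sys.b), rhs=ordering.gather(sys.rhs))


# ---------------------------------------------------------------------------
# voltage-system assembly (implicit Euler)


def assemble_voltage_system(parent, c_nF, g_axial, dt, g_mech, i_rhs, v) -> TreeSystem:
    """Assemble the implicit-Euler voltage update system.

    For node i with capacitance C_i (nF), mechanism conductance load
    ``g_mech[i]`` (uS) and linearized mechanism/injection right-hand side
    ``i_rhs[i]`` (nA):

        d_i  = C_i/dt + g_mech_i + sum of axial couplings (uS)
        a_i  = b_i = -g_axial(i, parent)
        rhs_i = C_i/dt * v_i + i_rhs_i

    Solving yields V(t + dt) in mV.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    parent = np.asarray(parent, dtype=np.int64)
    n = len(parent)
    g_axial = np.asarray(g_axial, dtype=float)
    d = np.asarray(c_nF, dtype=float) / dt + np.asarray(g_mech, dtype=float)
    d = d + g_axial
    np.add.at(d, parent[parent >= 0], g_axial[parent >= 0])
    a = -g_axial
    b = -g_axial.copy()
    rhs = np.asarray(c_nF, dtype=float) / dt * np.asarray(v, dtype=float) \
        + np.asarray(i_rhs, dtype=float)
    return TreeSystem(parent=parent, d=d, a=a, b=b, rhs=rhs)
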