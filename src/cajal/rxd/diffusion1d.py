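"""Implicit 1D diffusion on the compartment tree via the Hines solver.

Finite-volume form on compartment centers: the mole flux between adjacent
compartments i, j is ``g_ij (c_j - c_i)`` with ``g_ij = D A_ij / dx_ij``
(A_ij: cross-section area at the shared boundary, um^2; dx_ij: center
distance, um; units mM um^3 / ms).  Backward Euler then solves

    (vol_i / dt) c'_i - sum_j g_ij (c'_j - c'_i) = (vol_i / dt) c_i

which is tree-structured, handled in O(n) by the Hines solver.  Ends are
sealed (zero flux), so total moles ``sum vol_i c_i`` are conserved to
roundoff; the uniform state is the exact equilibrium.
"""

from __future__ import annotations

import numpy as np

from ..morphology import DiscretizedCell
from ..solver import TreeSystem, hines_solve


def diffuse1d_step(values, cell: DiscretizedCell, d_coeff: float,
                   dt: float) -> np.ndarray:
    """Advance concentrations on a cell's compartments by one implicit step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if d_coeff < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    c = np.asarray(values, dtype=float)
    if c.shape != (cell.n,):
        raise ValueError(f"expected {cell.n} values, got {c.shape}")
    if d_coeff == 0.0:
        return c.copy()
    parent = cell.parent_index
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(cell.axial_dist > 0,
                     d_coeff * cell.axial_area / cell.axial_dist, 0.0)
    vol = cell.volume
    diag = vol / dt + g
    np.add.at(diag, parent[parent >= 0], g[parent >= 0])
    sys = TreeSystem(parent=parent, d=diag, a=-g, b=-g.copy(),
                     rhs=vol / dt * c)
    return hines_solve(sys)


def total_moles(values, cell: DiscretizedCell) -> float:
    """sum vol_i c_i (mM um^3), the conserved quantity of sealed diffusion."""
    return float(np.dot(cell.volume, np.asarray(values, dtype=float)))
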