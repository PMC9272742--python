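"""Nernst equilibrium potentials and the membrane-voltage probe."""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..units import FARADAY, GAS_CONSTANT


def nernst(z: int, c_in: float, c_out: float, celsius: float = 6.3) -> float:
    """Equilibrium potential E = (R T / z F) ln(c_out / c_in), in mV.

    Concentrations in any common unit (only the ratio matters); T from
    celsius.  Antisymmetric under swapping c_in and c_out; zero when they
    are equal.
    """
    if z == 0:
        raise ValueError("valence must be nonzero")
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    temperature = celsius + 273.15
    return 1000.0 * GAS_CONSTANT * temperature / (z * FARADAY) \
        * math.log(c_out / c_in)


@dataclass
class VoltageProbe:
    """Readable/writable view of the membrane potential at a location.

    Rate expressions that reference the symbol ``v`` are evaluated with
    this probe's value, allowing voltage-driven chemical dynamics without
    a DSL mechanism.  When attached to an engine simulation the probe is
    refreshed from the compartment voltage before each reaction step.
    """

    value: float = -65.0

    def read_from(self, sim, cell: int, section: int, x: float) -> float:
        node = sim.model.global_index(cell, section, x)
        self.value = sim.state.get_v(node)
        return self.value
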