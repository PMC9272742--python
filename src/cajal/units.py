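"""Unit conversion factors to the package's internal unit scheme.

Internal (NEURON-conventional) units:

====================  =========
quantity              unit
====================  =========
time                  ms
voltage               mV
concentration         mM
length                um
membrane capacitance  uF/cm^2
axial resistivity     ohm*cm
density conductance   S/cm^2
point current         nA
lumped conductance    uS
lumped capacitance    nF
diffusion coeff       um^2/ms
====================  =========

These choices make ``uS * mV = nA`` and ``nF * mV / ms = nA`` hold exactly,
so lumped membrane quantities combine without stray powers of ten:
``C[nF] = cm[uF/cm^2] * area[um^2] * 1e-5``,
``g[uS] = gbar[S/cm^2] * area[um^2] * 1e-2``,
``R_axial[Mohm] = ra[ohm*cm] * dx[um] / (pi r^2 [um^2]) * 1e-2``.

``unit_factor(name)`` returns the multiplier that converts a quantity
expressed in ``name`` into the internal unit of the same dimension, e.g.
``unit_factor("hour") == 3.6e6`` (ms), so circadian-scale rate constants
written per hour can be scaled into the ms-based engine.
"""

from __future__ import annotations

# Physical constants (SI, CODATA 2018 exact values derived from e, NA, kB):
# used by the Nernst relation and flux coupling.
FARADAY = 96485.33212331001  # C/mol = e * NA
GAS_CONSTANT = 8.31446261815324  # J/(mol*K) = kB * NA

_FACTORS: dict[str, float] = {
    # time -> ms
    "ms": 1.0,
    "us": 1e-3,
    "s": 1000.0,
    "sec": 1000.0,
    "minute": 60_000.0,
    "min": 60_000.0,
    "hour": 3.6e6,
    "day": 8.64e7,
    # voltage -> mV
    "mV": 1.0,
    "uV": 1e-3,
    "V": 1000.0,
    # concentration -> mM
    "mM": 1.0,
    "uM": 1e-3,
    "nM": 1e-6,
    "pM": 1e-9,
    "M": 1000.0,
    "molar": 1000.0,
    # length -> um
    "um": 1.0,
    "nm": 1e-3,
    "mm": 1000.0,
    "cm": 1e4,
    "m": 1e6,
    # current -> nA
    "nA": 1.0,
    "pA": 1e-3,
    "uA": 1e3,
    "mA": 1e6,
    # conductance -> uS
    "uS": 1.0,
    "nS": 1e-3,
    "mS": 1e3,
    "S": 1e6,
    # capacitance -> nF
    "nF": 1.0,
    "pF": 1e-3,
    "uF": 1e3,
}

# Greek-mu aliases (both MICRO SIGN and GREEK SMALL LETTER MU).
for _ascii, _dim in [("us", "u"), ("uV", "u"), ("uM", "u"), ("um", "u"),
                     ("uA", "u"), ("uS", "u"), ("uF", "u")]:
    for _mu in ("µ", "μ"):
        _FACTORS[_mu + _ascii[1:]] = _FACTORS[_ascii]


def unit_factor(name: str) -> float:
    """Multiplier converting a quantity in unit ``name`` to internal units.

    Raises ``KeyError`` for unknown tokens.
    """
    try:
        return _FACTORS[name]
    except KeyError:
        raise KeyError(f"unknown unit token: {name!r}") from None


def known_units() -> tuple[str, ...]:
    return tuple(sorted(_FACTORS))
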