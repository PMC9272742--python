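"""Builtin mechanism sources: squid-axon hh, passive leak, exponential
synapse, and a current-step stimulus.

These are fixtures as much as conveniences: they exercise every DSL
feature the engine relies on (ion currents, cnexp states, NET_RECEIVE,
comparison-gated stimuli) and are the mechanisms the test models use.
"""

from __future__ import annotations

from functools import lru_cache

from .parser import parse_mechanism

HH_SOURCE = """\
NEURON {
    SUFFIX hh
    USEION na READ ena WRITE ina
    USEION k READ ek WRITE ik
    NONSPECIFIC_CURRENT il
    RANGE gnabar, gkbar, gl, el
}
UNITS {
    (mV) = (millivolt)
    (S) = (siemens)
}
PARAMETER {
    gnabar = 0.12 (S/cm2)
    gkbar = 0.036 (S/cm2)
    gl = 0.0003 (S/cm2)
    el = -54.3 (mV)
}
STATE {
    m
    h
    n
}
ASSIGNED {
    gna (S/cm2)
    gk (S/cm2)
}
INITIAL {
    LOCAL am, bm, ah, bh, an, bn
    am = 0.1 * (v + 40) / (1 - exp(-(v + 40) / 10))
    bm = 4 * exp(-(v + 65) / 18)
    ah = 0.07 * exp(-(v + 65) / 20)
    bh = 1 / (1 + exp(-(v + 35) / 10))
    an = 0.01 * (v + 55) / (1 - exp(-(v + 55) / 10))
    bn = 0.125 * exp(-(v + 65) / 80)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
}
BREAKPOINT {
    SOLVE states METHOD cnexp
    gna = gnabar * m ^ 3 * h
    ina = gna * (v - ena)
    gk = gkbar * n ^ 4
    ik = gk * (v - ek)
    il = gl * (v - el)
}
DERIVATIVE states {
    LOCAL am, bm, ah, bh, an, bn, q10
    q10 = 3 ^ ((celsius - 6.3) / 10)
    am = 0.1 * (v + 40) / (1 - exp(-(v + 40) / 10))
    bm = 4 * exp(-(v + 65) / 18)
    ah = 0.07 * exp(-(v + 65) / 20)
    bh = 1 / (1 + exp(-(v + 35) / 10))
    an = 0.01 * (v + 55) / (1 - exp(-(v + 55) / 10))
    bn = 0.125 * exp(-(v + 65) / 80)
    m' = q10 * (am * (1 - m) - bm * m)
    h' = q10 * (ah * (1 - h) - bh * h)
    n' = q10 * (an * (1 - n) - bn * n)
}
"""

PAS_SOURCE = """\
NEURON {
    SUFFIX pas
    NONSPECIFIC_CURRENT i
    RANGE g, e
}
PARAMETER {
    g = 0.001 (S/cm2)
    e = -70 (mV)
}
BREAKPOINT {
    i = g * (v - e)
}
"""

EXPSYN_SOURCE = """\
NEURON {
    POINT_PROCESS expsyn
    NONSPECIFIC_CURRENT i
    RANGE tau, e
}
PARAMETER {
    tau = 2 (ms)
    e = 0 (mV)
}
STATE {
    g (uS)
}
INITIAL {
    g = 0
}
BREAKPOINT {
    SOLVE state METHOD cnexp
    i = g * (v - e)
}
DERIVATIVE state {
    g' = -g / tau
}
NET_RECEIVE(weight) {
    g = g + weight
}
"""

STIM_SOURCE = """\
NEURON {
    POINT_PROCESS stim
    NONSPECIFIC_CURRENT i
    RANGE onset, dur, amp
}
PARAMETER {
    onset = 1 (ms)
    dur = 1 (ms)
    amp = 0.1 (nA)
}
BREAKPOINT {
    i = -amp * ((t >= onset) * (t < onset + dur))
}
"""

SOURCES = {"hh": HH_SOURCE, "pas": PAS_SOURCE, "expsyn": EXPSYN_SOURCE,
           "stim": STIM_SOURCE}


@lru_cache(maxsize=1)
def builtin_library():
    """``{name: (source text, parsed MechanismSpec)}`` for the builtins."""
    return {name: (src, parse_mechanism(src)) for name, src in SOURCES.items()}
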