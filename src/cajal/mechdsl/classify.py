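"""Symbolic classification of DERIVATIVE-block ODEs and the analytic update.

A state ``s`` with rate ``ds/dt = f(s, v, params)`` is *linear* when f is
affine in s with coefficients independent of every state: ``ds/dt = a + b s``.
Such states admit the exact one-step (cnexp) update

    s(t + dt) = -a/b + (s + a/b) e^{b dt}        (|b| > eps)
    s(t + dt) = s + a dt                         (b ~ 0)

which is what makes analytic solver generation worthwhile: the expensive
per-step implicit solve degenerates to one exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy

from . import expr as E
from .spec import MechanismSpec


@dataclass
class ODEClassification:
    state: str
    kind: str  # 'linear' | 'nonlinear'
    a: sympy.Expr | None = None  # state-independent offset
    b: sympy.Expr | None = None  # state-independent slope


def classify_ode(spec: MechanismSpec, state: str) -> ODEClassification:
    """Classify one state's ODE, with in-block locals inlined first."""
    if state not in spec.states:
        raise KeyError(f"unknown state {state!r}")
    rate = E.to_sympy(spec.rate_expression(state))
    s = sympy.Symbol(state)
    state_syms = {sympy.Symbol(x) for x in spec.states}
    try:
        curvature = sympy.simplify(sympy.diff(rate, s, 2))
    except Exception:  # non-smooth constructs (Piecewise gates etc.)
        return ODEClassification(state, "nonlinear")
    if curvature != 0:
        return ODEClassification(state, "nonlinear")
    b = sympy.simplify(sympy.diff(rate, s))
    a = sympy.simplify(rate - b * s)
    if (a.free_symbols | b.free_symbols) & state_syms:
        return ODEClassification(state, "nonlinear")
    return ODEClassification(state, "linear", a=a, b=b)


def exact_update(s, a, b, dt, eps: float = 1e-12):
    """Exact solution of ``ds/dt = a + b s`` after ``dt`` (vectorized).

    The ``eps`` guard switches to the ``b -> 0`` limit ``s + a dt``.
    """
    s_in = np.asarray(s, dtype=float)
    a_in = np.asarray(a, dtype=float)
    b_in = np.asarray(b, dtype=float)
    scalar = s_in.ndim == 0 and a_in.ndim == 0 and b_in.ndim == 0
    s_in, a_in, b_in = np.broadcast_arrays(s_in, a_in, b_in)
    mask = np.abs(b_in) > eps
    safe_b = np.where(mask, b_in, 1.0)
    s_inf = -a_in / safe_b
    out = np.where(mask,
                   s_inf + (s_in - s_inf) * np.exp(b_in * dt),
                   s_in + a_in * dt)
    return float(out) if scalar else out
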