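"""Kernel generation: one mechanism, two translations.

Every mechanism is compiled twice from the same spec: a *reference* variant
(scalar Python over ``math``, operating on one instance's record dict) and a
*compact* variant (vectorized ``numpy`` over contiguous per-variable
arrays).  The two must agree numerically — layout is an implementation
detail, never a modelling choice — and this parity is what licenses moving
a running model between the two engine backends.

Per kernel set:

* ``init``         runs the INITIAL block.
* ``current``      evaluates the BREAKPOINT currents at v and v + eps_v and
                   returns ``(g, i)`` with ``g = di/dv`` by forward
                   difference (eps_v = 0.001 mV) — the linearization the
                   implicit voltage step needs.
* ``state``        advances states by dt: analytic (cnexp) updates for
                   linear states, damped Newton implicit Euler for the
                   nonlinear subset (tol 1e-10, <= 50 iterations).
* ``net_receive``  applies a discrete event (synaptic weight) to one
                   instance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..errors import NumericError
from . import expr as E
from .classify import ODEClassification, classify_ode, exact_update
from .spec import MechanismSpec

EPS_V = 0.001  # mV, forward-difference step for di/dv
NEWTON_TOL = 1e-10
NEWTON_MAXIT = 50


@dataclass
class KernelSet:
    mech: str
    layout: str  # 'reference' | 'compact'
    init: Callable
    current: Callable
    state: Callable
    net_receive: Callable | None
    source: dict[str, str]
    classifications: dict[str, ODEClassification] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Newton helpers shared by generated state kernels


def _newton_scalar(rates, y0, dt, mech):
    """Damped Newton for y = y0 + dt*f(y), scalars; forward-difference Jacobian."""
    m = len(y0)
    y = np.array(y0, dtype=float)
    y0 = np.array(y0, dtype=float)
    for _ in range(NEWTON_MAXIT):
        f = np.array(rates(y), dtype=float)
        res = y - y0 - dt * f
        nrm = np.max(np.abs(res))
        if nrm < NEWTON_TOL:
            return y
        J = np.empty((m, m))
        for j in range(m):
            h = 1e-7 * max(1.0, abs(y[j]))
            yp = y.copy()
            yp[j] += h
            J[:, j] = -dt * (np.array(rates(yp)) - f) / h
        J[np.arange(m), np.arange(m)] += 1.0
        try:
            step = np.linalg.solve(J, res)
        except np.linalg.LinAlgError:
            raise NumericError(f"{mech}: singular Newton Jacobian") from None
        lam = 1.0
        while lam > 1e-6:
            cand = y - lam * step
            rc = cand - y0 - dt * np.array(rates(cand), dtype=float)
            if np.max(np.abs(rc)) <= nrm:
                y = cand
                break
            lam *= 0.5
        else:
            y = y - step
    raise NumericError(f"{mech}: Newton failed to converge within {NEWTON_MAXIT} iterations")


def _newton_vec(rates, y0, dt, mech):
    """Vectorized damped Newton over instances; y0 shape (m, n)."""
    y0 = np.asarray(y0, dtype=float)
    m, n = y0.shape
    y = y0.copy()
    for _ in range(NEWTON_MAXIT):
        f = np.asarray(rates(y), dtype=float)
        res = y - y0 - dt * f
        nrm = np.max(np.abs(res), axis=0)
        if np.all(nrm < NEWTON_TOL):
            return y
        J = np.zeros((n, m, m))
        for j in range(m):
            h = 1e-7 * np.maximum(1.0, np.abs(y[j]))
            yp = y.copy()
            yp[j] += h
            J[:, :, j] = (-dt * (np.asarray(rates(yp)) - f) / h).T
        J[:, np.arange(m), np.arange(m)] += 1.0
        try:
            step = np.linalg.solve(J, res.T[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            raise NumericError(f"{mech}: singular Newton Jacobian") from None
        lam = np.ones(n)
        for _damp in range(20):
            cand = y - lam * step
            rc = cand - y0 - dt * np.asarray(rates(cand), dtype=float)
            worse = np.max(np.abs(rc), axis=0) > nrm
            if not np.any(worse):
                break
            lam = np.where(worse, lam * 0.5, lam)
        y = y - lam * step
    raise NumericError(f"{mech}: Newton failed to converge within {NEWTON_MAXIT} iterations")


# ---------------------------------------------------------------------------
# code generation


def _make_resolver(spec, layout, locals_map, indexed=False, overrides=None):
    ivars = set(spec.instance_vars())

    def resolve(name):
        if overrides and name in overrides:
            return overrides[name]
        if name in locals_map:
            return locals_map[name]
        if name in ivars:
            return f"P[{name!r}][idx]" if indexed else f"P[{name!r}]"
        return name  # builtin symbol (v, celsius, t, dt) or call argument

    return resolve


def _emit_stmts(stmts, spec, layout, lines, indent, locals_map, prefix,
                indexed=False, overrides=None, shadow=None):
    """Emit assignment statements.  ``shadow`` maps already-shadowed targets
    to local names (used by the perturbed current pass)."""
    resolve = _make_resolver(spec, layout, locals_map, indexed, overrides)
    ivars = set(spec.instance_vars())
    for st in stmts:
        if st[0] == "local":
            for nm in st[1]:
                locals_map[nm] = f"_l_{nm}"
            continue
        if st[0] == "solve":
            continue
        _, target, ast = st
        rhs = E.to_python(ast, resolve, prefix)
        if shadow is not None and target in ivars:
            shadow[target] = f"_pv_{target}"
            overrides[target] = f"_pv_{target}"
            lines.append(f"{indent}_pv_{target} = {rhs}")
        elif target in locals_map:
            lines.append(f"{indent}{locals_map[target]} = {rhs}")
        elif target in ivars:
            tgt = f"P[{target!r}][idx]" if indexed else f"P[{target!r}]"
            lines.append(f"{indent}{tgt} = {rhs}")
        else:
            locals_map[target] = f"_l_{target}"
            lines.append(f"{indent}_l_{target} = {rhs}")


def _gen_init(spec, layout, prefix):
    lines = [f"def init(P, v, celsius, t):"]
    body = []
    _emit_stmts(spec.initial, spec, layout, body, "    ", {}, prefix)
    lines.extend(body or ["    pass"])
    return "\n".join(lines) + "\n"


def _gen_current(spec, layout, prefix):
    assigns = [st for st in spec.breakpoint if st[0] == "assign"]
    cur_vars = spec.current_vars
    lines = [f"def current(P, v, celsius, t):"]
    locals_map: dict = {}
    _emit_stmts(assigns, spec, layout, lines, "    ", locals_map, prefix)
    lines.append("    _i0 = 0.0 * v")
    for cv in cur_vars:
        lines.append(f"    _i0 = _i0 + P[{cv!r}]")
    # perturbed pass: shadow every written instance var into a local
    shadow: dict = {}
    overrides = {"v": "_vp"}
    lines.append(f"    _vp = v + {EPS_V!r}")
    plocals: dict = {}
    _emit_stmts(assigns, spec, layout, lines, "    ", plocals, prefix,
                overrides=overrides, shadow=shadow)
    lines.append("    _i1 = 0.0 * v")
    for cv in cur_vars:
        lines.append(f"    _i1 = _i1 + {shadow.get(cv, f'P[{cv!r}]')}")
    lines.append(f"    _g = (_i1 - _i0) / {EPS_V!r}")
    lines.append("    return _g, _i0")
    return "\n".join(lines) + "\n"


def _gen_state(spec, layout, prefix, classifications):
    lines = ["def state(P, v, dt, celsius, t):"]
    if spec.solve is None or not spec.states:
        lines.append("    pass")
        return "\n".join(lines) + "\n"
    resolve = _make_resolver(spec, layout, {})
    linear = [s for s in spec.states if classifications[s].kind == "linear"]
    nonlinear = [s for s in spec.states if classifications[s].kind == "nonlinear"]
    for s in linear:
        rate = spec.rate_expression(s)
        r0 = E.substitute(rate, {s: ("num", 0.0)})
        r1 = E.substitute(rate, {s: ("num", 1.0)})
        lines.append(f"    _r0_{s} = {E.to_python(r0, resolve, prefix)}")
        lines.append(f"    _r1_{s} = {E.to_python(r1, resolve, prefix)}")
        lines.append(f"    P[{s!r}] = exact_update(P[{s!r}], _r0_{s}, "
                     f"_r1_{s} - _r0_{s}, dt)")
    if nonlinear:
        # joint implicit-Euler Newton solve over the nonlinear subset;
        # linear states appear at their already-updated values
        ymap = {s: f"Y[{i}]" for i, s in enumerate(nonlinear)}
        rres = _make_resolver(spec, layout, {}, overrides=ymap)
        lines.append("    def _rates(Y):")
        exprs = []
        for s in nonlinear:
            rate = spec.rate_expression(s)
            exprs.append(E.to_python(rate, rres, prefix))
        joined = ", ".join(exprs)
        lines.append(f"        return ({joined},)")
        y0 = ", ".join(f"P[{s!r}]" for s in nonlinear)
        helper = "_newton_scalar" if layout == "reference" else "_newton_vec"
        if layout == "reference":
            lines.append(f"    _y = {helper}(_rates, ({y0},), dt, {spec.name!r})")
        else:
            lines.append(f"    _y = {helper}(_rates, numpy.array([{y0}]), dt, "
                         f"{spec.name!r})")
        for i, s in enumerate(nonlinear):
            lines.append(f"    P[{s!r}] = _y[{i}]")
    return "\n".join(lines) + "\n"


def _gen_net_receive(spec, layout, prefix):
    if spec.net_receive is None:
        return None
    arg, stmts = spec.net_receive
    indexed = layout == "compact"
    sig = "def net_receive(P, idx, {a}, t):" if indexed else "def net_receive(P, {a}, t):"
    lines = [sig.format(a=arg)]
    body = []
    _emit_stmts(stmts, spec, layout, body, "    ", {}, prefix, indexed=indexed)
    lines.extend(body or ["    pass"])
    return "\n".join(lines) + "\n"


def generate_kernels(spec: MechanismSpec, layout: str = "reference") -> KernelSet:
    """Translate a mechanism spec into executable kernels for one layout."""
    if layout not in ("reference", "compact"):
        raise ValueError(f"unknown layout {layout!r}")
    prefix = "math" if layout == "reference" else "numpy"
    classifications = {s: classify_ode(spec, s) for s in spec.states}
    source = {
        "init": _gen_init(spec, layout, prefix),
        "current": _gen_current(spec, layout, prefix),
        "state": _gen_state(spec, layout, prefix, classifications),
    }
    nr_src = _gen_net_receive(spec, layout, prefix)
    if nr_src is not None:
        source["net_receive"] = nr_src
    ns = {"math": math, "numpy": np, "exact_update": exact_update,
          "_newton_scalar": _newton_scalar, "_newton_vec": _newton_vec}
    for src in source.values():
        exec(compile(src, f"<{spec.name}:{layout}>", "exec"), ns)
    return KernelSet(
        mech=spec.name, layout=layout,
        init=ns["init"], current=ns["current"], state=ns["state"],
        net_receive=ns.get("net_receive"), source=source,
        classifications=classifications)
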