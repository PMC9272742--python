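"""Validated in-memory representation of a parsed mechanism."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import SemanticError
from . import expr as E

#: reversal-potential defaults supplied to ion READ symbols (mV)
ION_READ_DEFAULTS = {"ena": 50.0, "ek": -77.0, "eca": 132.458, "ecl": -70.0}

BUILTIN_SYMBOLS = {"v", "celsius", "t", "dt"}


@dataclass
class IonSpec:
    name: str
    reads: tuple[str, ...] = ()
    writes: tuple[str, ...] = ()


@dataclass
class MechanismSpec:
    """Parsed mechanism: declarations plus block statement lists.

    Statements are tuples: ``('assign', target, ast)``, ``('deriv', state,
    ast)``, ``('local', (names,))``, ``('solve', block, method)``.
    """

    name: str
    kind: str  # 'density' | 'point_process'
    parameters: dict[str, tuple[float, str | None]] = field(default_factory=dict)
    states: tuple[str, ...] = ()
    state_units: dict[str, str | None] = field(default_factory=dict)
    assigned: tuple[str, ...] = ()
    ranges: tuple[str, ...] = ()
    ions: tuple[IonSpec, ...] = ()
    nonspecific: tuple[str, ...] = ()
    breakpoint: tuple = ()
    solve: tuple[str, str] | None = None  # (derivative block name, method)
    derivative_blocks: dict[str, tuple] = field(default_factory=dict)
    initial: tuple = ()
    net_receive: tuple | None = None  # (arg name, statements)
    unit_lines: tuple[str, ...] = ()

    # -- symbol tables ----------------------------------------------------
    @property
    def current_vars(self) -> tuple[str, ...]:
        out = list(self.nonspecific)
        for ion in self.ions:
            out.extend(w for w in ion.writes if w.startswith("i"))
        return tuple(out)

    @property
    def ion_inputs(self) -> tuple[str, ...]:
        out = []
        for ion in self.ions:
            out.extend(ion.reads)
        return tuple(out)

    def instance_vars(self) -> tuple[str, ...]:
        """Variables stored per instance: params, states, assigned, ion I/O."""
        seen, out = set(), []
        for name in (*self.parameters, *self.states, *self.assigned,
                     *self.ion_inputs, *self.current_vars):
            if name not in seen:
                seen.add(name)
                out.append(name)
        return tuple(out)

    def default_values(self) -> dict[str, float]:
        vals = {name: 0.0 for name in self.instance_vars()}
        for name, (default, _unit) in self.parameters.items():
            vals[name] = default
        for name in self.ion_inputs:
            vals[name] = ION_READ_DEFAULTS.get(name, 0.0)
        return vals

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in ("density", "point_process"):
            raise SemanticError(f"unknown mechanism kind {self.kind!r}")
        declared = set(self.parameters) | set(self.states) | set(self.assigned) \
            | set(self.ion_inputs) | set(self.current_vars) | BUILTIN_SYMBOLS
        dup = [s for s in self.states if list(self.states).count(s) > 1]
        if dup:
            raise SemanticError(f"duplicate state {dup[0]!r} in {self.name}")

        def check_stmts(stmts, where, extra=()):
            local = set(extra)
            for st in stmts:
                if st[0] == "local":
                    local |= set(st[1])
                elif st[0] == "solve":
                    if st[1] not in self.derivative_blocks:
                        raise SemanticError(
                            f"{where}: SOLVE references unknown block {st[1]!r}")
                elif st[0] in ("assign", "deriv"):
                    _, target, ast = st
                    for sym in sorted(E.free_vars(ast)):
                        if sym not in declared and sym not in local \
                                and sym not in E.FUNCTIONS:
                            raise SemanticError(
                                f"{where}: undeclared symbol {sym!r} in {self.name}")
                    if st[0] == "assign":
                        if target not in declared and target not in local:
                            raise SemanticError(
                                f"{where}: assignment to undeclared {target!r}")
                        local.add(target)
                    else:
                        if target not in self.states:
                            raise SemanticError(
                                f"{where}: derivative of non-state {target!r}")

        check_stmts(self.breakpoint, "BREAKPOINT")
        for bname, stmts in self.derivative_blocks.items():
            check_stmts(stmts, f"DERIVATIVE {bname}")
            derived = [st[1] for st in stmts if st[0] == "deriv"]
            for s in derived:
                if derived.count(s) > 1:
                    raise SemanticError(f"state {s!r} has multiple rate expressions")
        check_stmts(self.initial, "INITIAL")
        if self.net_receive is not None:
            arg, stmts = self.net_receive
            check_stmts(stmts, "NET_RECEIVE", extra=(arg,))
        if self.solve is not None:
            bname = self.solve[0]
            if bname not in self.derivative_blocks:
                raise SemanticError(f"SOLVE references unknown block {bname!r}")
            derived = {st[1] for st in self.derivative_blocks[bname]
                       if st[0] == "deriv"}
            missing = [s for s in self.states if s not in derived]
            if missing:
                raise SemanticError(
                    f"state {missing[0]!r} has no rate expression in {bname!r}")
        elif self.states:
            raise SemanticError(f"{self.name}: states declared but nothing SOLVEd")

    def rate_expression(self, state: str):
        """Rate AST for a state with in-block local assignments inlined."""
        if self.solve is None:
            raise SemanticError(f"{self.name}: no DERIVATIVE block")
        env: dict = {}
        for st in self.derivative_blocks[self.solve[0]]:
            if st[0] == "assign":
                env[st[1]] = E.substitute(st[2], env)
            elif st[0] == "deriv" and st[1] == state:
                return E.substitute(st[2], env)
        raise KeyError(f"no rate expression for state {state!r}")

    # -- normalized emission ----------------------------------------------
    def emit(self) -> str:
        """Normalized DSL source; parsing it reproduces this spec."""
        out = ["NEURON {"]
        kw = "SUFFIX" if self.kind == "density" else "POINT_PROCESS"
        out.append(f"    {kw} {self.name}")
        for ion in self.ions:
            line = f"    USEION {ion.name}"
            if ion.reads:
                line += " READ " + ", ".join(ion.reads)
            if ion.writes:
                line += " WRITE " + ", ".join(ion.writes)
            out.append(line)
        if self.nonspecific:
            out.append("    NONSPECIFIC_CURRENT " + ", ".join(self.nonspecific))
        if self.ranges:
            out.append("    RANGE " + ", ".join(self.ranges))
        out.append("}")
        if self.unit_lines:
            out.append("UNITS {")
            out.extend(f"    {ln}" for ln in self.unit_lines)
            out.append("}")
        if self.parameters:
            out.append("PARAMETER {")
            for name, (default, unit) in self.parameters.items():
                line = f"    {name} = {E.to_str(('num', default))}"
                if unit:
                    line += f" ({unit})"
                out.append(line)
            out.append("}")
        if self.states:
            out.append("STATE {")
            for s in self.states:
                unit = self.state_units.get(s)
                out.append(f"    {s}" + (f" ({unit})" if unit else ""))
            out.append("}")
        if self.assigned:
            out.append("ASSIGNED {")
            out.extend(f"    {a}" for a in self.assigned)
            out.append("}")

        def stmt_lines(stmts):
            for st in stmts:
                if st[0] == "local":
                    yield "    LOCAL " + ", ".join(st[1])
                elif st[0] == "solve":
                    yield f"    SOLVE {st[1]} METHOD {st[2]}"
                elif st[0] == "assign":
                    yield f"    {st[1]} = {E.to_str(st[2])}"
                elif st[0] == "deriv":
                    yield f"    {st[1]}' = {E.to_str(st[2])}"

        if self.initial:
            out.append("INITIAL {")
            out.extend(stmt_lines(self.initial))
            out.append("}")
        out.append("BREAKPOINT {")
        out.extend(stmt_lines(self.breakpoint))
        out.append("}")
        for bname, stmts in self.derivative_blocks.items():
            out.append(f"DERIVATIVE {bname} {{")
            out.extend(stmt_lines(stmts))
            out.append("}")
        if self.net_receive is not None:
            arg, stmts = self.net_receive
            out.append(f"NET_RECEIVE({arg}) {{")
            out.extend(stmt_lines(stmts))
            out.append("}")
        return "\n".join(out) + "\n"
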