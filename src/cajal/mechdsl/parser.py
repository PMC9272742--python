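"""Tokenizer and recursive-descent parser for the mechanism DSL subset.

Supported blocks: NEURON, UNITS, PARAMETER, STATE, ASSIGNED, BREAKPOINT,
DERIVATIVE <name>, INITIAL, NET_RECEIVE(<arg>).  ``SOLVE <block> METHOD
cnexp|derivimplicit`` selects the integration path.  Comments run from
``:`` to end of line.  Statements are newline-separated.
"""

from __future__ import annotations

import re

from ..errors import ParseError, SemanticError
from .spec import IonSpec, MechanismSpec

_TOKEN_RE = re.compile(r"""
    (?P<num>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|[{}()=+\-*/^'<>,])
  | (?P<ws>[ \t\r]+)
  | (?P<comment>[:?][^\n]*)
  | (?P<nl>\n)
""", re.VERBOSE)

_METHODS = ("cnexp", "derivimplicit")
_BLOCKS = ("NEURON", "UNITS", "PARAMETER", "STATE", "ASSIGNED", "BREAKPOINT",
           "DERIVATIVE", "INITIAL", "NET_RECEIVE")


def _tokenize(text):
    tokens, line, pos = [], 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ParseError(f"unexpected character {text[pos]!r}", line)
        pos = m.end()
        kind = m.lastgroup
        if kind in ("ws", "comment"):
            continue
        if kind == "nl":
            tokens.append(("nl", "\n", line))
            line += 1
        elif kind == "num":
            tokens.append(("num", float(m.group()), line))
        else:
            tokens.append((kind, m.group(), line))
    tokens.append(("eof", "", line))
    return tokens


class _Parser:
    def __init__(self, text):
        self.toks = _tokenize(text)
        self.i = 0

    # -- token helpers -----------------------------------------------------
    def peek(self, skip_nl=False):
        j = self.i
        if skip_nl:
            while self.toks[j][0] == "nl":
                j += 1
        return self.toks[j]

    def next(self, skip_nl=False):
        if skip_nl:
            while self.toks[self.i][0] == "nl":
                self.i += 1
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, value, skip_nl=False):
        tok = self.next(skip_nl=skip_nl)
        if tok[1] != value:
            raise ParseError(f"expected {value!r}, got {tok[1]!r}", tok[2])
        return tok

    def expect_name(self, skip_nl=False):
        tok = self.next(skip_nl=skip_nl)
        if tok[0] != "name":
            raise ParseError(f"expected a name, got {tok[1]!r}", tok[2])
        return tok

    def skip_newlines(self):
        while self.toks[self.i][0] == "nl":
            self.i += 1

    def name_list(self):
        names = [self.expect_name()[1]]
        while self.peek()[1] == ",":
            self.next()
            names.append(self.expect_name()[1])
        return names

    # -- expressions ---------------------------------------------------------
    def expression(self):
        return self._cmp()

    def _cmp(self):
        left = self._add()
        if self.peek()[1] in ("<", ">", "<=", ">="):
            op = self.next()[1]
            right = self._add()
            return ("bin", op, left, right)
        return left

    def _add(self):
        node = self._mul()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = ("bin", op, node, self._mul())
        return node

    def _mul(self):
        node = self._unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = ("bin", op, node, self._unary())
        return node

    def _unary(self):
        if self.peek()[1] == "-":
            self.next()
            return ("un", "-", self._unary())
        if self.peek()[1] == "+":
            self.next()
            return self._unary()
        return self._power()

    def _power(self):
        base = self._atom()
        if self.peek()[1] == "^":
            self.next()
            return ("bin", "^", base, self._unary())
        return base

    def _atom(self):
        tok = self.next()
        if tok[0] == "num":
            return ("num", tok[1])
        if tok[0] == "name":
            if self.peek()[1] == "(":
                self.next()
                args = [self.expression()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.expression())
                self.expect(")")
                return ("call", tok[1], args)
            return ("var", tok[1])
        if tok[1] == "(":
            node = self.expression()
            self.expect(")")
            return node
        raise ParseError(f"unexpected token {tok[1]!r} in expression", tok[2])

    # -- statements ----------------------------------------------------------
    def statements(self, allow_deriv=False, allow_solve=False):
        """Parse newline-separated statements until the closing brace."""
        stmts = []
        while True:
            self.skip_newlines()
            tok = self.peek()
            if tok[1] == "}":
                self.next()
                return tuple(stmts)
            if tok[0] == "eof":
                raise ParseError("unexpected end of file inside block", tok[2])
            if tok[1] == "LOCAL":
                self.next()
                stmts.append(("local", tuple(self.name_list())))
            elif tok[1] == "SOLVE":
                if not allow_solve:
                    raise ParseError("SOLVE only allowed in BREAKPOINT", tok[2])
                self.next()
                block = self.expect_name()[1]
                self.expect("METHOD")
                method = self.expect_name()[1]
                if method not in _METHODS:
                    raise ParseError(f"unknown SOLVE method {method!r}", tok[2])
                stmts.append(("solve", block, method))
            else:
                name = self.expect_name()[1]
                if self.peek()[1] == "'":
                    if not allow_deriv:
                        raise ParseError(
                            "state derivative outside DERIVATIVE block", tok[2])
                    self.next()
                    self.expect("=")
                    stmts.append(("deriv", name, self.expression()))
                else:
                    self.expect("=")
                    stmts.append(("assign", name, self.expression()))
            nxt = self.peek()
            if nxt[1] != "}" and nxt[0] not in ("nl", "eof"):
                raise ParseError(f"unexpected token {nxt[1]!r} after statement", nxt[2])

    # -- declaration blocks ----------------------------------------------------
    def _unit_suffix(self):
        if self.peek()[1] == "(":
            self.next()
            parts = []
            depth = 1
            while depth:
                tok = self.next()
                if tok[1] == "(":
                    depth += 1
                elif tok[1] == ")":
                    depth -= 1
                    if depth == 0:
                        break
                if tok[0] == "num":
                    parts.append(("%g" % tok[1]))
                else:
                    parts.append(str(tok[1]))
            return "".join(parts)
        return None

    def neuron_block(self, spec_kw):
        self.expect("{", skip_nl=True)
        while True:
            self.skip_newlines()
            tok = self.next()
            if tok[1] == "}":
                return
            if tok[1] in ("SUFFIX", "POINT_PROCESS"):
                spec_kw["kind"] = "density" if tok[1] == "SUFFIX" else "point_process"
                spec_kw["name"] = self.expect_name()[1]
            elif tok[1] == "RANGE":
                spec_kw.setdefault("ranges", [])
                spec_kw["ranges"].extend(self.name_list())
            elif tok[1] == "NONSPECIFIC_CURRENT":
                spec_kw.setdefault("nonspecific", [])
                spec_kw["nonspecific"].extend(self.name_list())
            elif tok[1] == "USEION":
                ion = self.expect_name()[1]
                reads, writes = [], []
                while self.peek()[1] in ("READ", "WRITE"):
                    kw = self.next()[1]
                    (reads if kw == "READ" else writes).extend(self.name_list())
                spec_kw.setdefault("ions", [])
                spec_kw["ions"].append(
                    IonSpec(ion, tuple(reads), tuple(writes)))
            elif tok[1] in ("GLOBAL", "THREADSAFE"):
                if tok[1] == "GLOBAL":
                    self.name_list()
            else:
                raise ParseError(f"unknown NEURON-block keyword {tok[1]!r}", tok[2])

    def decl_block(self, with_default):
        self.expect("{", skip_nl=True)
        entries = []
        while True:
            self.skip_newlines()
            tok = self.peek()
            if tok[1] == "}":
                self.next()
                return entries
            name = self.expect_name()[1]
            default = None
            if with_default and self.peek()[1] == "=":
                self.next()
                sign = 1.0
                if self.peek()[1] == "-":
                    self.next()
                    sign = -1.0
                num = self.next()
                if num[0] != "num":
                    raise ParseError("parameter default must be a number", num[2])
                default = sign * num[1]
            unit = self._unit_suffix()
            entries.append((name, default, unit))

    def units_block(self):
        self.expect("{", skip_nl=True)
        lines, current = [], []
        while True:
            tok = self.next()
            if tok[1] == "}":
                if current:
                    lines.append(" ".join(current))
                return tuple(lines)
            if tok[0] == "eof":
                raise ParseError("unexpected end of file in UNITS", tok[2])
            if tok[0] == "nl":
                if current:
                    lines.append(" ".join(current))
                    current = []
            elif tok[0] == "num":
                current.append("%g" % tok[1])
            else:
                current.append(str(tok[1]))


def parse_mechanism(text: str) -> MechanismSpec:
    """Parse mechanism DSL source into a validated :class:`MechanismSpec`."""
    p = _Parser(text)
    kw: dict = {}
    parameters: dict = {}
    states: list[str] = []
    state_units: dict = {}
    assigned: list[str] = []
    breakpoint_stmts = ()
    solve = None
    derivative_blocks: dict = {}
    initial = ()
    net_receive = None
    unit_lines = ()

    while True:
        tok = p.next(skip_nl=True)
        if tok[0] == "eof":
            break
        if tok[0] != "name" or tok[1] not in _BLOCKS:
            raise ParseError(f"unknown block {tok[1]!r}", tok[2])
        block = tok[1]
        if block == "NEURON":
            p.neuron_block(kw)
        elif block == "UNITS":
            unit_lines = p.units_block()
        elif block == "PARAMETER":
            for name, default, unit in p.decl_block(with_default=True):
                if name in parameters:
                    raise SemanticError(f"duplicate parameter {name!r}", tok[2])
                parameters[name] = (default if default is not None else 0.0, unit)
        elif block == "STATE":
            for name, _d, unit in p.decl_block(with_default=False):
                if name in states:
                    raise SemanticError(f"duplicate state {name!r}", tok[2])
                states.append(name)
                state_units[name] = unit
        elif block == "ASSIGNED":
            for name, _d, unit in p.decl_block(with_default=False):
                assigned.append(name)
        elif block == "BREAKPOINT":
            p.expect("{", skip_nl=True)
            breakpoint_stmts = p.statements(allow_solve=True)
            for st in breakpoint_stmts:
                if st[0] == "solve":
                    solve = (st[1], st[2])
        elif block == "DERIVATIVE":
            bname = p.expect_name()[1]
            p.expect("{", skip_nl=True)
            derivative_blocks[bname] = p.statements(allow_deriv=True)
        elif block == "INITIAL":
            p.expect("{", skip_nl=True)
            initial = p.statements()
        elif block == "NET_RECEIVE":
            p.expect("(")
            arg = p.expect_name()[1]
            p.expect(")")
            p.expect("{", skip_nl=True)
            net_receive = (arg, p.statements())

    if "name" not in kw:
        raise SemanticError("NEURON block must declare SUFFIX or POINT_PROCESS")
    spec = MechanismSpec(
        name=kw["name"], kind=kw["kind"], parameters=parameters,
        states=tuple(states), state_units=state_units,
        assigned=tuple(assigned), ranges=tuple(kw.get("ranges", ())),
        ions=tuple(kw.get("ions", ())),
        nonspecific=tuple(kw.get("nonspecific", ())),
        breakpoint=breakpoint_stmts, solve=solve,
        derivative_blocks=derivative_blocks, initial=initial,
        net_receive=net_receive, unit_lines=unit_lines)
    spec.validate()
    return spec
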