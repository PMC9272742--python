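"""Expression AST shared by the mechanism-DSL parser, classifier and codegen.

Nodes are plain tuples:

    ('num', value)            literal
    ('var', name)             symbol reference
    ('un', '-', e)            unary minus
    ('bin', op, l, r)         op in + - * / ^ < > <= >=
    ('call', fn, [args])      builtin function call

Comparison operators evaluate to 0/1 and let mechanisms express gated
quantities (e.g. a current step active on [onset, onset+dur)) without a
conditional statement form.
"""

from __future__ import annotations

import sympy

#: builtin function name -> (math-module name, numpy name)
FUNCTIONS = {
    "exp": ("math.exp", "numpy.exp"),
    "log": ("math.log", "numpy.log"),
    "log10": ("math.log10", "numpy.log10"),
    "sqrt": ("math.sqrt", "numpy.sqrt"),
    "fabs": ("math.fabs", "numpy.fabs"),
    "sin": ("math.sin", "numpy.sin"),
    "cos": ("math.cos", "numpy.cos"),
    "tan": ("math.tan", "numpy.tan"),
    "tanh": ("math.tanh", "numpy.tanh"),
    "floor": ("math.floor", "numpy.floor"),
    "pow": ("math.pow", "numpy.power"),
}

_PREC = {"<": 1, ">": 1, "<=": 1, ">=": 1, "+": 2, "-": 2, "*": 3, "/": 3, "^": 4}


def free_vars(ast) -> set[str]:
    kind = ast[0]
    if kind == "num":
        return set()
    if kind == "var":
        return {ast[1]}
    if kind == "un":
        return free_vars(ast[2])
    if kind == "bin":
        return free_vars(ast[2]) | free_vars(ast[3])
    if kind == "call":
        out = set()
        for a in ast[2]:
            out |= free_vars(a)
        return out
    raise ValueError(f"bad AST node {ast!r}")


def substitute(ast, mapping: dict):
    """Replace ('var', name) nodes by the ASTs in ``mapping`` (one pass)."""
    kind = ast[0]
    if kind == "num":
        return ast
    if kind == "var":
        return mapping.get(ast[1], ast)
    if kind == "un":
        return ("un", ast[1], substitute(ast[2], mapping))
    if kind == "bin":
        return ("bin", ast[1], substitute(ast[2], mapping), substitute(ast[3], mapping))
    if kind == "call":
        return ("call", ast[1], [substitute(a, mapping) for a in ast[2]])
    raise ValueError(f"bad AST node {ast!r}")


def to_str(ast, parent_prec=0) -> str:
    """Normalized DSL text for an expression (used by spec round-tripping)."""
    kind = ast[0]
    if kind == "num":
        v = ast[1]
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if kind == "var":
        return ast[1]
    if kind == "un":
        inner = to_str(ast[2], 5)
        return f"-{inner}"
    if kind == "call":
        return f"{ast[1]}({', '.join(to_str(a) for a in ast[2])})"
    op, l, r = ast[1], ast[2], ast[3]
    prec = _PREC[op]
    # right operand gets prec+1 for left-assoc ops; ^ is right-assoc
    rp = prec if op == "^" else prec + 1
    s = f"{to_str(l, prec)} {op} {to_str(r, rp)}"
    return f"({s})" if prec < parent_prec else s


def to_python(ast, resolve, prefix="math") -> str:
    """Python source for an expression.

    ``resolve(name) -> str`` maps a symbol to its Python access expression
    (e.g. ``P['gbar']`` or a local name).  ``prefix`` selects the function
    namespace ('math' for scalar kernels, 'numpy' for vectorized ones).
    """
    kind = ast[0]
    if kind == "num":
        return repr(float(ast[1]))
    if kind == "var":
        return resolve(ast[1])
    if kind == "un":
        return f"(-{to_python(ast[2], resolve, prefix)})"
    if kind == "call":
        fn = FUNCTIONS[ast[1]][0 if prefix == "math" else 1]
        args = ", ".join(to_python(a, resolve, prefix) for a in ast[2])
        return f"{fn}({args})"
    op, l, r = ast[1], ast[2], ast[3]
    ls, rs = to_python(l, resolve, prefix), to_python(r, resolve, prefix)
    if op == "^":
        return f"({ls}) ** ({rs})"
    if op in ("<", ">", "<=", ">="):
        # numeric 0/1 so gates can multiply into rate/current expressions
        return f"(1.0 * (({ls}) {op} ({rs})))"
    return f"(({ls}) {op} ({rs}))"


def to_sympy(ast):
    kind = ast[0]
    if kind == "num":
        return sympy.Float(ast[1]) if not float(ast[1]).is_integer() \
            else sympy.Integer(int(ast[1]))
    if kind == "var":
        return sympy.Symbol(ast[1])
    if kind == "un":
        return -to_sympy(ast[2])
    if kind == "call":
        args = [to_sympy(a) for a in ast[2]]
        fn = ast[1]
        table = {"exp": sympy.exp, "log": sympy.log, "sqrt": sympy.sqrt,
                 "fabs": sympy.Abs, "sin": sympy.sin, "cos": sympy.cos,
                 "tan": sympy.tan, "tanh": sympy.tanh, "floor": sympy.floor}
        if fn == "log10":
            return sympy.log(args[0], 10)
        if fn == "pow":
            return args[0] ** args[1]
        return table[fn](*args)
    op, l, r = ast[1], ast[2], ast[3]
    L, R = to_sympy(l), to_sympy(r)
    if op == "+":
        return L + R
    if op == "-":
        return L - R
    if op == "*":
        return L * R
    if op == "/":
        return L / R
    if op == "^":
        return L ** R
    rel = {"<": sympy.Lt, ">": sympy.Gt, "<=": sympy.Le, ">=": sympy.Ge}[op](L, R)
    return sympy.Piecewise((1, rel), (0, True))
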