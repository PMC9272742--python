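"""Mechanism DSL: parsing, ODE classification, kernel generation."""

import math

import numpy as np
import pytest
import sympy

from cajal.errors import ParseError, SemanticError
from cajal.mechdsl import (builtin_library, classify_ode, exact_update,
                           generate_kernels, parse_mechanism)

PASSIVE = """\
NEURON {
    SUFFIX leak
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

DECAY = """\
NEURON {
    SUFFIX dk
    RANGE k
}
PARAMETER {
    k = 2.0
}
STATE {
    s
}
INITIAL {
    s = 1
}
BREAKPOINT {
    SOLVE dyn METHOD derivimplicit
}
DERIVATIVE dyn {
    s' = -k * s ^ 2
}
"""

ALPHA_BETA = """\
NEURON {
    SUFFIX ab
    RANGE q
}
PARAMETER {
    q = 1.0
}
STATE {
    m
}
INITIAL {
    m = 0
}
BREAKPOINT {
    SOLVE dyn METHOD cnexp
}
DERIVATIVE dyn {
    LOCAL alpha, beta
    alpha = 0.2 * exp(v / 20)
    beta = 0.3 * exp(-v / 25)
    m' = alpha * (1 - m) - beta * m
}
"""


class TestParse:
    def test_minimal_passive_mechanism(self):
        spec = parse_mechanism(PASSIVE)
        assert spec.kind == "density"
        assert spec.states == ()
        assert spec.current_vars == ("i",)
        assert set(spec.parameters) == {"g", "e"}

    def test_hh_builtin_shape(self):
        spec = builtin_library()["hh"][1]
        assert spec.states == ("m", "h", "n")
        assert set(spec.current_vars) == {"ina", "ik", "il"}
        ions = {ion.name: ion for ion in spec.ions}
        assert ions["na"].reads == ("ena",) and ions["na"].writes == ("ina",)
        assert ions["k"].reads == ("ek",) and ions["k"].writes == ("ik",)
        assert spec.solve == ("states", "cnexp")

    def test_undeclared_symbol_error_names_it(self):
        src = PASSIVE.replace("g * (v - e)", "g * (v - e) + q")
        with pytest.raises(SemanticError, match="'q'"):
            parse_mechanism(src)

    def test_duplicate_state_rejected(self):
        src = DECAY.replace("STATE {\n    s\n}", "STATE {\n    s\n    s\n}")
        with pytest.raises(SemanticError, match="duplicate state"):
            parse_mechanism(src)

    def test_unknown_block_rejected_with_line(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_mechanism("KINETIC foo {\n}\n")

    def test_error_reports_line_number(self):
        bad = PASSIVE + "\nBOGUS {\n}\n"
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_mechanism(bad)

    def test_emit_roundtrip_is_identity(self):
        for name, (_src, spec) in builtin_library().items():
            again = parse_mechanism(spec.emit())
            assert again == spec, name


class TestClassify:
    def test_first_order_relaxation_is_linear(self):
        src = ALPHA_BETA.replace(
            "LOCAL alpha, beta\n    alpha = 0.2 * exp(v / 20)\n"
            "    beta = 0.3 * exp(-v / 25)\n    m' = alpha * (1 - m) - beta * m",
            "LOCAL minf, mtau\n    minf = 1 / (1 + exp(-v / 10))\n"
            "    mtau = 2\n    m' = (minf - m) / mtau")
        spec = parse_mechanism(src)
        cls = classify_ode(spec, "m")
        assert cls.kind == "linear"
        v = sympy.Symbol("v")
        minf = 1 / (1 + sympy.exp(-v / 10))
        assert sympy.simplify(cls.a - minf / 2) == 0
        assert sympy.simplify(cls.b + sympy.Rational(1, 2)) == 0

    def test_quadratic_decay_is_nonlinear(self):
        spec = parse_mechanism(DECAY)
        assert classify_ode(spec, "s").kind == "nonlinear"

    def test_alpha_beta_form_reexpands_symbolically(self):
        spec = parse_mechanism(ALPHA_BETA)
        cls = classify_ode(spec, "m")
        assert cls.kind == "linear"
        # a + b*m must reproduce the original rate alpha(1-m) - beta m
        v, m = sympy.symbols("v m")
        alpha = 0.2 * sympy.exp(v / 20)
        beta = 0.3 * sympy.exp(-v / 25)
        original = alpha * (1 - m) - beta * m
        assert sympy.simplify(cls.a + cls.b * m - original) == 0

    def test_all_hh_states_linear(self):
        spec = builtin_library()["hh"][1]
        for state in spec.states:
            assert classify_ode(spec, state).kind == "linear"


class TestExactUpdate:
    def test_no_dynamics(self):
        assert exact_update(0.7, 0.0, 0.0, 5.0) == 0.7

    def test_pure_decay_closed_form(self):
        tau = 3.0
        assert exact_update(0.5, 0.0, -1.0 / tau, tau) == pytest.approx(
            0.5 * math.exp(-1.0))

    def test_matches_fine_step_integration(self):
        a, b, s, dt = 2.0, -0.5, 0.0, 0.1
        n, h = 1000, 0.1 / 1000
        y = s

        def f(x):
            return a + b * x

        for _ in range(n):  # RK4 substeps: independent fine-step oracle
            k1, k2 = f(y), f(y + h / 2 * f(y))
            k3 = f(y + h / 2 * k2)
            k4 = f(y + h * k3)
            y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert exact_update(s, a, b, dt) == pytest.approx(y, abs=1e-9)

    def test_equals_limit_of_implicit_euler_substeps(self):
        # one exact step == n -> inf implicit-Euler substeps (n = 1e4, tol 1e-6)
        a, b, s, dt = 1.3, -0.7, 0.2, 0.1
        n = 10_000
        y = s
        h = dt / n
        for _ in range(n):
            y = (y + a * h) / (1.0 - b * h)
        assert abs(exact_update(s, a, b, dt) - y) <= 1e-6

    def test_vectorized_matches_scalar(self):
        s = np.array([0.1, 0.2])
        out = exact_update(s, np.array([0.0, 1.0]), np.array([-0.5, 0.0]), 0.2)
        assert out[0] == pytest.approx(exact_update(0.1, 0.0, -0.5, 0.2))
        assert out[1] == pytest.approx(exact_update(0.2, 1.0, 0.0, 0.2))


class TestKernels:
    def test_passive_current_zero_at_reversal(self):
        spec = parse_mechanism(PASSIVE)
        kern = generate_kernels(spec, "reference")
        P = spec.default_values()
        g, i = kern.current(P, -70.0, 6.3, 0.0)
        assert i == pytest.approx(0.0, abs=1e-15)
        assert g == pytest.approx(0.001, rel=1e-6)  # density S/cm^2

    def test_hh_state_step_matches_fine_substep_oracle(self):
        spec = builtin_library()["hh"][1]
        kern = generate_kernels(spec, "reference")
        P = spec.default_values()
        kern.init(P, -65.0, 6.3, 0.0)
        v, dt = -40.5, 0.025
        expected = {}
        # oracle: 1000 implicit-Euler substeps of the same ODEs at fixed v
        rates = {
            "m": (0.1 * (v + 40) / (1 - math.exp(-(v + 40) / 10)),
                  4 * math.exp(-(v + 65) / 18)),
            "h": (0.07 * math.exp(-(v + 65) / 20),
                  1 / (1 + math.exp(-(v + 35) / 10))),
            "n": (0.01 * (v + 55) / (1 - math.exp(-(v + 55) / 10)),
                  0.125 * math.exp(-(v + 65) / 80)),
        }
        for s, (alpha, beta) in rates.items():
            y = P[s]
            h = dt / 1000

            def f(x, a=alpha, b=beta):
                return a * (1 - x) - b * x

            for _ in range(1000):  # classic RK4 substeps as the oracle
                k1 = f(y)
                k2 = f(y + h / 2 * k1)
                k3 = f(y + h / 2 * k2)
                k4 = f(y + h * k3)
                y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            expected[s] = y
        kern.state(P, v, dt, 6.3, 0.0)
        for s in ("m", "h", "n"):
            assert abs(P[s] - expected[s]) <= 1e-8

    def test_reference_and_compact_kernels_agree(self, rng):
        for name, (_src, spec) in builtin_library().items():
            ref = generate_kernels(spec, "reference")
            cmp_ = generate_kernels(spec, "compact")
            n = 5
            Pr = [spec.default_values() for _ in range(n)]
            vs = rng.uniform(-80, 20, n)
            for P, v in zip(Pr, vs):
                ref.init(P, v, 6.3, 0.0)
            Pc = {k: np.array([P[k] for P in Pr]) for k in spec.instance_vars()}
            cmp_.init(Pc, vs, 6.3, 0.0)
            for P, v in zip(Pr, vs):
                ref.current(P, v, 6.3, 2.0)
                ref.state(P, v, 0.025, 6.3, 2.0)
            cmp_.current(Pc, vs, 6.3, 2.0)
            cmp_.state(Pc, vs, 0.025, 6.3, 2.0)
            for key in spec.instance_vars():
                ref_col = np.array([P[key] for P in Pr])
                np.testing.assert_allclose(Pc[key], ref_col, rtol=1e-12,
                                           atol=1e-300, err_msg=f"{name}.{key}")

    def test_nonlinear_state_newton_matches_fine_oracle(self):
        spec = parse_mechanism(DECAY)
        kern = generate_kernels(spec, "reference")
        P = spec.default_values()
        kern.init(P, -65.0, 6.3, 0.0)
        dt, k = 0.1, 2.0
        kern.state(P, -65.0, dt, 6.3, 0.0)
        # implicit Euler on s' = -k s^2: s satisfies s = s0 - dt k s^2
        s = (-1 + math.sqrt(1 + 4 * dt * k * 1.0)) / (2 * dt * k)
        assert P["s"] == pytest.approx(s, abs=1e-9)

    def test_generation_is_deterministic(self):
        spec = builtin_library()["hh"][1]
        a = generate_kernels(spec, "compact")
        b = generate_kernels(spec, "compact")
        assert a.source == b.source

    def test_stim_gate_window(self):
        spec = builtin_library()["stim"][1]
        kern = generate_kernels(spec, "reference")
        P = spec.default_values()  # onset 1, dur 1, amp 0.1
        assert kern.current(P, -65.0, 6.3, 0.5)[1] == 0.0
        assert kern.current(P, -65.0, 6.3, 1.5)[1] == pytest.approx(-0.1)
        assert kern.current(P, -65.0, 6.3, 2.5)[1] == 0.0

    def test_expsyn_net_receive_increments_conductance(self):
        spec = builtin_library()["expsyn"][1]
        kern = generate_kernels(spec, "reference")
        P = spec.default_values()
        kern.init(P, -65.0, 6.3, 0.0)
        kern.net_receive(P, 0.001, 0.0)
        assert P["g"] == pytest.approx(0.001)


def test_builtin_library_contents():
    lib = builtin_library()
    assert set(lib) == {"hh", "pas", "expsyn", "stim"}
    assert lib["pas"][1].states == ()
    assert lib["expsyn"][1].net_receive is not None
    assert lib["hh"][1].solve == ("states", "cnexp")
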