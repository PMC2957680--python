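"""Parser and forward-mode AD: exactness against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddesens as d
from ddesens.errors import (EvaluationDomainError, ExpressionSyntaxError,
                            UndeclaredSymbolError)
from ddesens.expressions import eval_env, grad_env

DECLARED = {"x1": "state", "x2": "state", "p1": "parameter", "p2": "parameter"}


def central_diff(graph, env, name, h=None):
    x = env[name]
    if h is None:
        h = 1e-6 * max(1.0, abs(x))
    hi = dict(env, **{name: x + h})
    lo = dict(env, **{name: x - h})
    return (eval_env(graph, hi) - eval_env(graph, lo)) / (2 * h)


class TestParsing:
    def test_minimal_binary_expression(self):
        g = d.parse_expression("x1 + 2", DECLARED)
        assert g.root.op == "+"
        assert g.root.children[0].kind == "state"
        assert g.root.children[0].name == "x1"
        assert g.root.children[1].value == 2.0
        assert g.free_symbols == {"x1"}

    def test_hill_term_has_expected_operator_count(self):
        decl = {"x2d": "state", "p0": "parameter", "r1": "parameter",
                "n_hill": "parameter"}
        g = d.parse_expression("1/(1+(x2d/p0 + r1)^n_hill)", decl)
        assert g.n_operators == 5
        assert g.free_symbols == {"x2d", "p0", "r1", "n_hill"}

    @pytest.mark.parametrize("text, expected", [
        ("2^3^2", 512.0),        # ^ right-associative
        ("-2^2", -4.0),          # ^ binds tighter than unary minus
        ("2 - 3 - 4", -5.0),     # left-associative
        ("12/3/2", 2.0),
        ("2 + 3 * 4", 14.0),
        ("2 ^ -1", 0.5),
        ("-x1 + 2", 1.0),
        ("1e2 + 1.5e-2", 100.015),
    ])
    def test_precedence_and_associativity(self, text, expected):
        g = d.parse_expression(text, DECLARED)
        assert eval_env(g, {"x1": 1.0}) == pytest.approx(expected, rel=1e-15)

    def test_malformed_input_reports_position(self):
        with pytest.raises(ExpressionSyntaxError) as exc:
            d.parse_expression("x1 + * 2", DECLARED)
        assert exc.value.position == 5

    @pytest.mark.parametrize("text", ["", "   ", "x1 +", "(x1", "foo(x1)",
                                      "x1 2"])
    def test_rejects_malformed_text(self, text):
        with pytest.raises(ExpressionSyntaxError):
            d.parse_expression(text, DECLARED)

    def test_rejects_undeclared_symbol_by_name(self):
        with pytest.raises(UndeclaredSymbolError, match="z"):
            d.parse_expression("x1 + z", DECLARED)

    def test_delayed_reference_requires_declaration(self):
        decl = dict(DECLARED, **{"x2@d1": "delayed_state"})
        g = d.parse_expression("-p1 * x2@d1", decl)
        assert "x2@d1" in g.free_symbols
        with pytest.raises(UndeclaredSymbolError):
            d.parse_expression("x2@nope", DECLARED)


class TestEvaluation:
    def test_hill_midpoint(self):
        decl = {"x2d": "state", "p0": "parameter"}
        g = d.parse_expression("1/(1+(x2d/p0)^8)", decl)
        b = d.Binding(state={"x2d": 100.0}, parameters={"p0": 100.0})
        assert d.evaluate_graph(g, b) == pytest.approx(0.5)

    def test_intrinsics(self):
        g = d.parse_expression("sin(0) + cos(0) + tanh(0) + sqrt(4)", {})
        assert d.evaluate_graph(g, d.Binding()) == pytest.approx(3.0)

    def test_division_by_zero_is_domain_error(self):
        g = d.parse_expression("1/(x1-1)", DECLARED)
        with pytest.raises(EvaluationDomainError, match="division"):
            d.evaluate_graph(g, d.Binding(state={"x1": 1.0}))

    @pytest.mark.parametrize("text, env", [
        ("log(x1)", {"x1": 0.0}),
        ("log(x1)", {"x1": -1.0}),
        ("sqrt(x1)", {"x1": -4.0}),
        ("x1^0.5", {"x1": -1.0}),
        ("x1^-2", {"x1": 0.0}),
    ])
    def test_domain_errors(self, text, env):
        g = d.parse_expression(text, DECLARED)
        with pytest.raises(EvaluationDomainError):
            eval_env(g, env)

    def test_missing_binding_symbol_rejected(self):
        g = d.parse_expression("x1 + p1", DECLARED)
        with pytest.raises(UndeclaredSymbolError):
            d.evaluate_graph(g, d.Binding(state={"x1": 1.0}))


class TestForwardPartials:
    def test_power_rule(self):
        g = d.parse_expression("x1^2", DECLARED)
        v, p = d.forward_partials(g, d.Binding(state={"x1": 3.0}), ["x1"])
        assert v == 9.0
        assert p[0] == 6.0

    def test_chain_rule(self):
        g = d.parse_expression("sin(2*x1)", DECLARED)
        v, p = d.forward_partials(g, d.Binding(state={"x1": 0.0}), ["x1"])
        assert v == 0.0
        assert p[0] == 2.0

    def test_hill_slope_matches_central_difference(self):
        # the baroreflex gain term at its midpoint: slope -n/(4 p0) = -0.02
        decl = {"x2d": "state", "p0": "parameter", "r1": "parameter",
                "n_hill": "parameter"}
        g = d.parse_expression("1/(1+(x2d/p0 + r1)^n_hill)", decl)
        env = {"x2d": 100.0, "p0": 100.0, "r1": 0.0, "n_hill": 8.0}
        b = d.Binding(state={"x2d": 100.0},
                      parameters={"p0": 100.0, "r1": 0.0, "n_hill": 8.0})
        v, p = d.forward_partials(g, b, ["x2d"])
        fd = central_diff(g, env, "x2d")
        assert v == pytest.approx(0.5)
        assert p[0] == pytest.approx(-0.02, rel=1e-12)
        assert p[0] == pytest.approx(fd, rel=1e-7)

    def test_integer_power_valid_for_negative_base(self):
        g = d.parse_expression("x1^3", DECLARED)
        v, p = d.forward_partials(g, d.Binding(state={"x1": -2.0}), ["x1"])
        assert v == -8.0
        assert p[0] == 12.0

    def test_fractional_power_of_negative_base_rejected(self):
        g = d.parse_expression("x1^p1", DECLARED)
        b = d.Binding(state={"x1": -1.0}, parameters={"p1": 0.5})
        with pytest.raises(EvaluationDomainError):
            d.forward_partials(g, b, ["x1"])

    def test_abs_at_zero_uses_subgradient_with_warning(self):
        g = d.parse_expression("abs(x1)", DECLARED)
        with pytest.warns(RuntimeWarning, match="subgradient"):
            v, p = d.forward_partials(g, d.Binding(state={"x1": 0.0}), ["x1"])
        assert v == 0.0
        assert p[0] == 0.0

    def test_value_channel_identical_to_evaluate(self):
        for seed in range(30):
            g, b = d.random_expression_generator(seed, depth=5)
            wrt = sorted(g.free_symbols - {"t"})
            v, _ = d.forward_partials(g, b, wrt)
            assert v == d.evaluate_graph(g, b)  # bit-identical

    def test_fuzzed_graphs_match_central_differences(self):
        # 50 here; the full 200-graph sweep runs in the acceptance suite
        for seed in range(50):
            g, b = d.random_expression_generator(seed, depth=6)
            env = b.to_env()
            wrt = sorted(g.free_symbols - {"t"})
            if not wrt:
                continue
            _, partials = d.forward_partials(g, b, wrt)
            for name, ad in zip(wrt, partials):
                fd = central_diff(g, env, name)
                assert abs(ad - fd) <= 1e-5 * max(1.0, abs(ad)), \
                    f"seed {seed}, d/d{name}: AD {ad} vs FD {fd}"

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), c=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_linearity_of_partials(self, a, b, c):
        """d(u+v)/dx = du/dx + dv/dx and d(c*u)/dx = c*du/dx."""
        decl = DECLARED
        u = d.parse_expression("sin(x1)*x2", decl)
        v = d.parse_expression("x1^2 + x2", decl)
        s = d.parse_expression("sin(x1)*x2 + (x1^2 + x2)", decl)
        bind = d.Binding(state={"x1": a, "x2": b})
        _, gu = d.forward_partials(u, bind, ["x1", "x2"])
        _, gv = d.forward_partials(v, bind, ["x1", "x2"])
        _, gs = d.forward_partials(s, bind, ["x1", "x2"])
        np.testing.assert_allclose(gs, gu + gv, rtol=1e-12, atol=1e-12)
        scaled = d.parse_expression(f"({c!r}) * (sin(x1)*x2)", decl)
        _, gc = d.forward_partials(scaled, bind, ["x1", "x2"])
        np.testing.assert_allclose(gc, c * gu, rtol=1e-12, atol=1e-12)


class TestSystemJacobians:
    def test_linear_decay(self):
        m = d.build_model("[states]\nx = 1.0\n[parameters]\nk = 1.0\n"
                          "[equations]\ndx/dt = -k*x\n")
        b = d.Binding(state={"x": 2.0}, parameters={"k": 1.0})
        A, B, C = d.system_jacobians(m, b)
        np.testing.assert_allclose(A, [[-1.0]])
        assert B.shape == (1, 0)
        np.testing.assert_allclose(C, [[-2.0]])

    def test_all_state_dependence_delayed(self):
        m = d.build_model("[states]\nx = 1.0\n[parameters]\nk = 1.0\n"
                          "[delays]\nd1 = 1.0\n[equations]\ndx/dt = -k*x@d1\n")
        b = d.Binding(state={"x": 5.0}, delayed_state={"x@d1": 3.0},
                      parameters={"k": 1.0})
        A, B, C = d.system_jacobians(m, b)
        np.testing.assert_allclose(A, [[0.0]])
        np.testing.assert_allclose(B, [[-1.0]])
        np.testing.assert_allclose(C, [[-3.0]])

    def test_cardiovascular_jacobians_match_finite_differences(self, cardio):
        m = cardio.model
        env = m.make_env(0.7, np.array([100.0, 100.0]), np.array([100.0]))
        b = d.Binding(time=0.7, state={"x1": 100.0, "x2": 100.0},
                      delayed_state={"x2@d1": 100.0},
                      parameters=dict(m.parameters))
        A, B, C = d.system_jacobians(m, b)
        names = (list(m.states) + list(m.delay_names) + list(m.param_names))
        J = np.hstack([A, B, C])
        for j, name in enumerate(names):
            for i, eq in enumerate(m.equations):
                fd = central_diff(eq, env, name)
                assert abs(J[i, j] - fd) <= 1e-6 * max(1.0, abs(J[i, j])), \
                    f"d f_{i} / d {name}"


class TestSympyOracle:
    """Cross-check value and gradient against symbolic differentiation."""

    CASES = [
        "x1*sin(x2) + exp(-p1*x1)",
        "1/(1+(x1/p1)^3) - tanh(x2*p2)",
        "log(x1 + 2) * sqrt(p1 + 1) + cos(x1*x2)",
        "(x1 - x2)^2 / (p1 + 0.5) + x1*p2",
    ]

    @pytest.mark.parametrize("text", CASES)
    def test_against_sympy(self, text):
        sympy = pytest.importorskip("sympy")
        syms = {n: sympy.Symbol(n) for n in ("x1", "x2", "p1", "p2")}
        expr = sympy.sympify(text.replace("^", "**"), locals=syms)
        g = d.parse_expression(text, DECLARED)
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = {n: float(v)
                    for n, v in zip(syms, rng.uniform(0.3, 1.7, size=4))}
            b = d.Binding(state={k: vals[k] for k in ("x1", "x2")},
                          parameters={k: vals[k] for k in ("p1", "p2")})
            wrt = sorted(g.free_symbols)
            v, partials = d.forward_partials(g, b, wrt)
            assert v == pytest.approx(float(expr.subs(vals)), rel=1e-12)
            for name, ad in zip(wrt, partials):
                exact = float(sympy.diff(expr, syms[name]).subs(vals))
                assert ad == pytest.approx(exact, rel=1e-10, abs=1e-12)
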