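"""Expression graphs with forward-mode automatic differentiation.

Model right-hand sides are supplied at run time as plain text.  They are parsed
into small expression trees whose nodes are elementary arithmetic operators
(``+ - * / ^``), intrinsic functions (``sin cos tan exp log sqrt abs tanh``),
and primitives (constants, state variables, delayed state variables,
parameters, and the time variable ``t``).  Partial derivatives are obtained by
a single bottom-up sweep that carries a (value, gradient) pair per node and
applies the chain rule at every elementary operation, so derivatives are exact
up to floating-point round-off — no symbolic expansion, no finite-difference
truncation.

The grammar uses standard precedence: ``^`` binds tighter than unary minus,
which binds tighter than ``* /``, which bind tighter than ``+ -``.  All binary
operators are left-associative except ``^`` (right-associative).  Delayed
state references are written ``name@label`` where the label names a declared
discrete delay (e.g. ``x2@d1`` for x2 evaluated one delay-duration ago).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .errors import EvaluationDomainError, ExpressionSyntaxError, UndeclaredSymbolError

if TYPE_CHECKING:  # pragma: no cover
    from .model import DDEModel

__all__ = [
    "INTRINSICS",
    "ExprNode",
    "ExpressionGraph",
    "Binding",
    "parse_expression",
    "evaluate_graph",
    "forward_partials",
    "system_jacobians",
]

INTRINSICS = ("sin", "cos", "tan", "exp", "log", "sqrt", "abs", "tanh")

#: node kinds a reference leaf may carry
_REF_KINDS = ("state", "delayed_state", "parameter")


class ExprNode:
    """One node of a parsed expression tree.

    ``kind`` is one of ``constant | state | delayed_state | parameter | time |
    unary | binary | call``.  Binary nodes have exactly two children, unary and
    call nodes exactly one, leaves none.
    """

    __slots__ = ("kind", "value", "name", "op", "func", "children", "pos")

    def __init__(self, kind, *, value=None, name=None, op=None, func=None,
                 children=(), pos=None):
        self.kind = kind
        self.value = value
        self.name = name
        self.op = op
        self.func = func
        self.children = tuple(children)
        self.pos = pos

    def __eq__(self, other):
        if not isinstance(other, ExprNode):
            return NotImplemented
        return (self.kind == other.kind and self.value == other.value
                and self.name == other.name and self.op == other.op
                and self.func == other.func and self.children == other.children)

    def __hash__(self):
        return hash((self.kind, self.value, self.name, self.op, self.func,
                     self.children))

    def __repr__(self):  # compact s-expression, handy in test failures
        if self.kind == "constant":
            return f"(const {self.value!r})"
        if self.kind in _REF_KINDS:
            return f"({self.kind} {self.name})"
        if self.kind == "time":
            return "(time t)"
        if self.kind == "unary":
            return f"(neg {self.children[0]!r})"
        if self.kind == "binary":
            return f"({self.op} {self.children[0]!r} {self.children[1]!r})"
        return f"({self.func} {self.children[0]!r})"


@dataclass
class ExpressionGraph:
    """A parsed right-hand-side expression plus its free symbols."""

    root: ExprNode
    free_symbols: frozenset[str]
    source: str = ""
    _tape: list | None = field(default=None, repr=False, compare=False)

    def tape(self):
        if self._tape is None:
            self._tape = _compile(self.root)
        return self._tape

    @property
    def n_operators(self) -> int:
        """Number of operator/intrinsic nodes (excludes leaves)."""
        return sum(1 for ins in self.tape() if ins[0] >= _NEG)


@dataclass
class Binding:
    """Concrete values for every free symbol of a graph at one time point."""

    time: float = 0.0
    state: Mapping[str, float] = field(default_factory=dict)
    delayed_state: Mapping[str, float] = field(default_factory=dict)
    parameters: Mapping[str, float] = field(default_factory=dict)

    def to_env(self) -> dict[str, float]:
        env = dict(self.parameters)
        env.update(self.state)
        env.update(self.delayed_state)
        env["t"] = self.time
        return env


# ---------------------------------------------------------------------------
# tokenizer / parser
# ---------------------------------------------------------------------------

_OPS = "+-*/^"


def _tokenize(text: str):
    tokens = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            try:
                val = float(text[i:j])
            except ValueError:
                raise ExpressionSyntaxError(f"bad number '{text[i:j]}'", i)
            tokens.append(("num", val, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            name = text[i:j]
            if j < n and text[j] == "@":
                k = j + 1
                m = k
                while m < n and (text[m].isalnum() or text[m] == "_"):
                    m += 1
                if m == k:
                    raise ExpressionSyntaxError("expected delay label after '@'", j)
                name = text[i:j] + "@" + text[k:m]
                tokens.append(("dref", name, i))
                i = m
                continue
            tokens.append(("ident", name, i))
            i = j
            continue
        if c in _OPS:
            tokens.append(("op", c, i))
            i += 1
            continue
        if c == "(":
            tokens.append(("lparen", c, i))
            i += 1
            continue
        if c == ")":
            tokens.append(("rparen", c, i))
            i += 1
            continue
        raise ExpressionSyntaxError(f"unexpected character '{c}'", i)
    tokens.append(("end", "", n))
    return tokens


class _Parser:
    def __init__(self, text: str, declared: Mapping[str, str]):
        self.text = text
        self.tokens = _tokenize(text)
        self.k = 0
        self.declared = declared

    def peek(self):
        return self.tokens[self.k]

    def next(self):
        tok = self.tokens[self.k]
        self.k += 1
        return tok

    def error(self, msg):
        kind, val, pos = self.peek()
        shown = "end of expression" if kind == "end" else f"token '{val}'"
        raise ExpressionSyntaxError(f"{msg}, found {shown}", pos)

    # expr := term (('+'|'-') term)*
    def expr(self):
        node = self.term()
        while self.peek()[0] == "op" and self.peek()[1] in "+-":
            _, op, pos = self.next()
            rhs = self.term()
            node = ExprNode("binary", op=op, children=(node, rhs), pos=pos)
        return node

    # term := factor (('*'|'/') factor)*
    def term(self):
        node = self.factor()
        while self.peek()[0] == "op" and self.peek()[1] in "*/":
            _, op, pos = self.next()
            rhs = self.factor()
            node = ExprNode("binary", op=op, children=(node, rhs), pos=pos)
        return node

    # factor := '-' factor | power       (unary minus binds looser than '^')
    def factor(self):
        if self.peek()[0] == "op" and self.peek()[1] == "-":
            _, _, pos = self.next()
            child = self.factor()
            return ExprNode("unary", op="-", children=(child,), pos=pos)
        if self.peek()[0] == "op" and self.peek()[1] == "+":
            self.next()
            return self.factor()
        return self.power()

    # power := atom ('^' factor)?        (right-associative)
    def power(self):
        node = self.atom()
        if self.peek()[0] == "op" and self.peek()[1] == "^":
            _, _, pos = self.next()
            rhs = self.factor()
            node = ExprNode("binary", op="^", children=(node, rhs), pos=pos)
        return node

    def atom(self):
        kind, val, pos = self.peek()
        if kind == "num":
            self.next()
            return ExprNode("constant", value=val, pos=pos)
        if kind == "lparen":
            self.next()
            node = self.expr()
            if self.peek()[0] != "rparen":
                self.error("expected ')'")
            self.next()
            return node
        if kind == "dref":
            self.next()
            if self.declared.get(val) != "delayed_state":
                raise UndeclaredSymbolError(val, pos)
            return ExprNode("delayed_state", name=val, pos=pos)
        if kind == "ident":
            self.next()
            if self.peek()[0] == "lparen":
                if val not in INTRINSICS:
                    raise ExpressionSyntaxError(f"unknown function '{val}'", pos)
                self.next()
                arg = self.expr()
                if self.peek()[0] != "rparen":
                    self.error("expected ')'")
                self.next()
                return ExprNode("call", func=val, children=(arg,), pos=pos)
            ref_kind = self.declared.get(val)
            if ref_kind is None:
                raise UndeclaredSymbolError(val, pos)
            return ExprNode(ref_kind, name=val, pos=pos)
        self.error("expected a value")


def parse_expression(text: str,
                     declared_symbols: Mapping[str, str] | Sequence[str] | set,
                     ) -> ExpressionGraph:
    """Parse expression ``text`` into an :class:`ExpressionGraph`.

    ``declared_symbols`` is either a mapping from identifier to one of
    ``{"state", "delayed_state", "parameter", "time"}``, or a plain collection
    of identifiers (then all are treated as parameters).  The time variable
    ``t`` is always available.  Unknown identifiers are rejected.
    """
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    if isinstance(declared_symbols, Mapping):
        declared = dict(declared_symbols)
    else:
        declared = {name: "parameter" for name in declared_symbols}
    declared.setdefault("t", "time")
    parser = _Parser(text, declared)
    root = parser.expr()
    if parser.peek()[0] != "end":
        parser.error("unexpected trailing input")
    free = frozenset(_collect_refs(root))
    return ExpressionGraph(root=root, free_symbols=free, source=text)


def _collect_refs(node: ExprNode, acc=None):
    if acc is None:
        acc = set()
    if node.kind in _REF_KINDS:
        acc.add(node.name)
    elif node.kind == "time":
        acc.add("t")
    for c in node.children:
        _collect_refs(c, acc)
    return acc


# ---------------------------------------------------------------------------
# tape compilation and evaluation
# ---------------------------------------------------------------------------
# The tree is flattened once into a post-order "tape" of instructions; a value
# sweep (and optionally a gradient sweep) is then a flat Python loop, which is
# what keeps run-time Jacobian evaluation cheap inside the integrator.

_CONST, _REF, _TIME, _NEG, _ADD, _SUB, _MUL, _DIV, _POW, _CALL = range(10)

_OPCODE = {"+": _ADD, "-": _SUB, "*": _MUL, "/": _DIV, "^": _POW}


def _compile(root: ExprNode) -> list:
    tape = []

    def walk(node: ExprNode) -> int:
        if node.kind == "constant":
            tape.append((_CONST, -1, -1, node.value, node.pos))
        elif node.kind in _REF_KINDS:
            tape.append((_REF, -1, -1, node.name, node.pos))
        elif node.kind == "time":
            tape.append((_TIME, -1, -1, None, node.pos))
        elif node.kind == "unary":
            a = walk(node.children[0])
            tape.append((_NEG, a, -1, None, node.pos))
        elif node.kind == "binary":
            a = walk(node.children[0])
            b = walk(node.children[1])
            tape.append((_OPCODE[node.op], a, b, None, node.pos))
        elif node.kind == "call":
            a = walk(node.children[0])
            tape.append((_CALL, a, -1, node.func, node.pos))
        else:  # pragma: no cover - parser never produces other kinds
            raise AssertionError(node.kind)
        return len(tape) - 1

    walk(root)
    return tape


def _pow_value(u: float, v: float, pos) -> float:
    if u > 0.0:
        return u ** v
    if v == int(v):
        if u == 0.0 and v < 0:
            raise EvaluationDomainError(
                f"0 raised to negative power {v:g} (at position {pos})")
        return u ** int(v)
    raise EvaluationDomainError(
        f"negative base {u:.6g} with fractional exponent {v:.6g} "
        f"(at position {pos})")


def _call_value(func: str, u: float, pos) -> float:
    if func == "sin":
        return math.sin(u)
    if func == "cos":
        return math.cos(u)
    if func == "tan":
        return math.tan(u)
    if func == "exp":
        return math.exp(u)
    if func == "log":
        if u <= 0.0:
            raise EvaluationDomainError(
                f"log of non-positive argument {u:.6g} (at position {pos})")
        return math.log(u)
    if func == "sqrt":
        if u < 0.0:
            raise EvaluationDomainError(
                f"sqrt of negative argument {u:.6g} (at position {pos})")
        return math.sqrt(u)
    if func == "abs":
        return abs(u)
    if func == "tanh":
        return math.tanh(u)
    raise AssertionError(func)  # pragma: no cover


def eval_env(graph: ExpressionGraph, env: Mapping[str, float]) -> float:
    """Evaluate ``graph`` against a flat name->value environment."""
    vals = []
    append = vals.append
    for code, a, b, payload, pos in graph.tape():
        if code == _CONST:
            append(payload)
        elif code == _REF:
            append(env[payload])
        elif code == _TIME:
            append(env["t"])
        elif code == _ADD:
            append(vals[a] + vals[b])
        elif code == _SUB:
            append(vals[a] - vals[b])
        elif code == _MUL:
            append(vals[a] * vals[b])
        elif code == _DIV:
            d = vals[b]
            if d == 0.0:
                raise EvaluationDomainError(
                    f"division by zero (at position {pos})")
            append(vals[a] / d)
        elif code == _NEG:
            append(-vals[a])
        elif code == _POW:
            append(_pow_value(vals[a], vals[b], pos))
        else:  # _CALL
            append(_call_value(payload, vals[a], pos))
    return vals[-1]


def evaluate_graph(graph: ExpressionGraph, binding: Binding) -> float:
    """Evaluate a graph at one binding; pure function of the leaf values."""
    missing = graph.free_symbols - set(binding.to_env())
    if missing:
        raise UndeclaredSymbolError(sorted(missing)[0])
    return eval_env(graph, binding.to_env())


def grad_env(graph: ExpressionGraph, env: Mapping[str, float],
             wrt: Sequence[str]) -> tuple[float, list[float]]:
    """One bottom-up chain-rule sweep: value and d(value)/d(wrt_j) for all j.

    The value channel computes exactly the same floating-point operations as
    :func:`eval_env`, so the two agree bit-for-bit.
    """
    w = len(wrt)
    index = {name: i for i, name in enumerate(wrt)}
    zeros = [0.0] * w  # shared read-only
    vals: list[float] = []
    grads: list[list[float]] = []
    for code, a, b, payload, pos in graph.tape():
        if code == _CONST:
            v, g = payload, zeros
        elif code == _REF:
            v = env[payload]
            i = index.get(payload)
            if i is None:
                g = zeros
            else:
                g = [0.0] * w
                g[i] = 1.0
        elif code == _TIME:
            v = env["t"]
            i = index.get("t")
            if i is None:
                g = zeros
            else:
                g = [0.0] * w
                g[i] = 1.0
        elif code == _ADD:
            v = vals[a] + vals[b]
            ga, gb = grads[a], grads[b]
            g = [p + q for p, q in zip(ga, gb)]
        elif code == _SUB:
            v = vals[a] - vals[b]
            ga, gb = grads[a], grads[b]
            g = [p - q for p, q in zip(ga, gb)]
        elif code == _MUL:
            u, x = vals[a], vals[b]
            v = u * x
            ga, gb = grads[a], grads[b]
            g = [x * p + u * q for p, q in zip(ga, gb)]
        elif code == _DIV:
            u, x = vals[a], vals[b]
            if x == 0.0:
                raise EvaluationDomainError(
                    f"division by zero (at position {pos})")
            v = u / x
            ga, gb = grads[a], grads[b]
            g = [(p - v * q) / x for p, q in zip(ga, gb)]
        elif code == _NEG:
            v = -vals[a]
            g = [-p for p in grads[a]]
        elif code == _POW:
            u, x = vals[a], vals[b]
            v = _pow_value(u, x, pos)
            ga, gb = grads[a], grads[b]
            exp_active = any(q != 0.0 for q in gb)
            if u > 0.0:
                du = x * (u ** (x - 1.0))
                if exp_active:
                    dv = v * math.log(u)
                    g = [du * p + dv * q for p, q in zip(ga, gb)]
                else:
                    g = [du * p for p in ga]
            else:
                # u <= 0: only defined for an exponent that is an inactive
                # integer constant -> plain power rule (covers Hill exponents
                # when the base transiently touches zero or goes negative).
                if exp_active:
                    raise EvaluationDomainError(
                        f"derivative of {u:.6g}^{x:.6g} with active exponent "
                        f"(at position {pos})")
                c = int(x)
                if u == 0.0 and c < 1:
                    raise EvaluationDomainError(
                        f"derivative of 0^{c} undefined (at position {pos})")
                du = float(c) * (u ** (c - 1)) if c != 0 else 0.0
                g = [du * p for p in ga]
        else:  # _CALL
            u = vals[a]
            v = _call_value(payload, u, pos)
            if payload == "sin":
                d = math.cos(u)
            elif payload == "cos":
                d = -math.sin(u)
            elif payload == "tan":
                d = 1.0 + v * v
            elif payload == "exp":
                d = v
            elif payload == "log":
                d = 1.0 / u
            elif payload == "sqrt":
                if u == 0.0:
                    raise EvaluationDomainError(
                        f"derivative of sqrt at 0 (at position {pos})")
                d = 0.5 / v
            elif payload == "abs":
                if u == 0.0:
                    warnings.warn("abs differentiated at 0; using subgradient 0",
                                  RuntimeWarning, stacklevel=3)
                    d = 0.0
                else:
                    d = 1.0 if u > 0.0 else -1.0
            else:  # tanh
                d = 1.0 - v * v
            g = [d * p for p in grads[a]]
        vals.append(v)
        grads.append(g)
    return vals[-1], grads[-1]


def forward_partials(graph: ExpressionGraph, binding: Binding,
                     wrt: Sequence[str]) -> tuple[float, np.ndarray]:
    """Value and exact partial derivatives with respect to ``wrt``.

    Returns ``(value, partials)`` where ``partials[j] = d graph / d wrt[j]``
    at the binding.  The value equals :func:`evaluate_graph` bit-for-bit.
    """
    v, g = grad_env(graph, binding.to_env(), list(wrt))
    return v, np.asarray(g, dtype=float)


def system_jacobians(model: "DDEModel", binding: Binding,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jacobians of the model right-hand side at one binding.

    Returns ``(A, B, C)`` with ``A = df/dx`` (n x n, current states),
    ``B = df/dy`` (n x m, delayed states), ``C = df/dtheta`` (n x p,
    parameters), each row obtained from a single chain-rule sweep over the
    corresponding equation graph.
    """
    env = binding.to_env()
    return _jacobians_env(model, env)


def _jacobians_env(model: "DDEModel", env: Mapping[str, float],
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m, p = model.n, model.m, model.p
    wrt = list(model.states) + list(model.delay_names) + list(model.param_names)
    J = np.empty((n, n + m + p))
    for i, eq in enumerate(model.equations):
        _, g = grad_env(eq, env, wrt)
        J[i, :] = g
    return J[:, :n], J[:, n:n + m], J[:, n + m:]
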