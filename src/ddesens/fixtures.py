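"""Bundled models, analytic test problems, and independent oracles.

The oracles validate the solver and the AD engine without ever using them as
their own reference:

* closed-form method-of-steps solutions for the linear test DDE;
* a reference integrator (method of steps over scipy's adaptive Runge-Kutta
  steppers with dense output) standing in for an external DDE solver;
* forward-difference sensitivities obtained by re-solving perturbed models
  with that reference integrator;
* a deterministic random-expression generator for fuzzing the AD sweep
  against central finite differences.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import FixtureUnavailableError
from .expressions import Binding, ExpressionGraph, ExprNode, _collect_refs, eval_env
from .model import DDEModel, SamplingGrid, SolverConfig, load_model
from .sensitivity import SensitivitySeries

__all__ = [
    "ModelFixture",
    "cardiovascular_model",
    "linear_dde_fixture",
    "exponential_decay_fixture",
    "reference_solve",
    "finite_difference_sensitivities",
    "random_expression_generator",
    "tnf_model",
]


@dataclass
class ModelFixture:
    """A ready-to-solve model, optionally with its exact solution attached."""

    model: DDEModel
    analytic_solution: Callable[[float], np.ndarray] | None
    notes: str
    grid: SamplingGrid | None = None
    config: SolverConfig | None = None


def cardiovascular_model(**param_overrides: float) -> ModelFixture:
    """The two-state baroreflex model of heart rate and blood pressure.

    16 parameters at their published nominal values, one unit delay in
    dimensionless time.  The published parameter set does not include initial
    conditions; the fixture starts the system at the uncontrolled operating
    point x1(0) = h0 = 100, x2(0) = p0 = 100 (an assumption, recorded in
    ``notes``).  Keyword overrides replace nominal parameter values, e.g.
    ``cardiovascular_model(A1=0.0, A2=0.0)`` switches respiration off.
    """
    text = (resources.files("ddesens") / "models" / "cardiovascular.dde"
            ).read_text()
    model, grid, cfg = load_model(text)
    if param_overrides:
        model = model.with_parameters(**param_overrides)
    return ModelFixture(
        model=model,
        analytic_solution=None,
        notes=("Initial conditions x1(0)=h0, x2(0)=p0 and the sampling "
               "horizon t in [0, 200] with step 0.02 are fixture choices; "
               "they are not part of the published parameter table."),
        grid=grid,
        config=cfg,
    )


def linear_dde_fixture(theta: float = 1.0, tau: float = 1.0,
                       c: float = 1.0) -> ModelFixture:
    """dx/dt = -theta * x(t - tau) with constant history c.

    The attached closed form is the method-of-steps solution: on the k-th
    delay interval [(k-1)*tau, k*tau]

        x(t) = c * sum_{j=0}^{k} (-theta)^j (t - (j-1)*tau)^j / j!,

    a piecewise polynomial of increasing degree (x(t) = c*(1 - theta*t) on
    the first interval, etc.).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    text = "\n".join([
        "[states]",
        f"x = {c!r}",
        "[parameters]",
        f"theta = {theta!r}",
        "[delays]",
        f"d = {tau!r}",
        "[equations]",
        "dx/dt = -theta * x@d",
        "[options]",
        "t0 = 0.0",
    ])
    model, _, _ = load_model(text)

    def analytic(t: float) -> np.ndarray:
        if t <= 0:
            return np.array([c])
        k = int(math.ceil(t / tau - 1e-12))
        acc = 0.0
        for j in range(k + 1):
            acc += ((-theta) ** j) * (t - (j - 1) * tau) ** j / math.factorial(j)
        return np.array([c * acc])

    return ModelFixture(model=model, analytic_solution=analytic,
                        notes="linear single-delay test problem")


def exponential_decay_fixture(theta: float = 1.0,
                              x0: float = 1.0) -> ModelFixture:
    """dx/dt = -theta * x, the delay-free special case with known solution
    x(t) = x0 * exp(-theta t) and sensitivity dx/dtheta = -t x0 exp(-theta t)."""
    text = "\n".join([
        "[states]",
        f"x = {x0!r}",
        "[parameters]",
        f"theta = {theta!r}",
        "[equations]",
        "dx/dt = -theta * x",
        "[options]",
        "t0 = 0.0",
    ])
    model, _, _ = load_model(text)
    analytic = lambda t: np.array([x0 * math.exp(-theta * t)])
    return ModelFixture(model=model, analytic_solution=analytic,
                        notes="linear decay (no delay)")


# ---------------------------------------------------------------------------
# reference integrator (independent of the trapezoidal solver)
# ---------------------------------------------------------------------------

def reference_solve(model: DDEModel, grid: SamplingGrid,
                    rtol: float = 1e-9, atol: float = 1e-9,
                    method: str = "RK45") -> tuple[np.ndarray, np.ndarray]:
    """Method of steps over scipy's adaptive ODE steppers.

    Integrates segment-by-segment (segments no longer than the smallest
    delay) so that every delayed lookup lands in already completed dense
    output; delay-free models are integrated in one sweep.  Returns
    ``(times, states)`` with times = [t0] + grid points.
    """
    t0, t_end = model.t0, float(grid.points[-1])
    taus = model.delay_durations
    idx = model.delay_state_indices
    seg_len = min(taus) if taus else (t_end - t0)
    seg_ends: list[float] = []
    seg_sols: list = []

    def history(t: float) -> np.ndarray:
        if t <= t0:
            return model.x0
        i = bisect_left(seg_ends, t)
        if i == len(seg_ends):
            i -= 1
        return seg_sols[i](t)

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        y = np.array([history(t - tau)[j] for j, tau in zip(idx, taus)])
        return model.rhs_env(model.make_env(t, x, y))

    t, x = t0, model.x0.copy()
    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        t_next = min(t + seg_len, t_end)
        sol = solve_ivp(rhs, (t, t_next), x, method=method, rtol=rtol,
                        atol=atol, dense_output=True)
        if not sol.success:  # pragma: no cover - scipy failure surface
            raise RuntimeError(f"reference solver failed at t={t}: "
                               f"{sol.message}")
        seg_ends.append(t_next)
        seg_sols.append(sol.sol)
        x = sol.y[:, -1]
        t = t_next

    times = np.concatenate(([t0], grid.points))
    states = np.array([model.x0 if s <= t0 else history(s) for s in times])
    return times, states


def finite_difference_sensitivities(
        model: DDEModel, grid: SamplingGrid, spacing_ratio: float,
        parameters: Sequence[str] | None = None,
        include_initial_conditions: bool = False,
        solver: Callable | None = None,
        rtol: float = 1e-9, atol: float = 1e-9) -> SensitivitySeries:
    """Forward-difference absolute sensitivities on an independent solver.

    Each chosen parameter (and optionally each initial condition) theta_j is
    perturbed by Delta = spacing_ratio * theta_j (absolute fallback 1e-6 when
    theta_j = 0), the model is re-solved, and the forward quotient
    (x_perturbed - x_nominal) / Delta is formed at the grid points.  The
    solver defaults to :func:`reference_solve`; the trapezoidal solver under
    test is deliberately never used here.
    """
    if not 0 < spacing_ratio <= 0.5:
        raise ValueError("spacing_ratio must lie in (0, 0.5]")
    if solver is None:
        solver = lambda m: reference_solve(m, grid, rtol=rtol, atol=atol)[1]
    if parameters is None:
        parameters = list(model.param_names)
    unknown = set(parameters) - set(model.param_names)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")

    base = solver(model)
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for name in parameters:
        theta = model.parameters[name]
        delta = spacing_ratio * theta if theta != 0 else 1e-6
        pert = solver(model.with_parameters(**{name: theta + delta}))
        cols.append((pert - base) / delta)
        labels.append(name)
    if include_initial_conditions:
        for j, sname in enumerate(model.states):
            x0j = model.x0[j]
            delta = spacing_ratio * x0j if x0j != 0 else 1e-6
            x0 = model.x0.copy()
            x0[j] += delta
            pert = solver(model.with_initial_conditions(x0))
            cols.append((pert - base) / delta)
            labels.append(f"{sname}(0)")

    times = np.concatenate(([model.t0], grid.points))
    matrices = np.stack(cols, axis=-1)  # (k, n, q_selected)
    return SensitivitySeries(times=times, matrices=matrices,
                             column_labels=tuple(labels),
                             state_names=model.states)


# ---------------------------------------------------------------------------
# random expression fuzzing
# ---------------------------------------------------------------------------

_FUZZ_SYMBOLS = {"x1": "state", "x2": "state", "p1": "parameter",
                 "p2": "parameter"}
_FUZZ_CALLS = ("sin", "cos", "tan", "exp", "log", "sqrt", "abs", "tanh")


def _random_node(rng: np.random.Generator, depth: int) -> ExprNode:
    if depth <= 0 or rng.random() < 0.3:
        if rng.random() < 0.4:
            return ExprNode("constant", value=float(np.round(
                rng.uniform(0.5, 2.0), 3)))
        name = str(rng.choice(list(_FUZZ_SYMBOLS)))
        return ExprNode(_FUZZ_SYMBOLS[name], name=name)
    r = rng.random()
    if r < 0.55:
        op = str(rng.choice(["+", "-", "*", "/"]))
        return ExprNode("binary", op=op,
                        children=(_random_node(rng, depth - 1),
                                  _random_node(rng, depth - 1)))
    if r < 0.65:
        # powers restricted to small integer constant exponents so fuzzed
        # values stay in a range where finite differences are well posed
        exponent = ExprNode("constant", value=float(rng.integers(2, 4)))
        return ExprNode("binary", op="^",
                        children=(_random_node(rng, depth - 1), exponent))
    if r < 0.75:
        return ExprNode("unary", op="-",
                        children=(_random_node(rng, depth - 1),))
    func = str(rng.choice(_FUZZ_CALLS))
    return ExprNode("call", func=func,
                    children=(_random_node(rng, depth - 1),))


def _binding_is_safe(graph: ExpressionGraph, env: dict) -> bool:
    """Reject (graph, binding) pairs near domain or conditioning edges:
    small divisors, log/sqrt arguments below 0.1, |abs| arguments below 0.01,
    tangent near its pole, large exponentials, or any node value above 50."""
    from .expressions import _CALL, _CONST, _DIV, _REF, _TIME
    vals = []
    for code, a, b, payload, _pos in graph.tape():
        try:
            if code == _CONST:
                v = payload
            elif code == _REF:
                v = env[payload]
            elif code == _TIME:
                v = env["t"]
            elif code == _DIV:
                if abs(vals[b]) < 0.1:
                    return False
                v = vals[a] / vals[b]
            elif code == _CALL:
                u = vals[a]
                if payload in ("log", "sqrt") and u < 0.1:
                    return False
                if payload == "abs" and abs(u) < 0.01:
                    return False
                if payload == "tan" and abs(math.cos(u)) < 0.3:
                    return False
                if payload == "exp" and u > 4.0:
                    return False
                from .expressions import _call_value
                v = _call_value(payload, u, None)
            else:
                from .expressions import _ADD, _MUL, _NEG, _POW, _SUB
                if code == _ADD:
                    v = vals[a] + vals[b]
                elif code == _SUB:
                    v = vals[a] - vals[b]
                elif code == _MUL:
                    v = vals[a] * vals[b]
                elif code == _NEG:
                    v = -vals[a]
                else:  # _POW, exponent is a safe integer constant
                    v = vals[a] ** vals[b]
        except (OverflowError, ValueError):
            return False
        if not math.isfinite(v) or abs(v) > 50.0:
            return False
        vals.append(v)
    return True


def random_expression_generator(seed: int, depth: int = 6,
                                ) -> tuple[ExpressionGraph, Binding]:
    """Deterministic fuzz case: a random expression graph plus a binding that
    keeps every intermediate value finite, moderate, and away from domain
    boundaries.  The same seed always yields the same (graph, binding)."""
    if depth < 0 or depth > 6:
        raise ValueError("depth must lie in [0, 6]")
    rng = np.random.default_rng(seed)
    for _ in range(500):
        root = _random_node(rng, depth)
        free = _collect_refs(root)
        values = {name: float(np.round(rng.uniform(0.5, 2.0), 6))
                  for name in sorted(free)}
        t_val = values.pop("t", float(np.round(rng.uniform(0.5, 2.0), 6)))
        graph = ExpressionGraph(root=root,
                                free_symbols=frozenset(free))
        env = dict(values)
        env["t"] = t_val
        if _binding_is_safe(graph, env):
            binding = Binding(
                time=t_val,
                state={k: v for k, v in values.items()
                       if _FUZZ_SYMBOLS.get(k) == "state"},
                parameters={k: v for k, v in values.items()
                            if _FUZZ_SYMBOLS.get(k) == "parameter"},
            )
            return graph, binding
    raise RuntimeError("could not draw a safe random expression "
                       f"for seed {seed}")  # pragma: no cover


def tnf_model() -> ModelFixture:
    """The 31-species TNF-alpha apoptosis/survival signalling model.

    Not bundled: its equations, species definitions and nominal parameter
    values live only in the original supplementary material, which this
    package does not redistribute.  To use it, transcribe the supplement
    into the sectioned model file format (31 [states] entries with the Table
    S1 initial concentrations, 29 [parameters], a 20-minute [delays] entry
    for the delayed cIAP/IkB transcription terms, and one equation per
    species) and load it with :func:`ddesens.model.load_model`.
    """
    raise FixtureUnavailableError(tnf_model.__doc__)
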