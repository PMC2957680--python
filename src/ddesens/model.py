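"""DDE model container and plain-text model file format.

A model is a system of n delay differential equations

    dx_i/dt = f_i(x(t), x(t - tau_1), ..., x(t - tau_r); theta),

with p parameters theta, discrete positive delays tau_k, initial values
x(t0) = x0, and a *constant* initial history x(t) = x0 for t <= t0.  The
sensitivity state is an n x q matrix Phi with q = p + n columns: first the
parameter sensitivities, then the sensitivities with respect to the initial
conditions (whose block of Phi(t0) is the identity).

Model file format (sectioned plain text, '#' comments, LF or CRLF)::

    [states]
    x1 = 100.0          # name = initial value; order defines indices
    [parameters]
    beta = 10.0
    [delays]
    d1 = 1.0            # label = duration (time units of the model)
    [equations]
    dx1/dt = -beta * x1@d1
    [options]
    t0 = 0.0
    sampling = 0:10:0.01    # start:stop:step, or comma-separated list
    epsilon = 1e-3
    iteration_limit = 20
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ModelParseError
from .expressions import (INTRINSICS, ExpressionGraph, eval_env,
                          parse_expression)

__all__ = [
    "DelayTerm",
    "DDEModel",
    "SamplingGrid",
    "SolverConfig",
    "build_model",
    "load_model",
    "serialize_model",
    "initial_history",
]

_RESERVED = set(INTRINSICS) | {"t"}


@dataclass(frozen=True)
class DelayTerm:
    """One delayed variable y = state(t - delay), addressed as state@label."""

    label: str
    state_name: str
    delay: float

    @property
    def name(self) -> str:
        return f"{self.state_name}@{self.label}"


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances of the adaptive solver.

    epsilon is the stiffness tolerance (the run aborts when mu*epsilon >= 1,
    mu being the Jacobian-norm bound); the fixed-point correctors stop when
    every component changes by less than atol + rtol*|value|, and fail after
    iteration_limit sweeps.
    """

    epsilon: float = 1e-3
    iteration_limit: int = 20
    convergence_rtol: float = 1e-8
    convergence_atol: float = 1e-12

    def __post_init__(self):
        if self.epsilon <= 0 or self.iteration_limit <= 0 \
                or self.convergence_rtol <= 0 or self.convergence_atol <= 0:
            raise ValueError("all solver tolerances must be positive")


@dataclass(frozen=True)
class SamplingGrid:
    """Strictly increasing output times, all greater than the model's t0."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size == 0:
            raise ValueError("sampling grid must be a non-empty 1-d sequence")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("sampling points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_string(cls, text: str, t0: float = 0.0) -> "SamplingGrid":
        text = text.strip()
        if ":" in text:
            parts = text.split(":")
            if len(parts) != 3:
                raise ValueError(f"bad sampling spec '{text}' "
                                 "(expected start:stop:step)")
            start, stop, step = (float(p) for p in parts)
            if step <= 0 or stop <= start:
                raise ValueError(f"bad sampling spec '{text}'")
            k = int(round((stop - start) / step))
            pts = start + step * np.arange(1, k + 1)
            if start > t0:
                pts = np.concatenate(([start], pts))
        else:
            pts = np.array([float(p) for p in text.split(",")])
        return cls(pts)

    def validate_against(self, t0: float) -> None:
        if self.points[0] <= t0:
            raise ValueError(
                f"first sampling point {self.points[0]} must exceed t0={t0}")

    def __len__(self):
        return len(self.points)


class DDEModel:
    """A validated DDE system with parameters, delays and initial data."""

    def __init__(self, states: Iterable[str], parameters: Mapping[str, float],
                 delays: Iterable[DelayTerm], equations: Iterable[ExpressionGraph],
                 x0: Iterable[float], t0: float = 0.0,
                 phi0: np.ndarray | None = None):
        self.states = tuple(states)
        self.parameters = dict(parameters)
        self.delays = tuple(delays)
        self.equations = tuple(equations)
        self.x0 = np.asarray(list(x0), dtype=float)
        self.t0 = float(t0)
        n, p = len(self.states), len(self.parameters)
        if len(self.equations) != n or self.x0.shape != (n,):
            raise ValueError("states, equations and x0 must have equal length")
        if phi0 is None:
            phi0 = np.zeros((n, p + n))
            phi0[:, p:] = np.eye(n)
        phi0 = np.asarray(phi0, dtype=float)
        if phi0.shape != (n, p + n):
            raise ValueError(f"phi0 must be {n}x{p + n}, got {phi0.shape}")
        self.phi0 = phi0
        self._validate()
        # caches used by the integrator hot loop
        self._param_env = dict(self.parameters)
        self._jac_wrt = (list(self.states) + list(self.delay_names)
                         + list(self.param_names))

    # -- derived quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def p(self) -> int:
        return len(self.parameters)

    @property
    def m(self) -> int:
        return len(self.delays)

    @property
    def q(self) -> int:
        return self.p + self.n

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.parameters)

    @property
    def delay_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.delays)

    @property
    def delay_durations(self) -> tuple[float, ...]:
        return tuple(d.delay for d in self.delays)

    @property
    def delay_state_indices(self) -> tuple[int, ...]:
        return tuple(self.states.index(d.state_name) for d in self.delays)

    @property
    def column_labels(self) -> tuple[str, ...]:
        """Sensitivity column labels: parameters, then initial conditions."""
        return self.param_names + tuple(f"{s}(0)" for s in self.states)

    # -- validation ---------------------------------------------------------
    def _validate(self):
        names = list(self.states) + list(self.parameters)
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate symbol names: {sorted(dupes)}")
        bad = set(names) & _RESERVED
        if bad:
            raise ValueError(f"reserved names used as symbols: {sorted(bad)}")
        for d in self.delays:
            if d.delay <= 0:
                raise ValueError(f"delay '{d.label}' must be positive")
            if d.state_name not in self.states:
                raise ValueError(
                    f"delay term references undeclared state '{d.state_name}'")
        allowed = (set(self.states) | set(self.parameters)
                   | set(self.delay_names) | {"t"})
        for state, eq in zip(self.states, self.equations):
            extra = eq.free_symbols - allowed
            if extra:
                raise ValueError(
                    f"equation for {state} uses undeclared symbol "
                    f"'{sorted(extra)[0]}'")

    # -- evaluation helpers -------------------------------------------------
    def rhs_env(self, env: Mapping[str, float]) -> np.ndarray:
        """f(x, y, t; theta) from a flat environment (one model evaluation)."""
        return np.array([eval_env(eq, env) for eq in self.equations])

    def make_env(self, t: float, x: np.ndarray, y: np.ndarray) -> dict:
        env = dict(self._param_env)
        for name, val in zip(self.states, x):
            env[name] = val
        for name, val in zip(self.delay_names, y):
            env[name] = val
        env["t"] = t
        return env

    # -- functional updates -------------------------------------------------
    def with_parameters(self, **updates: float) -> "DDEModel":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        return DDEModel(self.states, params, self.delays, self.equations,
                        self.x0, self.t0, self.phi0)

    def with_initial_conditions(self, x0: Iterable[float]) -> "DDEModel":
        return DDEModel(self.states, self.parameters, self.delays,
                        self.equations, x0, self.t0, self.phi0)

    def __eq__(self, other):
        if not isinstance(other, DDEModel):
            return NotImplemented
        return (self.states == other.states
                and self.parameters == other.parameters
                and self.delays == other.delays
                and self.t0 == other.t0
                and np.array_equal(self.x0, other.x0)
                and np.array_equal(self.phi0, other.phi0)
                and all(a.root == b.root
                        for a, b in zip(self.equations, other.equations)))

    def __repr__(self):
        return (f"DDEModel(n={self.n}, p={self.p}, m={self.m}, "
                f"t0={self.t0})")


def initial_history(model: DDEModel, t: float) -> np.ndarray:
    """Constant initial history: x(t) = x(t0) for every t <= t0."""
    if t > model.t0:
        raise ValueError(f"initial history queried at t={t} > t0={model.t0}")
    return model.x0.copy()


# ---------------------------------------------------------------------------
# model file parsing
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\[(\w+)\]$")
_ASSIGN_RE = re.compile(r"^(\w+)\s*=\s*(.+)$")
_EQUATION_RE = re.compile(r"^d\s*(\w+)\s*/\s*dt\s*=\s*(.+)$")
_DELAY_REF_RE = re.compile(r"\b(\w+)@(\w+)")

_KNOWN_SECTIONS = ("states", "parameters", "delays", "equations", "options")


def _parse_sections(text: str):
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, raw in enumerate(text.replace("\r\n", "\n").split("\n"), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        msec = _SECTION_RE.match(line)
        if msec:
            current = msec.group(1)
            if current not in _KNOWN_SECTIONS:
                raise ModelParseError(f"unknown section '{current}'", lineno)
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ModelParseError("content before any [section] header", lineno)
        sections[current].append((lineno, line))
    return sections


def load_model(text: str,
               ) -> tuple[DDEModel, SamplingGrid | None, SolverConfig]:
    """Parse a full model file into (model, sampling grid, solver config)."""
    sections = _parse_sections(text)
    for required in ("states", "equations"):
        if required not in sections:
            raise ModelParseError(f"missing [{required}] section")

    states: list[str] = []
    x0: list[float] = []
    for lineno, line in sections.get("states", []):
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ModelParseError("expected 'name = initial_value'", lineno,
                                  "states")
        name, val = m.group(1), m.group(2)
        try:
            x0.append(float(val))
        except ValueError:
            raise ModelParseError(f"bad initial value '{val}'", lineno, "states")
        states.append(name)

    parameters: dict[str, float] = {}
    for lineno, line in sections.get("parameters", []):
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ModelParseError("expected 'name = value'", lineno,
                                  "parameters")
        try:
            parameters[m.group(1)] = float(m.group(2))
        except ValueError:
            raise ModelParseError(f"bad parameter value '{m.group(2)}'",
                                  lineno, "parameters")

    delay_durations: dict[str, float] = {}
    for lineno, line in sections.get("delays", []):
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ModelParseError("expected 'label = duration'", lineno,
                                  "delays")
        try:
            dur = float(m.group(2))
        except ValueError:
            raise ModelParseError(f"bad delay duration '{m.group(2)}'",
                                  lineno, "delays")
        if dur <= 0:
            raise ModelParseError(f"delay '{m.group(1)}' must be positive",
                                  lineno, "delays")
        delay_durations[m.group(1)] = dur

    # scan equations for delayed references, in order of first appearance
    eq_texts: dict[str, tuple[int, str]] = {}
    delays: list[DelayTerm] = []
    seen_delay_names: set[str] = set()
    for lineno, line in sections.get("equations", []):
        m = _EQUATION_RE.match(line)
        if not m:
            raise ModelParseError("expected 'dNAME/dt = expression'", lineno,
                                  "equations")
        state, expr_text = m.group(1), m.group(2).strip()
        if state not in states:
            raise ModelParseError(f"equation for undeclared state '{state}'",
                                  lineno, "equations")
        if state in eq_texts:
            raise ModelParseError(f"duplicate equation for '{state}'", lineno,
                                  "equations")
        eq_texts[state] = (lineno, expr_text)
        for sname, label in _DELAY_REF_RE.findall(expr_text):
            if label not in delay_durations:
                raise ModelParseError(
                    f"undeclared delay label '{label}' in '{sname}@{label}'",
                    lineno, "equations")
            if sname not in states:
                raise ModelParseError(
                    f"delayed reference to undeclared state '{sname}'",
                    lineno, "equations")
            key = f"{sname}@{label}"
            if key not in seen_delay_names:
                seen_delay_names.add(key)
                delays.append(DelayTerm(label, sname, delay_durations[label]))

    missing_eqs = [s for s in states if s not in eq_texts]
    if missing_eqs:
        raise ModelParseError(f"no equation for state '{missing_eqs[0]}'",
                              section="equations")

    declared = {name: "state" for name in states}
    declared.update({name: "parameter" for name in parameters})
    declared.update({d.name: "delayed_state" for d in delays})
    declared["t"] = "time"

    equations = []
    for state in states:
        lineno, expr_text = eq_texts[state]
        try:
            equations.append(parse_expression(expr_text, declared))
        except Exception as exc:
            raise ModelParseError(f"in equation for {state}: {exc}", lineno,
                                  "equations") from exc

    t0 = 0.0
    grid: SamplingGrid | None = None
    cfg_kwargs: dict[str, float | int] = {}
    sampling_spec = None
    for lineno, line in sections.get("options", []):
        m = _ASSIGN_RE.match(line)
        if not m:
            raise ModelParseError("expected 'key = value'", lineno, "options")
        key, val = m.group(1), m.group(2).strip()
        try:
            if key == "t0":
                t0 = float(val)
            elif key == "sampling":
                sampling_spec = (lineno, val)
            elif key == "epsilon":
                cfg_kwargs["epsilon"] = float(val)
            elif key == "iteration_limit":
                cfg_kwargs["iteration_limit"] = int(val)
            elif key == "convergence_rtol":
                cfg_kwargs["convergence_rtol"] = float(val)
            elif key == "convergence_atol":
                cfg_kwargs["convergence_atol"] = float(val)
            else:
                raise ModelParseError(f"unknown option '{key}'", lineno,
                                      "options")
        except ModelParseError:
            raise
        except ValueError:
            raise ModelParseError(f"bad value for option '{key}': '{val}'",
                                  lineno, "options")

    if sampling_spec is not None:
        lineno, val = sampling_spec
        try:
            grid = SamplingGrid.from_string(val, t0=t0)
            grid.validate_against(t0)
        except ValueError as exc:
            raise ModelParseError(str(exc), lineno, "options") from exc

    try:
        model = DDEModel(states, parameters, delays, equations, x0, t0)
    except ValueError as exc:
        raise ModelParseError(str(exc)) from exc
    return model, grid, SolverConfig(**cfg_kwargs)


def build_model(text: str) -> DDEModel:
    """Parse a model file and return the validated :class:`DDEModel` only."""
    return load_model(text)[0]


def serialize_model(model: DDEModel, grid: SamplingGrid | None = None,
                    cfg: SolverConfig | None = None) -> str:
    """Write a model back to the sectioned text format (round-trips)."""
    out = ["[states]"]
    for name, val in zip(model.states, model.x0):
        out.append(f"{name} = {float(val)!r}")
    out.append("")
    out.append("[parameters]")
    for name, val in model.parameters.items():
        out.append(f"{name} = {float(val)!r}")
    if model.delays:
        out.append("")
        out.append("[delays]")
        seen = set()
        for d in model.delays:
            if d.label not in seen:
                seen.add(d.label)
                out.append(f"{d.label} = {d.delay!r}")
    out.append("")
    out.append("[equations]")
    for name, eq in zip(model.states, model.equations):
        out.append(f"d{name}/dt = {eq.source}")
    out.append("")
    out.append("[options]")
    out.append(f"t0 = {model.t0!r}")
    if grid is not None:
        out.append("sampling = " + ",".join(repr(float(p)) for p in grid.points))
    if cfg is not None:
        out.append(f"epsilon = {cfg.epsilon!r}")
        out.append(f"iteration_limit = {cfg.iteration_limit}")
        out.append(f"convergence_rtol = {cfg.convergence_rtol!r}")
        out.append(f"convergence_atol = {cfg.convergence_atol!r}")
    return "\n".join(out) + "\n"
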