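"""Adaptive trapezoidal DDE integration.

Each sampling interval is covered by one or more internal steps.  A step of
size eta advances the state with the implicit trapezoidal (Crank-Nicolson)
collocation rule

    x(t+eta) = x(t) + eta/2 * [ f(x(t), y(t)) + f(x(t+eta), y(t+eta)) ],

solved by fixed-point iteration from an explicit Euler predictor.  Delayed
values y(t) = x(t - tau) come from an append-only history buffer with linear
interpolation between accepted nodes; times at or before t0 return the
constant initial history.

Step-size control follows the Jacobian-norm bound

    mu = n * (m + n) * max_ij |a_ij|,   A = [df/dx, df/dy],

an upper bound on ||A||_2: the run aborts as *stiff* when mu * epsilon >= 1,
and the step is clipped to 0.9/mu whenever mu * eta > 1 (which keeps the
fixed-point corrector a contraction).  With delays present the step is
additionally capped at the smallest delay, the standard method-of-steps
constraint, so y(t+eta) never requires states beyond the current accepted
time.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .errors import (ConvergenceError, HistoryExtrapolationError,
                     StiffnessError)
from .expressions import _jacobians_env
from .model import DDEModel, SamplingGrid, SolverConfig

__all__ = [
    "HistoryBuffer",
    "Trajectory",
    "interpolate_history",
    "iterate_state",
    "control_step",
    "solve_dde",
]


class HistoryBuffer:
    """Append-only record of accepted (time, state[, sensitivity]) nodes.

    Node times are strictly increasing, the first node sits at t0.  Lookups
    at t <= t0 return the constant past (x0 and, for sensitivities, Phi0);
    lookups exactly at a node return the stored value; anything in between is
    linearly interpolated.  Lookups beyond the newest node raise.
    """

    def __init__(self, t0: float, constant_past: np.ndarray,
                 constant_past_phi: np.ndarray | None = None):
        self.t0 = float(t0)
        self.constant_past = np.asarray(constant_past, dtype=float)
        self.constant_past_phi = (None if constant_past_phi is None
                                  else np.asarray(constant_past_phi, float))
        self.times: list[float] = []
        self.states: list[np.ndarray] = []
        self.phis: list[np.ndarray | None] = []

    def append(self, t: float, state: np.ndarray,
               phi: np.ndarray | None = None) -> None:
        if self.times:
            if t <= self.times[-1]:
                raise ValueError(
                    f"history nodes must have strictly increasing times "
                    f"({t} after {self.times[-1]})")
        elif t != self.t0:
            raise ValueError(f"first history node must sit at t0={self.t0}")
        self.times.append(float(t))
        self.states.append(np.asarray(state, dtype=float))
        self.phis.append(None if phi is None else np.asarray(phi, float))

    def _bracket(self, t: float) -> tuple[int, int, float]:
        times = self.times
        if t > times[-1]:
            raise HistoryExtrapolationError(
                f"history lookup at t={t:.6g} beyond latest node "
                f"t={times[-1]:.6g}", time=times[-1])
        i = bisect_left(times, t)
        if times[i] == t:
            return i, i, 0.0
        a = i - 1
        w = (t - times[a]) / (times[i] - times[a])
        return a, i, w

    def state(self, t: float) -> np.ndarray:
        if t <= self.t0:
            return self.constant_past
        a, b, w = self._bracket(t)
        if a == b:
            return self.states[a]
        return self.states[a] + w * (self.states[b] - self.states[a])

    def phi(self, t: float) -> np.ndarray:
        if t <= self.t0:
            if self.constant_past_phi is None:
                raise ValueError("history carries no sensitivity nodes")
            return self.constant_past_phi
        a, b, w = self._bracket(t)
        pa = self.phis[a]
        if pa is None:
            raise ValueError("history carries no sensitivity nodes")
        if a == b:
            return pa
        return pa + w * (self.phis[b] - pa)

    def __len__(self):
        return len(self.times)


def interpolate_history(history: HistoryBuffer, t: float) -> np.ndarray:
    """Linearly interpolated state at time t (constant past for t <= t0)."""
    return history.state(t)


@dataclass
class Trajectory:
    """Solver output: all accepted node times/states plus bookkeeping.

    ``times`` holds t0, every internal accepted step, and every sampling
    point; ``grid_index`` marks which rows correspond to t0 followed by the
    sampling grid.  ``eval_count`` is the number of full model right-hand-side
    evaluations (value or Jacobian sweeps), the cost diagnostic of the method.
    """

    times: np.ndarray
    states: np.ndarray
    eval_count: int
    grid_index: np.ndarray

    @property
    def grid_times(self) -> np.ndarray:
        return self.times[self.grid_index]

    @property
    def grid_states(self) -> np.ndarray:
        return self.states[self.grid_index]

    def state_series(self, model: DDEModel, name: str) -> np.ndarray:
        return self.grid_states[:, model.states.index(name)]


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def _delayed_values(model: DDEModel, history: HistoryBuffer,
                    t: float) -> np.ndarray:
    idx = model.delay_state_indices
    out = np.empty(len(idx))
    for k, (j, tau) in enumerate(zip(idx, model.delay_durations)):
        out[k] = history.state(t - tau)[j]
    return out


def iterate_state(model: DDEModel, history: HistoryBuffer, t: float,
                  eta: float, cfg: SolverConfig,
                  _stats: dict | None = None) -> np.ndarray:
    """One trapezoidal step from the accepted state at t to t + eta.

    Explicit Euler predictor, then fixed-point corrections of the implicit
    trapezoidal rule until max_i |dx_i| <= atol + rtol*|x_i| or the iteration
    limit; a limit hit raises :class:`ConvergenceError` (the caller aborts).
    Requires eta <= min delay when delays are present so that y(t + eta) is
    covered by already accepted history.
    """
    x_t = history.state(t)
    y_t = _delayed_values(model, history, t)
    f_t = model.rhs_env(model.make_env(t, x_t, y_t))
    nev = 1
    t_next = t + eta
    y_next = _delayed_values(model, history, t_next)
    x = x_t + eta * f_t
    converged = False
    polish = False
    for _ in range(cfg.iteration_limit):
        f_next = model.rhs_env(model.make_env(t_next, x, y_next))
        nev += 1
        x_new = x_t + 0.5 * eta * (f_t + f_next)
        delta = np.abs(x_new - x)
        x = x_new
        if polish:
            converged = True
            break
        if np.all(delta <= cfg.convergence_atol
                  + cfg.convergence_rtol * np.abs(x_new)):
            # one extra sweep after the increment test passes, so the
            # returned iterate sits within O(contraction * tol) of the
            # implicit solution rather than O(tol)
            polish = True
    converged = converged or polish
    if _stats is not None:
        _stats["evals"] = _stats.get("evals", 0) + nev
    if not converged:
        raise ConvergenceError(
            f"trapezoidal corrector did not converge in "
            f"{cfg.iteration_limit} iterations (eta={eta:.6g})", time=t)
    return x


def _mu_bound(model: DDEModel, A: np.ndarray, B: np.ndarray) -> float:
    n, m = model.n, model.m
    amax = 0.0
    if A.size:
        amax = float(np.max(np.abs(A)))
    if B.size:
        amax = max(amax, float(np.max(np.abs(B))))
    return n * (m + n) * amax


def _control(model: DDEModel, mu: float, eta: float, cfg: SolverConfig,
             t: float | None = None) -> float:
    if mu * cfg.epsilon >= 1.0:
        raise StiffnessError(mu, cfg.epsilon, time=t)
    if model.m > 0:
        eta = min(eta, min(model.delay_durations))
    if mu * eta > 1.0:
        eta = 0.9 / mu
    return eta


def control_step(model: DDEModel, x_p: np.ndarray, y_p: np.ndarray,
                 eta: float, cfg: SolverConfig, t: float | None = None,
                 ) -> float:
    """Adapt the step size from the Jacobian-norm bound mu at (x_p, y_p).

    mu = n*(m+n)*max|a_ij| over A = [df/dx, df/dy].  Raises
    :class:`StiffnessError` when mu*epsilon >= 1; returns 0.9/mu when
    mu*eta > 1 and eta unchanged otherwise (capped at the smallest delay when
    delays are present).
    """
    env = model.make_env(model.t0 if t is None else t, np.asarray(x_p, float),
                         np.asarray(y_p, float))
    A, B, _ = _jacobians_env(model, env)
    return _control(model, _mu_bound(model, A, B), eta, cfg, t=t)


# ---------------------------------------------------------------------------
# driver loop
# ---------------------------------------------------------------------------

def _solve(model: DDEModel, grid: SamplingGrid, cfg: SolverConfig,
           with_sensitivities: bool):
    from . import sensitivity as _sens  # deferred: sensitivity imports us

    grid.validate_against(model.t0)
    phi0 = model.phi0 if with_sensitivities else None
    history = HistoryBuffer(model.t0, model.x0, phi0)
    history.append(model.t0, model.x0, phi0)

    times = [model.t0]
    states = [model.x0.copy()]
    grid_index = [0]
    phis = [phi0.copy()] if with_sensitivities else None
    stats = {"evals": 0}
    rel_eps = 1e-12

    t_prev = model.t0
    try:
        for t_i in grid.points:
            width = t_i - t_prev
            t_cur = t_prev
            eta = width
            while True:
                x_p = history.state(t_cur)
                y_p = _delayed_values(model, history, t_cur)
                env = model.make_env(t_cur, x_p, y_p)
                A, B, C = _jacobians_env(model, env)
                stats["evals"] += 1
                eta = _control(model, _mu_bound(model, A, B), eta, cfg,
                               t=t_cur)
                remaining = t_i - t_cur
                last = eta >= remaining * (1.0 - rel_eps)
                if last:
                    eta = remaining
                    t_next = t_i
                else:
                    t_next = t_cur + eta
                x_next = iterate_state(model, history, t_cur, eta, cfg,
                                       _stats=stats)
                phi_next = None
                if with_sensitivities:
                    phi_next = _sens.iterate_sensitivity(
                        model, history, t_cur, eta, x_p, x_next,
                        history.phi(t_cur), cfg,
                        _jac_left=(A, B, C), _stats=stats)
                history.append(t_next, x_next, phi_next)
                times.append(t_next)
                states.append(x_next)
                if last:
                    break
                t_cur = t_next
                eta = t_i - t_cur
            grid_index.append(len(times) - 1)
            if with_sensitivities:
                phis.append(history.phis[-1].copy())
            t_prev = t_i
    except (StiffnessError, ConvergenceError, HistoryExtrapolationError) as exc:
        exc.trajectory = Trajectory(np.array(times), np.array(states),
                                    stats["evals"], np.array(grid_index))
        raise

    traj = Trajectory(np.array(times), np.array(states), stats["evals"],
                      np.array(grid_index))
    if not with_sensitivities:
        return traj
    series = _sens.SensitivitySeries(
        times=traj.grid_times.copy(),
        matrices=np.array(phis),
        column_labels=model.column_labels,
        state_names=model.states,
    )
    return traj, series


def solve_dde(model: DDEModel, grid: SamplingGrid,
              cfg: SolverConfig | None = None) -> Trajectory:
    """Integrate the model over the sampling grid (states only).

    Every sampling point is hit exactly (the last internal step of an
    interval is the remaining width).  A model without delays is handled
    identically with no history lookups — the plain ODE special case.
    """
    return _solve(model, grid, cfg or SolverConfig(), with_sensitivities=False)
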