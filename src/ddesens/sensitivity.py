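"""Direct-decoupled forward sensitivity propagation for DDE models.

The absolute sensitivities s(x_i, theta_j) = dx_i/dtheta_j satisfy the linear
(delayed) variational system obtained by differentiating the model through
its parameters,

    dPhi/dt = A(t) Phi(t) + sum_k B_k(t) Phi(t - tau_k)|rows + C(t),

where A = df/dx, B = df/dy (delayed states) and C = df/dtheta are evaluated
along the solution by forward-mode automatic differentiation.  The q = p + n
columns of Phi cover the p parameters (zero initial block) and the n initial
conditions (identity initial block) — sensitivities with respect to initial
values need no extra equations because f has no explicit x0 dependence, so
their columns of C are zero.

The scheme is *direct-decoupled*: within every accepted step the nonlinear
state system is solved first, then the linear sensitivity system is advanced
with the same trapezoidal rule and the same step size.  Step-size control
never looks at Phi, so switching sensitivities off does not perturb the state
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConvergenceError
from .expressions import _jacobians_env
from .integrator import HistoryBuffer, Trajectory, _solve
from .model import DDEModel, SamplingGrid, SolverConfig

__all__ = [
    "SensitivityMatrix",
    "SensitivitySeries",
    "init_sensitivities",
    "sensitivity_rhs",
    "iterate_sensitivity",
    "solve_with_sensitivities",
]


@dataclass
class SensitivityMatrix:
    """n x q matrix of absolute sensitivities with its column labels."""

    values: np.ndarray
    column_labels: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_labels):
            raise ValueError("values must be n x q with one label per column")


@dataclass
class SensitivitySeries:
    """Absolute sensitivity matrices saved at t0 and every sampling time."""

    times: np.ndarray
    matrices: np.ndarray  # shape (k, n, q)
    column_labels: tuple[str, ...]
    state_names: tuple[str, ...]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if len(self.times) != len(self.matrices):
            raise ValueError("times and matrices must align")

    def column(self, state: str, label: str) -> np.ndarray:
        """Time series s(state, label) over the saved sampling times."""
        i = self.state_names.index(state)
        j = self.column_labels.index(label)
        return self.matrices[:, i, j]

    def __len__(self):
        return len(self.times)


def init_sensitivities(model: DDEModel) -> SensitivityMatrix:
    """Phi(t0): zero parameter columns, identity initial-condition block
    (or whatever the model's phi0 override holds)."""
    return SensitivityMatrix(model.phi0.copy(), model.column_labels)


def sensitivity_rhs(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                    phi: np.ndarray,
                    phi_delayed: Sequence[np.ndarray],
                    delay_rows: Sequence[int]) -> np.ndarray:
    """dPhi/dt = A Phi + sum_k outer(B[:,k], Phi_delayed_k[row_k]) + C.

    ``phi_delayed[k]`` is the full n x q sensitivity matrix interpolated at
    t - tau_k, from which the row of the delayed state (``delay_rows[k]``) is
    selected.  ``C`` must already be n x q (parameter columns from AD,
    initial-condition columns zero).
    """
    if C.shape != phi.shape:
        raise ValueError(f"C must match phi shape {phi.shape}, got {C.shape}")
    out = A @ phi + C
    for k, row in enumerate(delay_rows):
        out += np.outer(B[:, k], phi_delayed[k][row])
    return out


def _extend_C(model: DDEModel, C_params: np.ndarray) -> np.ndarray:
    C = np.zeros((model.n, model.q))
    C[:, :model.p] = C_params
    return C


def _delayed_phis(model: DDEModel, history: HistoryBuffer,
                  t: float) -> list[np.ndarray]:
    return [history.phi(t - tau) for tau in model.delay_durations]


def iterate_sensitivity(model: DDEModel, history: HistoryBuffer, t: float,
                        eta: float, x_t: np.ndarray, x_next: np.ndarray,
                        phi_t: np.ndarray | SensitivityMatrix,
                        cfg: SolverConfig,
                        _jac_left=None, _stats: dict | None = None,
                        ) -> np.ndarray:
    """Advance Phi from t to t + eta with the state step already accepted.

    Euler predictor Phi + eta*Phidot(t), then trapezoidal fixed-point
    corrections with the right-endpoint Jacobians evaluated once at
    (x_next, y_next).  Delayed sensitivities Phi(t - tau) are linearly
    interpolated from stored nodes; lookups at or before t0 return Phi0.
    """
    from .integrator import _delayed_values  # local import to avoid cycle

    if isinstance(phi_t, SensitivityMatrix):
        phi_t = phi_t.values
    rows = model.delay_state_indices

    if _jac_left is None:
        y_t = _delayed_values(model, history, t)
        A0, B0, C0 = _jacobians_env(model, model.make_env(t, x_t, y_t))
        if _stats is not None:
            _stats["evals"] = _stats.get("evals", 0) + 1
    else:
        A0, B0, C0 = _jac_left
    C0 = _extend_C(model, C0)
    phid_t = _delayed_phis(model, history, t)
    phidot_t = sensitivity_rhs(A0, B0, C0, phi_t, phid_t, rows)

    t_next = t + eta
    y_next = _delayed_values(model, history, t_next)
    A1, B1, C1 = _jacobians_env(model, model.make_env(t_next, x_next, y_next))
    if _stats is not None:
        _stats["evals"] = _stats.get("evals", 0) + 1
    C1 = _extend_C(model, C1)
    phid_next = _delayed_phis(model, history, t_next)

    phi = phi_t + eta * phidot_t  # predictor
    polish = False
    for _ in range(cfg.iteration_limit):
        phidot_next = sensitivity_rhs(A1, B1, C1, phi, phid_next, rows)
        phi_new = phi_t + 0.5 * eta * (phidot_t + phidot_next)
        delta = np.abs(phi_new - phi)
        phi = phi_new
        if polish:
            return phi
        if np.all(delta <= cfg.convergence_atol
                  + cfg.convergence_rtol * np.abs(phi_new)):
            # same polishing sweep as the state corrector, keeping the two
            # iterations in lockstep on linear problems
            polish = True
    if polish:
        return phi
    raise ConvergenceError(
        f"sensitivity corrector did not converge in {cfg.iteration_limit} "
        f"iterations (eta={eta:.6g})", time=t)


def solve_with_sensitivities(model: DDEModel, grid: SamplingGrid,
                             cfg: SolverConfig | None = None,
                             ) -> tuple[Trajectory, SensitivitySeries]:
    """Integrate states and the n x q sensitivity matrix over the grid.

    Per accepted step the state is solved first, then the sensitivities with
    the same step size (direct-decoupled); Phi is saved at t0 and at every
    sampling time.  A model with q = 0 columns degenerates to a plain state
    solve with an empty series.
    """
    return _solve(model, grid, cfg or SolverConfig(), with_sensitivities=True)
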