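"""Sensitivity post-processing: relative/semi-relative forms, time averages,
ranking tables, and export helpers.

Absolute sensitivities s = dx_i/dtheta_j mix units.  For cross-parameter
comparison they are rescaled to the dimensionless *relative* (log-log) form
S = (theta_j / x_i) s, or — when a state passes near zero and the division
becomes unstable — to the *semi-relative* form S~ = theta_j s.  A single
parameter's importance over a whole run is summarised by the time-averaged
magnitude

    S_bar = (1 / (t_f - t_start)) * integral |S(t)| dt,

evaluated by the trapezoid rule on the sampling grid, and ranking tables
report these averages together with each column's percentage of the total
over all q columns.  Initial-condition columns use the initial value as the
scaling "parameter".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .integrator import Trajectory
from .model import DDEModel
from .sensitivity import SensitivitySeries

__all__ = [
    "RankingTable",
    "InstabilityWarning",
    "relative_sensitivity",
    "semi_relative_sensitivity",
    "time_averaged",
    "scaling_factors",
    "converted_series",
    "rank_table",
    "stacked_fractions",
    "series_to_dataframe",
    "ranking_to_dataframe",
    "write_stacked_fractions_json",
]


class InstabilityWarning(UserWarning):
    """Relative sensitivities requested where a state is (near) zero."""


@dataclass
class RankingTable:
    """Time-averaged sensitivity magnitudes of one state, largest first.

    ``rows`` are (column label, time-averaged value, percentage); the
    percentages are taken over *all* q columns, so a printed subset of rows
    does not sum to 100.  Ties keep the original column order.
    """

    target_state: str
    mode: str  # "relative" | "semi-relative" | "absolute"
    rows: list[tuple[str, float, float]]

    def top(self, k: int) -> list[tuple[str, float, float]]:
        return self.rows[:k]

    def value(self, label: str) -> float:
        for name, val, _ in self.rows:
            if name == label:
                return val
        raise KeyError(label)

    def rank_of(self, label: str) -> int:
        """1-based rank of a column label."""
        for i, (name, _, _) in enumerate(self.rows):
            if name == label:
                return i + 1
        raise KeyError(label)


def relative_sensitivity(s: float, x: float, theta: float,
                         floor: float = 1e-300) -> float:
    """(theta / x) * s — the dimensionless log-log sensitivity."""
    if abs(x) <= floor:
        raise ZeroDivisionError(
            "relative sensitivity undefined where the state is zero")
    return theta / x * s


def semi_relative_sensitivity(s: float, theta: float) -> float:
    """theta * s — bounded even where the state vanishes."""
    return theta * s


def time_averaged(times: Sequence[float], values: Sequence[float],
                  t_f: float | None = None,
                  t_start: float | None = None) -> float:
    """Trapezoidal time average of |S| over [t_start, t_f].

    Defaults to the full span of ``times``; sign flips of the series do not
    change the result.
    """
    t = np.asarray(times, dtype=float)
    v = np.abs(np.asarray(values, dtype=float))
    if t.size == 0:
        raise ValueError("empty series")
    if t_start is not None or t_f is not None:
        lo = t[0] if t_start is None else t_start
        hi = t[-1] if t_f is None else t_f
        mask = (t >= lo) & (t <= hi)
        t, v = t[mask], v[mask]
        if t.size < 2:
            raise ValueError("window contains fewer than two samples")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("degenerate time window")
    return float(np.trapezoid(v, t) / span)


def scaling_factors(model: DDEModel) -> np.ndarray:
    """theta_j per sensitivity column: nominal parameter values, then x0."""
    return np.concatenate([
        np.array([model.parameters[name] for name in model.param_names]),
        model.x0,
    ])


def converted_series(series: SensitivitySeries, trajectory: Trajectory,
                     model: DDEModel, mode: str = "relative",
                     allow_unstable: bool = False) -> np.ndarray:
    """Series matrices converted to the requested mode, shape (k, n, q).

    ``relative`` divides by the state trajectory at the matching sampling
    times and flags instability when any |x_i| drops below
    1e-12 * max_t |x_i| (the caller may switch to semi-relative instead).
    """
    S = series.matrices.copy()
    theta = scaling_factors(model)
    if mode == "absolute":
        return S
    S = S * theta[None, None, :]
    if mode in ("semi-relative", "semi"):
        return S
    if mode != "relative":
        raise ValueError(f"unknown mode '{mode}'")
    x = trajectory.grid_states  # (k, n), aligned with series.times
    if x.shape[0] != S.shape[0]:
        raise ValueError("trajectory grid and sensitivity series misaligned")
    floor = 1e-12 * np.max(np.abs(x), axis=0)
    unstable = np.abs(x) <= floor[None, :]
    if unstable.any():
        msg = ("relative sensitivities unstable: state(s) "
               f"{[series.state_names[i] for i in np.unique(np.where(unstable)[1])]} "
               "pass near zero; consider semi-relative mode")
        if not allow_unstable:
            raise ZeroDivisionError(msg)
        warnings.warn(msg, InstabilityWarning, stacklevel=2)
        x = np.where(unstable, np.nan, x)
    return S / x[:, :, None]


def rank_table(series: SensitivitySeries, trajectory: Trajectory,
               model: DDEModel, target_state: str, mode: str = "relative",
               t_f: float | None = None, t_start: float | None = None,
               allow_unstable: bool = False) -> RankingTable:
    """Ranking of all q sensitivity columns of one state by time-averaged
    magnitude, with percentages of the full-column total."""
    if target_state not in series.state_names:
        raise ValueError(f"unknown state '{target_state}'")
    S = converted_series(series, trajectory, model, mode,
                         allow_unstable=allow_unstable)
    i = series.state_names.index(target_state)
    averages = np.array([
        time_averaged(series.times, S[:, i, j], t_f=t_f, t_start=t_start)
        for j in range(S.shape[2])
    ])
    total = averages.sum()
    pct = 100.0 * averages / total if total > 0 else np.zeros_like(averages)
    order = sorted(range(len(averages)), key=lambda j: -averages[j])
    rows = [(series.column_labels[j], float(averages[j]), float(pct[j]))
            for j in order]
    return RankingTable(target_state=target_state, mode=mode, rows=rows)


def stacked_fractions(tables: Sequence[RankingTable]) -> pd.DataFrame:
    """Per-state columns of sensitivity fractions, each summing to 1.

    One table per state variable; the result is the data behind a
    100%-stacked column chart (rows: sensitivity columns, cols: states).
    """
    data = {}
    for tab in tables:
        values = {name: val for name, val, _ in tab.rows}
        total = sum(values.values())
        data[tab.target_state] = {
            name: (val / total if total > 0 else 0.0)
            for name, val in values.items()
        }
    return pd.DataFrame(data)


def series_to_dataframe(series: SensitivitySeries, trajectory: Trajectory,
                        model: DDEModel,
                        allow_unstable: bool = False) -> pd.DataFrame:
    """Long-format frame: time, state, parameter, absolute, relative,
    semi_relative (relative is NaN where flagged unstable)."""
    S_abs = series.matrices
    S_semi = converted_series(series, trajectory, model, "semi-relative")
    try:
        S_rel = converted_series(series, trajectory, model, "relative",
                                 allow_unstable=allow_unstable)
    except ZeroDivisionError:
        S_rel = np.full_like(S_abs, np.nan)
    k, n, q = S_abs.shape
    times = np.repeat(series.times, n * q)
    state = np.tile(np.repeat(series.state_names, q), k)
    param = np.tile(series.column_labels, k * n)
    return pd.DataFrame({
        "time": times,
        "state": state,
        "parameter": param,
        "absolute": S_abs.reshape(-1),
        "relative": S_rel.reshape(-1),
        "semi_relative": S_semi.reshape(-1),
    })


def ranking_to_dataframe(table: RankingTable) -> pd.DataFrame:
    return pd.DataFrame(
        [(table.target_state, table.mode, name, val, pct)
         for name, val, pct in table.rows],
        columns=["state", "mode", "parameter", "time_averaged", "percentage"],
    )


def write_stacked_fractions_json(frame: pd.DataFrame, path) -> None:
    payload = {state: {name: float(v) for name, v in frame[state].items()}
               for state in frame.columns}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
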