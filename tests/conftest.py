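import numpy as np
import pytest

import ddesens as d


@pytest.fixture(scope="session")
def decay():
    """dx/dt = -x, x(0)=1: analytic solution exp(-t)."""
    return d.exponential_decay_fixture(theta=1.0, x0=1.0)


@pytest.fixture(scope="session")
def linear_dde():
    """dx/dt = -x(t-1), constant history 1: piecewise-polynomial solution."""
    return d.linear_dde_fixture(theta=1.0, tau=1.0, c=1.0)


@pytest.fixture(scope="session")
def cardio():
    """The baroreflex heart-rate / blood-pressure model at nominal values."""
    return d.cardiovascular_model()


@pytest.fixture(scope="session")
def cardio_run30(cardio):
    """State + sensitivity solve of the baroreflex model over t in [0, 30]."""
    grid = d.SamplingGrid.from_string("0:30:0.05")
    traj, series = d.solve_with_sensitivities(cardio.model, grid,
                                              cardio.config)
    return grid, traj, series


def relative_series(model, traj, series, state, label):
    """(theta/x)*s over the saved sampling times."""
    i = model.states.index(state)
    theta = (model.parameters[label] if label in model.parameters
             else model.x0[list(model.column_labels).index(label) - model.p])
    return theta * series.column(state, label) / traj.grid_states[:, i]
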