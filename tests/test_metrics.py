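"""Relative/semi-relative conversion, time averages, and ranking tables."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddesens as d
from ddesens import metrics
from ddesens.integrator import Trajectory
from ddesens.sensitivity import SensitivitySeries


def toy_series(values, labels=("p1", "x(0)")):
    """Wrap a (k, n, q) array into a series over t = 0..k-1."""
    values = np.asarray(values, float)
    k = values.shape[0]
    return SensitivitySeries(times=np.arange(k, dtype=float),
                             matrices=values, column_labels=tuple(labels),
                             state_names=("x",))


class TestScalars:
    def test_relative_direct_substitution(self):
        assert d.relative_sensitivity(2.0, 4.0, 3.0) == pytest.approx(1.5)
        assert d.relative_sensitivity(0.0, 4.0, 3.0) == 0.0

    def test_relative_zero_state_rejected(self):
        with pytest.raises(ZeroDivisionError):
            d.relative_sensitivity(1.0, 0.0, 3.0)

    @pytest.mark.parametrize("s, theta, expected", [
        (2.0, 3.0, 6.0), (5.0, 0.0, 0.0), (-0.02, 100.0, -2.0),
    ])
    def test_semi_relative(self, s, theta, expected):
        assert d.semi_relative_sensitivity(s, theta) == expected


class TestTimeAveraged:
    def test_linear_ramp(self):
        t = np.arange(0, 1.0001, 0.01)
        assert d.time_averaged(t, t) == pytest.approx(0.5, abs=1e-4)

    def test_zero_series(self):
        t = np.linspace(0, 5, 50)
        assert d.time_averaged(t, np.zeros_like(t)) == 0.0

    def test_square_wave_magnitude(self):
        t = np.linspace(0, 2 * np.pi, 20001)
        v = 3.0 * np.sign(np.sin(t))
        assert d.time_averaged(t, v) == pytest.approx(3.0, abs=1e-3)

    def test_sign_flip_invariance(self):
        t = np.linspace(0, 1, 101)
        v = np.sin(7 * t)
        assert d.time_averaged(t, v) == d.time_averaged(t, -v)

    def test_window(self):
        t = np.arange(0, 2.0001, 0.01)
        out = d.time_averaged(t, t, t_start=1.0, t_f=2.0)
        assert out == pytest.approx(1.5, abs=1e-4)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            d.time_averaged([], [])


class TestRankTable:
    @pytest.fixture()
    def small_run(self, decay):
        grid = d.SamplingGrid.from_string("0:1:0.05")
        traj, series = d.solve_with_sensitivities(decay.model, grid)
        return decay.model, traj, series

    def test_single_column_dominates_with_full_percentage(self):
        # one nonzero column among q=2: percentages split accordingly
        vals = np.zeros((5, 1, 2))
        vals[:, 0, 0] = 2.0
        series = toy_series(vals)
        traj = Trajectory(times=np.arange(5.0), states=np.ones((5, 1)),
                          eval_count=0, grid_index=np.arange(5))
        m = d.build_model("[states]\nx = 1.0\n[parameters]\np1 = 1.0\n"
                          "[equations]\ndx/dt = -p1*x\n")
        tab = d.rank_table(series, traj, m, "x", mode="semi-relative")
        assert tab.rows[0] == ("p1", pytest.approx(2.0), pytest.approx(100.0))
        assert tab.rows[1][1] == 0.0

    def test_percentages_sum_to_100(self, small_run):
        m, traj, series = small_run
        tab = d.rank_table(series, traj, m, "x", mode="relative")
        assert sum(pct for _, _, pct in tab.rows) == pytest.approx(100.0,
                                                                   abs=1e-9)

    def test_rows_sorted_descending_with_stable_ties(self):
        vals = np.zeros((4, 1, 3))
        vals[:, 0, 0] = 1.0
        vals[:, 0, 1] = 2.0
        vals[:, 0, 2] = 1.0  # tied with column 0 -> keeps column order
        series = toy_series(vals, labels=("a", "b", "x(0)"))
        traj = Trajectory(times=np.arange(4.0), states=np.ones((4, 1)),
                          eval_count=0, grid_index=np.arange(4))
        m = d.build_model("[states]\nx = 1.0\n[parameters]\na = 1.0\n"
                          "b = 1.0\n[equations]\ndx/dt = -a*b*x\n")
        tab = d.rank_table(series, traj, m, "x", mode="semi-relative")
        assert [r[0] for r in tab.rows] == ["b", "a", "x(0)"]

    def test_unknown_state_rejected(self, small_run):
        m, traj, series = small_run
        with pytest.raises(ValueError):
            d.rank_table(series, traj, m, "y")

    def test_instability_flag_on_zero_crossing_state(self):
        # a state that crosses zero makes relative mode unusable
        m = d.build_model("[states]\nx = 1.0\n[parameters]\nw = 3.0\n"
                          "[equations]\ndx/dt = -w*x\n")
        grid = d.SamplingGrid.from_string("0:1:0.1")
        traj, series = d.solve_with_sensitivities(m, grid)
        traj.states[-1] = 0.0  # force an exact zero at a sampling point
        with pytest.raises(ZeroDivisionError):
            metrics.converted_series(series, traj, m, "relative")
        with pytest.warns(metrics.InstabilityWarning):
            metrics.converted_series(series, traj, m, "relative",
                                     allow_unstable=True)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_relative_mode_scale_covariance(self, c):
        """Scaling theta by c and its absolute column by 1/c leaves the
        relative ranking values unchanged."""
        vals = np.ones((4, 1, 2))
        series1 = toy_series(vals)
        vals2 = vals.copy()
        vals2[:, 0, 0] /= c
        series2 = toy_series(vals2)
        traj = Trajectory(times=np.arange(4.0),
                          states=np.full((4, 1), 2.0), eval_count=0,
                          grid_index=np.arange(4))
        m1 = d.build_model("[states]\nx = 1.0\n[parameters]\np1 = 1.0\n"
                           "[equations]\ndx/dt = -p1*x\n")
        m2 = m1.with_parameters(p1=c)
        t1 = d.rank_table(series1, traj, m1, "x", mode="relative")
        t2 = d.rank_table(series2, traj, m2, "x", mode="relative")
        assert t1.value("p1") == pytest.approx(t2.value("p1"), rel=1e-12)


class TestStackedFractions:
    def test_columns_sum_to_one(self, decay):
        grid = d.SamplingGrid.from_string("0:1:0.05")
        traj, series = d.solve_with_sensitivities(decay.model, grid)
        tabs = [d.rank_table(series, traj, decay.model, "x",
                             mode="relative")]
        frame = d.stacked_fractions(tabs)
        assert frame["x"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_nonzero_column_gets_fraction_one(self):
        tab = metrics.RankingTable("x", "semi-relative",
                                   rows=[("a", 3.0, 100.0), ("b", 0.0, 0.0)])
        frame = d.stacked_fractions([tab])
        assert frame.loc["a", "x"] == 1.0
        assert frame.loc["b", "x"] == 0.0

    def test_json_round_trip(self, tmp_path):
        tab = metrics.RankingTable("x", "relative",
                                   rows=[("a", 1.0, 50.0), ("b", 1.0, 50.0)])
        path = tmp_path / "frac.json"
        metrics.write_stacked_fractions_json(d.stacked_fractions([tab]), path)
        payload = json.loads(path.read_text())
        assert payload == {"x": {"a": 0.5, "b": 0.5}}


class TestLongFormat:
    def test_dataframe_shape_and_columns(self, decay):
        grid = d.SamplingGrid.from_string("0:1:0.25")
        traj, series = d.solve_with_sensitivities(decay.model, grid)
        frame = metrics.series_to_dataframe(series, traj, decay.model)
        assert list(frame.columns) == ["time", "state", "parameter",
                                       "absolute", "relative",
                                       "semi_relative"]
        assert len(frame) == len(series) * decay.model.n * decay.model.q
        one = frame[(frame.time == 1.0) & (frame.parameter == "x(0)")]
        assert one.relative.iloc[0] == pytest.approx(1.0, abs=1e-10)
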