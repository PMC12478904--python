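import numpy as np
import pytest

from conftest import DEFAULT_PARAM_DICT, random_parameter_dicts
from oracles import euler_reference
from worriedwell.model_core import CompartmentState, ModelParameters
from worriedwell.simulation import (
    DegenerateTrajectoryError,
    Trajectory,
    ratio_curve,
    simulate,
    summarize,
)


def make_trajectory(times, ip, iw, params=None):
    """Hand-built trajectory; S absorbs whatever the seeds leave over."""
    times = np.asarray(times, dtype=float)
    ip = np.asarray(ip, dtype=float)
    iw = np.asarray(iw, dtype=float)
    values = np.column_stack([1.0 - ip - iw, ip, iw, np.zeros_like(ip)])
    return Trajectory(
        times=times,
        values=values,
        params=params,
        initial_state=CompartmentState.from_array(values[0]),
    )


class TestSimulate:
    def test_dfe_initial_state_stays_constant(self, params):
        traj = simulate(params, CompartmentState(1, 0, 0, 0), 30.0, 0.5)
        np.testing.assert_allclose(
            traj.values, np.broadcast_to(traj.values[0], traj.values.shape), atol=1e-9
        )

    def test_invalid_horizons_rejected(self, params, balanced_state):
        with pytest.raises(ValueError, match="horizon"):
            simulate(params, balanced_state, -1.0)
        with pytest.raises(ValueError, match="output_step"):
            simulate(params, balanced_state, 1.0, output_step_days=2.0)

    def test_grid_starts_at_zero_ends_at_horizon(self, default_trajectory):
        assert default_trajectory.times[0] == 0.0
        assert default_trajectory.times[-1] == pytest.approx(350.0)
        assert np.all(np.diff(default_trajectory.times) > 0)

    def test_conservation_along_trajectory(self, default_trajectory):
        totals = default_trajectory.values.sum(axis=1)
        assert np.abs(totals - 1.0).max() <= 1e-6
        assert default_trajectory.values.min() >= 0.0

    def test_agrees_with_fixed_step_euler_over_one_day(self, balanced_state):
        rng = np.random.default_rng(23)
        for kw in random_parameter_dicts(rng, 3) + [dict(DEFAULT_PARAM_DICT)]:
            traj = simulate(ModelParameters(**kw), balanced_state, 1.0, 0.5)
            oracle = euler_reference(balanced_state.as_array(), 1.0, 1e-4, **kw)
            np.testing.assert_allclose(traj.values[-1], oracle, atol=1e-5)

    def test_early_worry_dominance_in_default_run(self, default_trajectory):
        """I_W(t) > I_P(t) throughout the first few days of the outbreak."""
        early = (default_trajectory.times > 0) & (default_trajectory.times <= 4.0)
        assert np.all(default_trajectory.I_W[early] > default_trajectory.I_P[early])

    def test_grid_refinement_stability(self, params, balanced_state):
        coarse = summarize(simulate(params, balanced_state, 350.0, 0.1))
        fine = summarize(simulate(params, balanced_state, 350.0, 0.05))
        assert abs(coarse.peak_IP_time - fine.peak_IP_time) < 0.1
        assert abs(coarse.peak_IW_time - fine.peak_IW_time) < 0.1
        assert abs(coarse.peak_IP_value - fine.peak_IP_value) < 1e-5
        assert abs(coarse.peak_IW_value - fine.peak_IW_value) < 1e-5

    def test_tolerance_robustness(self, params, balanced_state):
        loose = summarize(simulate(params, balanced_state, 350.0))
        tight = summarize(
            simulate(params, balanced_state, 350.0, rtol=1e-9, atol=1e-11)
        )
        for key, a in loose.to_dict().items():
            b = tight.to_dict()[key]
            if isinstance(a, float):
                assert a == pytest.approx(b, rel=1e-6), key


class TestSummarize:
    def test_triangle_peak_located_on_grid(self):
        times = np.arange(11.0)
        ip = np.concatenate([np.linspace(0, 0.5, 6), np.linspace(0.4, 0.0, 5)])
        traj = make_trajectory(times, ip, np.zeros_like(ip))
        summary = summarize(traj)
        assert summary.peak_IP_time == pytest.approx(5.0, abs=0.05)
        assert summary.peak_IP_value == pytest.approx(0.5, abs=1e-3)

    def test_quadratic_refinement_recovers_off_grid_vertex(self):
        # samples of an exact parabola peaking between grid points
        times = np.arange(0.0, 10.0, 1.0)
        ip = 0.5 - 0.004 * (times - 4.6) ** 2
        traj = make_trajectory(times, ip, np.zeros_like(ip))
        summary = summarize(traj)
        assert summary.peak_IP_time == pytest.approx(4.6, abs=1e-9)
        assert summary.peak_IP_value == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_trajectory_rejected(self, params, balanced_state):
        traj = simulate(params, balanced_state, 1.0, 0.5)
        short = Trajectory(
            times=traj.times[:2],
            values=traj.values[:2],
            params=params,
            initial_state=balanced_state,
        )
        with pytest.raises(DegenerateTrajectoryError):
            summarize(short)

    def test_constant_dfe_run_flags_undefined_ratio_and_no_crossing(self, params):
        traj = simulate(params, CompartmentState(1, 0, 0, 0), 10.0, 0.5)
        summary = summarize(traj)
        assert not summary.ratio_defined
        assert summary.peak_ratio_value is None
        assert summary.first_crossing_time is None

    def test_crossing_is_first_upward_sign_change(self):
        # I_P - I_W: negative until t in (3, 4), linear there, zero at 3.5
        times = np.arange(8.0)
        ip = np.array([0.10, 0.10, 0.10, 0.10, 0.20, 0.20, 0.20, 0.20])
        iw = np.array([0.20, 0.20, 0.20, 0.15, 0.15, 0.10, 0.10, 0.10])
        summary = summarize(make_trajectory(times, ip, iw))
        diff = ip - iw
        i = 4  # first index with positive difference
        expected = times[i - 1] + (0 - diff[i - 1]) / (diff[i] - diff[i - 1])
        assert summary.first_crossing_time == pytest.approx(expected)

    def test_tied_interval_resolves_to_left_endpoint(self):
        times = np.arange(6.0)
        ip = np.array([0.10, 0.10, 0.15, 0.15, 0.20, 0.20])
        iw = np.array([0.20, 0.15, 0.15, 0.15, 0.15, 0.10])
        summary = summarize(make_trajectory(times, ip, iw))
        assert summary.first_crossing_time == pytest.approx(2.0)

    def test_default_run_peak_within_horizon_and_above_initial_ratio(
        self, default_trajectory
    ):
        summary = summarize(default_trajectory)
        for t in (
            summary.peak_IP_time,
            summary.peak_IW_time,
            summary.peak_burden_time,
            summary.peak_ratio_time,
            summary.first_crossing_time,
        ):
            assert 0.0 <= t <= 350.0
        ratio0 = default_trajectory.I_W[0] / default_trajectory.I_P[0]
        assert summary.peak_ratio_value >= ratio0


class TestRatioCurve:
    def test_balanced_seed_starts_at_one(self, default_trajectory):
        ratio = ratio_curve(default_trajectory)
        assert ratio[0] == pytest.approx(1.0, rel=1e-12)
        assert np.nanmax(ratio) > 1.0

    def test_initial_quotient_of_seeds(self, params):
        state = CompartmentState.from_seeds(0.01, 0.001)
        traj = simulate(params, state, 5.0, 0.5)
        assert ratio_curve(traj)[0] == pytest.approx(0.1, rel=1e-12)

    def test_floor_marks_missing_not_infinite(self):
        times = np.arange(4.0)
        ip = np.array([0.0, 0.0, 0.1, 0.2])
        iw = np.array([0.1, 0.1, 0.1, 0.1])
        ratio = ratio_curve(make_trajectory(times, ip, iw))
        assert np.isnan(ratio[:2]).all()
        assert np.isfinite(ratio[2:]).all()


class TestCsvRoundTrip:
    def test_full_precision_round_trip(self, default_trajectory, tmp_path):
        path = tmp_path / "traj.csv"
        default_trajectory.to_csv(path)
        back = Trajectory.from_csv(path, params=default_trajectory.params)
        np.testing.assert_allclose(back.times, default_trajectory.times, atol=1e-12)
        np.testing.assert_allclose(
            back.values, default_trajectory.values, rtol=0, atol=1e-12
        )
        header = path.read_text().splitlines()[0]
        assert header == "time_days,S,I_P,I_W,R_P"
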