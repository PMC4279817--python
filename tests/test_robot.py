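"""Velocity-saturated execution of a loaded flexion path."""

import dataclasses

import numpy as np
import pytest

from robogait import (
    DegeneratePathError,
    JointModelParams,
    ParameterError,
    RangeError,
    RobotParams,
    RuntimeFailure,
    build_loaded_path,
    build_trajectory,
    find_optimal_increment,
    generate_passive_path,
    max_achieved_velocity,
    simulate_execution,
)
from robogait.robot import RobotTrace, _segment_schedule

AXIS_X = np.array([1.0, 0.0, 0.0])

QUIET_JOINT = JointModelParams(
    noise_sd_axial=0.0,
    noise_sd_pa=0.0,
    noise_sd_ml=0.0,
    cycle_jitter_sd=0.0,
    seed=0,
)


def ideal_path_for(traj, increment):
    """Noise-free passive path exactly covering a trajectory's angle grid."""
    k = np.rint((traj.angle - traj.angle[0]) / increment).astype(int)
    return generate_passive_path(
        np.zeros(3),
        AXIS_X,
        start_angle=float(traj.angle[0] + k.min() * increment),
        increment=increment,
        span=float((k.max() - k.min()) * increment),
    )


@pytest.fixture(scope="module")
def traj_10(corrected_curve):
    return build_trajectory(corrected_curve, 0.5, 10.0)


@pytest.fixture(scope="module")
def path_05(traj_10):
    return ideal_path_for(traj_10, 0.5)


class TestBuildLoadedPath:
    def test_exact_grid_point_maps_to_index_60(self, traj_10, path_05):
        loaded = build_loaded_path(traj_10, path_05, 300.0)
        i80 = np.argmin(np.abs(traj_10.angle - 80.0))
        expected = round((traj_10.angle[i80] - path_05.start_angle) / 0.5)
        assert loaded.path_index[i80] == expected

    def test_perturbed_angle_maps_to_nearest_index(self, path_05):
        rel = (52.24 - path_05.start_angle) / 0.5
        assert int(np.rint(rel)) == round(rel)
        # direct check of the documented rounding on a near-grid angle
        assert int(np.rint((52.24 - 50.0) / 0.5)) == 4

    def test_monotone_30_deg_ramp_covers_indices_0_to_60(self, ramp_curve):
        traj = build_trajectory(ramp_curve, 0.5, 10.0)
        path = ideal_path_for(traj, 0.5)
        loaded = build_loaded_path(traj, path, 300.0)
        assert set(loaded.path_index) >= set(range(61))

    def test_force_converted_to_newtons(self, traj_10, path_05):
        loaded = build_loaded_path(traj_10, path_05, 350.0)
        np.testing.assert_allclose(loaded.axial_force, traj_10.axial_force * 350.0)

    def test_increment_mismatch_rejected(self, traj_10):
        other = generate_passive_path(np.zeros(3), AXIS_X, 50.0, 0.25, 30.0)
        with pytest.raises(ParameterError, match="increment"):
            build_loaded_path(traj_10, other, 300.0)

    def test_out_of_span_angle_rejected(self, traj_10):
        short = generate_passive_path(np.zeros(3), AXIS_X, 50.0, 0.5, 10.0)
        with pytest.raises(RangeError, match="span"):
            build_loaded_path(traj_10, short, 300.0)


def quick_robot(**kw):
    defaults = dict(n_cycles=1, n_precondition=0)
    defaults.update(kw)
    return RobotParams(**defaults)


class TestSimulateExecution:
    def test_cap_limits_15_and_20_profiles(self, corrected_curve):
        for v_max in (15.0, 20.0):
            traj = build_trajectory(corrected_curve, 0.5, v_max)
            path = ideal_path_for(traj, 0.5)
            loaded = build_loaded_path(traj, path, 300.0)
            trace = simulate_execution(loaded, path, quick_robot(), QUIET_JOINT)
            assert max_achieved_velocity(trace) <= 10.0 * 1.02

    def test_uncapped_period_law(self, corrected_curve, path_05):
        products = []
        for v_max in (5.0, 10.0, 20.0):
            traj = build_trajectory(corrected_curve, 0.5, v_max)
            loaded = build_loaded_path(traj, path_05, 300.0)
            robot = quick_robot(v_cap=np.inf, t_min=0.0)
            trace = simulate_execution(loaded, path_05, robot, QUIET_JOINT)
            products.append(trace.cycle_period * v_max)
        assert np.ptp(products) / products[0] < 1e-3

    def test_latency_bound_formula(self, corrected_curve):
        # increment 0.1 deg with 25 ms per-point latency limits speed to
        # 0.1 / 0.025 = 4 deg/s even for huge commanded velocities
        traj = build_trajectory(corrected_curve, 0.1, 1000.0)
        path = ideal_path_for(traj, 0.1)
        loaded = build_loaded_path(traj, path, 300.0)
        robot = quick_robot(v_cap=np.inf, t_min=0.025)
        trace = simulate_execution(loaded, path, robot, QUIET_JOINT)
        assert max_achieved_velocity(trace) == pytest.approx(4.0, rel=0.02)

    def test_lag_begins_only_in_swing(self, corrected_curve):
        traj = build_trajectory(corrected_curve, 0.5, 20.0)
        path = ideal_path_for(traj, 0.5)
        loaded = build_loaded_path(traj, path, 300.0)
        t_exec, t_cmd, _, node_g, _ = _segment_schedule(
            loaded, path, quick_robot()
        )
        lag = t_exec - t_cmd
        capped = lag > 1e-9
        assert capped.any()
        first = int(np.argmax(capped))
        # executed schedule matches the command exactly until the cap binds
        np.testing.assert_allclose(lag[:first], 0.0, atol=1e-9)
        # the cap first binds after the swing phase begins
        assert node_g[first] % 100.0 > 54.0
        # and the lag never shrinks afterwards
        assert np.all(np.diff(lag[first:]) > -1e-9)

    def test_period_monotonicity(self, corrected_curve, path_05):
        periods_v = []
        for v_max in (5.0, 10.0, 20.0):
            traj = build_trajectory(corrected_curve, 0.5, v_max)
            loaded = build_loaded_path(traj, path_05, 300.0)
            trace = simulate_execution(loaded, path_05, quick_robot(), QUIET_JOINT)
            periods_v.append(trace.cycle_period)
        assert periods_v[0] >= periods_v[1] >= periods_v[2]

        traj = build_trajectory(corrected_curve, 0.5, 10.0)
        loaded = build_loaded_path(traj, path_05, 300.0)
        periods_t = []
        for t_min in (0.0, 0.05, 0.2):
            trace = simulate_execution(
                loaded, path_05, quick_robot(t_min=t_min), QUIET_JOINT
            )
            periods_t.append(trace.cycle_period)
        assert periods_t[0] <= periods_t[1] <= periods_t[2]

    def test_determinism(self, traj_10, path_05):
        loaded = build_loaded_path(traj_10, path_05, 300.0)
        joint = JointModelParams(seed=42)
        a = simulate_execution(loaded, path_05, quick_robot(n_cycles=3), joint)
        b = simulate_execution(loaded, path_05, quick_robot(n_cycles=3), joint)
        np.testing.assert_array_equal(a.f_pa, b.f_pa)
        np.testing.assert_array_equal(a.angle, b.angle)

    def test_angle_stays_within_path_span(self, traj_10, path_05):
        loaded = build_loaded_path(traj_10, path_05, 300.0)
        trace = simulate_execution(loaded, path_05, quick_robot(), QUIET_JOINT)
        assert trace.angle.min() >= path_05.start_angle - 1e-9
        assert trace.angle.max() <= path_05.start_angle + path_05.span + 1e-9

    def test_zero_length_segment_rejected(self, path_05):
        from robogait.robot import LoadedPath

        loaded = LoadedPath(
            path_index=np.array([0, 5, 5, 10]),
            velocity=np.full(4, 5.0),
            axial_force=np.full(4, 300.0),
            gait_pct=np.array([0.0, 25.0, 50.0, 75.0]),
            body_weight=300.0,
        )
        with pytest.raises(DegeneratePathError, match="segment"):
            simulate_execution(loaded, path_05, quick_robot(), QUIET_JOINT)


class TestMaxAchievedVelocity:
    def test_constant_velocity_recovered(self):
        t = np.arange(100) * 0.024
        trace = RobotTrace(
            time=t,
            cycle=np.zeros(100, int),
            gait_pct=np.linspace(0, 99, 100),
            angle=50.0 + 10.0 * t,
            f_axial=np.zeros(100),
            f_pa=np.zeros(100),
            f_ml=np.zeros(100),
            sample_dt=0.024,
            cycle_period=2.4,
        )
        assert max_achieved_velocity(trace) == pytest.approx(10.0, rel=0.02)

    def test_stationary_trace_is_zero(self):
        t = np.arange(10) * 0.024
        trace = RobotTrace(
            time=t,
            cycle=np.zeros(10, int),
            gait_pct=np.linspace(0, 90, 10),
            angle=np.full(10, 55.0),
            f_axial=np.zeros(10),
            f_pa=np.zeros(10),
            f_ml=np.zeros(10),
            sample_dt=0.024,
            cycle_period=0.24,
        )
        assert max_achieved_velocity(trace) == 0.0


class TestFindOptimalIncrement:
    CANDIDATES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0)

    def test_default_latency_selects_half_degree(self, corrected_curve):
        best = find_optimal_increment(
            corrected_curve, self.CANDIDATES, 10.0, RobotParams()
        )
        assert best == 0.5

    def test_single_qualifying_candidate(self, corrected_curve):
        best = find_optimal_increment(corrected_curve, [0.75], 10.0, RobotParams())
        assert best == 0.75

    def test_zero_latency_selects_smallest(self, corrected_curve):
        best = find_optimal_increment(
            corrected_curve, (0.2, 0.5, 1.0), 10.0, RobotParams(t_min=0.0)
        )
        assert best == 0.2

    def test_no_qualifier_reports_best(self, corrected_curve):
        with pytest.raises(RuntimeFailure, match="0.2"):
            find_optimal_increment(
                corrected_curve, (0.1, 0.2), 10.0, RobotParams(t_min=0.05)
            )
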