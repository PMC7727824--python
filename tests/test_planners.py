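"""Planners: S-curve segments, inverse kinematics, the three control
schemes and their motion-limit / coverage / nullification properties."""

import math

import numpy as np
import pytest

import mgsim as mg
from mgsim.planners import _scurve_plan

from conftest import constant_spin_trajectory


def assert_limits_respected(traj: mg.Trajectory, lim: mg.MotionLimits,
                            tol: float = 1e-6):
    """Exhaustive scan of rate, acceleration and sampled jerk."""
    for rate, acc in [(traj.alpha_rate, traj.alpha_acc),
                      (traj.beta_rate, traj.beta_acc)]:
        assert np.abs(rate).max() <= lim.rate_max * (1 + tol)
        assert np.abs(acc).max() <= lim.acc_max * (1 + tol)
        jerk = np.abs(np.diff(acc)) / traj.dt
        assert jerk.max() <= lim.jerk_max * (1 + tol)


def assert_rates_consistent(traj: mg.Trajectory, tol_factor: float = 5.0):
    """Central difference of the angle columns reproduces the stored rates
    to O(dt^2)."""
    for ang, rate in [(traj.alpha, traj.alpha_rate),
                      (traj.beta, traj.beta_rate)]:
        cd = (ang[2:] - ang[:-2]) / (2 * traj.dt)
        # O(dt^2) bound with the jerk-scale third derivative
        bound = tol_factor * mg.MotionLimits().jerk_max * traj.dt ** 2
        assert np.abs(cd - rate[1:-1]).max() < max(bound, 1e-9)


class TestScurve:
    def test_null_move_single_sample(self, limits):
        q, v, a = mg.scurve_segment(0.7, 0.7, limits, 0.01)
        assert len(q) == 1 and q[0] == 0.7 and v[0] == 0.0 and a[0] == 0.0

    @pytest.mark.parametrize("q0,q1", [(0.0, 3.0), (1.0, -2.5), (0.0, 0.05),
                                       (-0.3, 0.31), (2.0, 2.0001)])
    def test_profile_within_limits_and_exact_endpoints(self, limits, q0, q1):
        dt = 0.01
        q, v, a = mg.scurve_segment(q0, q1, limits, dt)
        assert q[0] == q0 and q[-1] == pytest.approx(q1, abs=1e-12)
        assert v[-1] == 0.0 and a[-1] == 0.0
        assert np.abs(v).max() <= limits.rate_max * (1 + 1e-9)
        assert np.abs(a).max() <= limits.acc_max * (1 + 1e-9)
        assert (np.abs(np.diff(a)) / dt).max() <= limits.jerk_max * (1 + 1e-6)

    def test_long_move_reaches_acc_limit_and_min_time_formula(self, limits):
        # independent oracle: with a cruise phase and the acceleration
        # plateau reached, T = D/vmax + vmax/amax + amax/jmax
        D = 4.0
        q, v, a = mg.scurve_segment(0.0, D, limits, 1e-3)
        assert a.max() == pytest.approx(limits.acc_max, rel=1e-9)
        assert v.max() == pytest.approx(limits.rate_max, rel=1e-9)
        T_expected = (D / limits.rate_max + limits.rate_max / limits.acc_max
                      + limits.acc_max / limits.jerk_max)
        assert mg.scurve_duration(D, limits) == pytest.approx(T_expected,
                                                              rel=1e-12)

    def test_short_move_triangular_phase_times(self, limits):
        # no cruise, no plateau: D = 2 j tj^3 exactly determines tj
        D = 0.01
        tj, ta, tc, _ = _scurve_plan(D, limits.rate_max, limits.acc_max,
                                     limits.jerk_max)
        assert ta == 0.0 and tc == 0.0
        assert 2 * limits.jerk_max * tj ** 3 == pytest.approx(D, rel=1e-9)


class TestInverseKinematics:
    def test_identity_pose(self):
        assert mg.inverse_kinematics((0, 0, -1), (0.0, 0.0)) == (0.0, 0.0)

    def test_antipode_round_trips(self):
        al, be = mg.inverse_kinematics((0, 0, 1), (0.0, 0.0))
        assert np.allclose(mg.gravity_direction(al, be), (0, 0, 1),
                           atol=1e-12)

    def test_random_directions_round_trip(self, rng):
        u = mg.sample_uniform_sphere(1000, rng=rng)
        pose = (0.3, -1.2)
        for w in u:
            al, be = mg.inverse_kinematics(w, pose)
            assert np.abs(mg.gravity_direction(al, be) - w).max() < 1e-6

    def test_nearest_branch_selected(self):
        # from a pose already near the target, angles should barely move
        w = mg.gravity_direction(0.2 + 2 * np.pi, 0.1)
        al, be = mg.inverse_kinematics(w, (2 * np.pi, 0.0))
        assert abs(al - (0.2 + 2 * np.pi)) < 1e-9 and abs(be - 0.1) < 1e-9

    def test_gimbal_lock_keeps_beta(self):
        al, be = mg.inverse_kinematics((0, -1, 0), (0.0, 0.77))
        assert be == 0.77 and al == pytest.approx(np.pi / 2)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            mg.inverse_kinematics((0, 0, -2.0))


class TestRandomWalk:
    def test_unit_norms_and_fixed_arc(self):
        arc = math.radians(5.0)
        path = mg.random_walk_sphere(500, arc, seed=3)
        u = path.directions
        assert np.abs(np.linalg.norm(u, axis=1) - 1).max() < 1e-9
        dots = np.sum(u[:-1] * u[1:], axis=1)
        assert np.abs(dots - math.cos(arc)).max() < 1e-9

    def test_first_steps_match_hand_rolled_oracle(self):
        # replay the documented update rule with the same seeded draws
        seed, arc, n = 11, math.radians(5.0), 2
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0.0, 2 * math.pi)
        p = np.array([0.0, 0.0, -1.0])
        h = np.array([math.cos(phi), math.sin(phi), 0.0])
        turns = rng.integers(0, 2, size=n)
        c, s = math.cos(arc), math.sin(arc)
        expected = [p.copy()]
        for k in range(n):
            p, h = c * p + s * h, -s * p + c * h
            expected.append(p.copy())
            h = (1.0 if turns[k] == 0 else -1.0) * np.cross(p, h)
        path = mg.random_walk_sphere(n, arc, seed=seed)
        assert np.allclose(path.directions, expected, atol=1e-12)

    def test_seed_reproducible(self):
        a = mg.random_walk_sphere(100, seed=5).directions
        b = mg.random_walk_sphere(100, seed=5).directions
        assert np.array_equal(a, b)

    def test_invalid_step_arc(self):
        with pytest.raises(ValueError):
            mg.random_walk_sphere(10, step_arc=4.0)


@pytest.fixture(scope="module")
def classic_traj():
    return mg.classic_random_control(
        mg.PlannerConfig(duration=300.0, dt=0.01, seed=4,
                         compensation=False))


@pytest.fixture(scope="module")
def uniform_traj():
    return mg.uniform_coverage_planner(
        mg.PlannerConfig(duration=300.0, dt=0.02, seed=6))


class TestClassicRandomControl:

    def test_motion_limits(self, classic_traj, limits):
        assert_limits_respected(classic_traj, limits)

    def test_angle_rate_consistency(self, classic_traj):
        assert_rates_consistent(classic_traj)

    def test_polar_concentration(self, classic_traj):
        # the induced direction density piles up at the inner-axis poles:
        # the caps |u_y| > 0.9 hold >= 2x their uniform share of 10%
        u = mg.trajectory_to_direction_path(classic_traj, 5).directions
        assert np.mean(np.abs(u[:, 1]) > 0.9) > 0.2

    def test_seed_reproducible(self):
        cfg = mg.PlannerConfig(duration=20.0, dt=0.01, seed=8)
        a = mg.classic_random_control(cfg)
        b = mg.classic_random_control(cfg)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta_rate, b.beta_rate)


class TestUniformCoveragePlanner:
    def test_motion_limits(self, uniform_traj, limits):
        assert_limits_respected(uniform_traj, limits)

    def test_angle_rate_consistency(self, uniform_traj):
        assert_rates_consistent(uniform_traj)

    def test_expected_length(self, uniform_traj):
        assert len(uniform_traj) == 300.0 / 0.02 + 1

    def test_residual_decays_with_compensation(self, uniform_traj):
        # the running-mean magnitude wobbles at the waypoint scale, so
        # monotone decay is asserted on its envelope over geometric windows
        # (brute-force running mean via residual_gravity's cumulative sum)
        res = mg.residual_gravity(mg.trajectory_to_direction_path(uniform_traj))
        edges = np.searchsorted(res.t, [18.75, 37.5, 75.0, 150.0, 300.0])
        env = [res.magnitude_g[a:b].max()
               for a, b in zip(edges[:-1], edges[1:])]
        assert np.all(np.diff(env) < 0)
        assert res.final_magnitude_g < 0.01

    @pytest.mark.parametrize("target", [0.1, 0.2, 0.4, 0.8])
    def test_partial_gravity_recovery(self, target):
        cfg = mg.PlannerConfig(duration=600.0, dt=0.05, mode="partial",
                               target_g=target, seed=3)
        u = mg.trajectory_to_direction_path(
            mg.uniform_coverage_planner(cfg)).directions
        recovered = np.linalg.norm(u.mean(axis=0))
        assert recovered == pytest.approx(target, rel=0.05)

    def test_seeded_runs_pass_uniformity_test(self):
        # decimated direction samples of the zero-gravity planner score
        # below the calibrated 5% critical value in >= 90% of seeded runs
        cal = mg.calibrate_null(300, 400, seed=9)
        crit = cal.critical_value(0.95)
        below = 0
        for seed in range(8):
            t = mg.uniform_coverage_planner(
                mg.PlannerConfig(duration=600.0, dt=0.05, seed=seed))
            u = mg.trajectory_to_direction_path(t, 40).directions
            below += mg.gine_F(u).F_star < crit
        assert below >= 7

    def test_seed_reproducible_bitwise(self):
        cfg = mg.PlannerConfig(duration=60.0, dt=0.02, seed=42)
        a = mg.uniform_coverage_planner(cfg)
        b = mg.uniform_coverage_planner(cfg)
        for col in ("alpha", "beta", "alpha_rate", "beta_rate",
                    "alpha_acc", "beta_acc"):
            assert np.array_equal(getattr(a, col), getattr(b, col))

    def test_infeasible_duration_rejected(self):
        with pytest.raises((mg.PlannerError, ValueError)):
            mg.uniform_coverage_planner(
                mg.PlannerConfig(duration=0.05, dt=0.01, seed=0,
                                 compensation=False))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            mg.PlannerConfig(duration=100.0, mode="zero", target_g=0.3)
        with pytest.raises(ValueError):
            mg.PlannerConfig(duration=100.0, mode="partial", target_g=1.5)


class TestTrajectoryToDirectionPath:
    def test_lengths(self):
        traj = constant_spin_trajectory(0.5, 10.0, 0.01)
        n = len(traj)
        assert len(mg.trajectory_to_direction_path(traj, 1)) == n
        assert len(mg.trajectory_to_direction_path(traj, 10)) == \
            math.ceil(n / 10)

    def test_single_axis_spin_traces_great_circle(self):
        # outer-axis spin: directions stay orthogonal to the axis image
        traj = constant_spin_trajectory(0.8, 30.0, 0.01)
        u = mg.trajectory_to_direction_path(traj, 7).directions
        assert np.abs(u[:, 0]).max() < 1e-12
        assert np.abs(np.linalg.norm(u, axis=1) - 1).max() < 1e-9
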