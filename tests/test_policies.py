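"""LQG policy synthesis: Riccati oracle checks, negation, time-to-contact."""

import numpy as np
import pytest

import reachmix as rm
from reachmix.policies import ControlConfig, _riccati
from conftest import rollout_closed_loop


def brute_force_dp(horizon, x0, q_term, r, grid):
    """Exhaustive DP oracle for the scalar system x' = x + u.

    Minimises q_term * x_T^2 + sum r * u_t^2 over a discretised control
    grid; the last stage is vectorised, outer stages enumerate.
    """
    if horizon == 1:
        return float(np.min(r * grid**2 + q_term * (x0 + grid) ** 2))
    best = np.inf
    for u0 in grid:
        c = r * u0 * u0 + brute_force_dp(horizon - 1, x0 + u0, q_term, r, grid)
        if c < best:
            best = c
    return best


def scalar_riccati(horizon, q_term, r):
    """Scalar finite-horizon Riccati for x' = x + u; returns P_0 and K_0."""
    P = q_term
    K0 = None
    for _ in range(horizon):
        K0 = P / (r + P)
        P = (1 - K0) ** 2 * P + r * K0 ** 2
    return P, K0


def test_scalar_one_step_matches_grid_minimisation():
    # min over u of u^2 + (x+u)^2 at x=1 -> u=-0.5, cost 0.5
    grid = np.arange(-2.0, 2.0 + 1e-9, 1e-4)
    costs = grid ** 2 + (1.0 + grid) ** 2
    u_star = grid[np.argmin(costs)]
    P0, K0 = scalar_riccati(1, 1.0, 1.0)
    assert u_star == pytest.approx(-K0 * 1.0, abs=1e-4)
    assert costs.min() == pytest.approx(P0 * 1.0, abs=1e-4)
    assert P0 == pytest.approx(0.5, abs=1e-12)


def test_scalar_three_step_value_matches_brute_force_dp():
    grid = np.arange(-2.0, 2.0 + 1e-9, 1e-3)
    v_dp = brute_force_dp(2, 1.0, q_term=1.0, r=1.0, grid=grid)
    P0, _ = scalar_riccati(2, 1.0, 1.0)
    assert v_dp == pytest.approx(P0, abs=1e-3)


def test_planar_riccati_reduces_to_scalar_recursion(quiet_plant):
    # With the planar A/B the velocity channel is (1 - damping*dt)-scaled;
    # cross-check the packaged recursion against an independent numpy one.
    goal = rm.Goal(position=(3.0, -1.0))
    pol = rm.synthesize_target_policy(quiet_plant, goal, horizon=25)
    A, B = quiet_plant.A, quiet_plant.B
    R = pol.control_weight * np.eye(2)
    P = np.diag([goal.terminal_position_weight] * 2 + [goal.terminal_velocity_weight] * 2)
    for t in range(24, -1, -1):
        K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
        np.testing.assert_allclose(K, pol.gains[t], atol=1e-8)
        P = (A - B @ K).T @ P @ (A - B @ K) + K.T @ R @ K
    np.testing.assert_allclose(P, pol.value[0], atol=1e-8)


def test_horizon_zero_rejected(quiet_plant):
    with pytest.raises(ValueError):
        rm.synthesize_target_policy(quiet_plant, rm.Goal(position=(1.0, 1.0)), horizon=0)


def test_stiff_terminal_weights_reach_goal(quiet_plant):
    goal = rm.Goal(
        position=(1.0, 2.0), terminal_position_weight=1e6, terminal_velocity_weight=1e6
    )
    pol = rm.synthesize_target_policy(quiet_plant, goal, horizon=60)
    traj = rollout_closed_loop(quiet_plant, pol, rm.State(position=(0, 0), velocity=(0, 0)))
    end = traj[-1]
    assert np.linalg.norm(end.position - np.array([1.0, 2.0])) < 1e-2
    assert end.speed < 1e-2


def test_obstacle_policy_is_velocity_unconstrained(quiet_plant):
    obs = rm.ObstacleGoal(position=(5.0, 5.0))
    pol = rm.synthesize_obstacle_policy(quiet_plant, obs, horizon=30)
    # terminal cost at the obstacle with arbitrary velocity is zero
    z = np.array([0.0, 0.0, 7.0, -3.0])
    assert z @ pol.value[-1] @ z == pytest.approx(0.0, abs=1e-12)
    # and it coincides with a target policy whose velocity weight is zero
    tgt = rm.Goal(position=(5.0, 5.0), terminal_velocity_weight=0.0)
    pol2 = rm.synthesize_target_policy(quiet_plant, tgt, horizon=30)
    np.testing.assert_allclose(pol.gains, pol2.gains)


def test_obstacle_policy_rollout_reaches_obstacle(quiet_plant):
    obs = rm.ObstacleGoal(position=(15.0, 15.0))
    T = rm.time_to_contact(rm.State(position=(0, 0), velocity=(0, 0)), (15, 15), quiet_plant.dt)
    pol = rm.synthesize_obstacle_policy(quiet_plant, obs, horizon=T)
    end = rollout_closed_loop(quiet_plant, pol, rm.State(position=(0, 0), velocity=(0, 0)))[-1]
    assert np.linalg.norm(end.position - np.array([15.0, 15.0])) < 1e-1


def test_negation_flips_controls_exactly(quiet_plant):
    pol = rm.synthesize_target_policy(quiet_plant, rm.Goal(position=(4.0, 4.0)), horizon=20)
    neg = rm.negate_policy(pol)
    rng = np.random.default_rng(1)
    for x in rng.normal(scale=10.0, size=(1000, 4)):
        np.testing.assert_array_equal(neg.control(x, 3), -pol.control(x, 3))
    np.testing.assert_array_equal(
        neg.control(pol.goal_offset, 0), np.zeros(2)
    )  # zero control is its own negation


def test_double_negation_rejected(quiet_plant):
    pol = rm.synthesize_obstacle_policy(quiet_plant, rm.ObstacleGoal(position=(1, 1)), horizon=10)
    neg = rm.negate_policy(pol)
    with pytest.raises(ValueError):
        rm.negate_policy(neg)


def test_negated_policy_step_increases_obstacle_distance(quiet_plant):
    obs = rm.ObstacleGoal(position=(10.0, 10.0))
    pol = rm.synthesize_obstacle_policy(quiet_plant, obs, horizon=40)
    neg = rm.negate_policy(pol)
    start = rm.State(position=(10.0 - 5 / np.sqrt(2), 10.0 - 5 / np.sqrt(2)), velocity=(0, 0))
    center = np.array([10.0, 10.0])

    def dist_after(policy):
        st = start
        for t in range(3):
            st = rm.step(quiet_plant, st, policy.control(st, t))
        return np.linalg.norm(st.position - center)

    assert dist_after(neg) > dist_after(pol)


def test_cost_to_go_zero_at_goal(quiet_plant):
    pol = rm.synthesize_target_policy(quiet_plant, rm.Goal(position=(2.0, 3.0)), horizon=15)
    at_goal = rm.State(position=(2.0, 3.0), velocity=(0.0, 0.0))
    assert rm.cost_to_go(pol, at_goal) == pytest.approx(0.0, abs=1e-10)


def test_cost_to_go_monotone_along_ray(quiet_plant):
    pol = rm.synthesize_target_policy(quiet_plant, rm.Goal(position=(0.0, 0.0)), horizon=30)
    costs = [
        rm.cost_to_go(pol, rm.State(position=(d, d), velocity=(0.0, 0.0)))
        for d in (1.0, 2.0, 4.0, 8.0, 16.0)
    ]
    assert all(b > a for a, b in zip(costs, costs[1:]))


def test_straight_line_reach_has_negligible_lateral_deviation(quiet_plant):
    goal = rm.Goal(position=(30.0, 30.0))
    pol = rm.synthesize_target_policy(quiet_plant, goal, horizon=100)
    traj = rollout_closed_loop(quiet_plant, pol, rm.State(position=(0, 0), velocity=(0, 0)))
    pos = np.array([s.position for s in traj])
    lateral = np.abs(pos[:, 1] - pos[:, 0]) / np.sqrt(2)
    path_len = np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))
    assert lateral.max() < 1e-3 * path_len


class TestTimeToContact:
    def test_zero_distance_clamps_to_floor(self):
        st = rm.State(position=(5.0, 5.0), velocity=(0.0, 0.0))
        assert rm.time_to_contact(st, (5.0, 5.0), 0.01) == ControlConfig().t_min

    def test_weak_monotonicity_in_distance(self):
        st = lambda d: rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        h1 = rm.time_to_contact(st(1), (10.0, 0.0), 0.01)
        h2 = rm.time_to_contact(st(1), (20.0, 0.0), 0.01)
        assert h2 >= h1

    def test_default_rule_arithmetic(self):
        # distance 30*sqrt(2) at reference speed 30 units/s, dt=0.01
        cfg = ControlConfig(v_ref=30.0)
        st = rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        assert rm.time_to_contact(st, (30.0, 30.0), 0.01, cfg) == 141

    def test_canonical_reach_is_one_second(self):
        st = rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        assert rm.time_to_contact(st, (30.0, 30.0), 0.01) == 100
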