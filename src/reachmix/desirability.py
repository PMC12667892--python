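"""Relative desirability: the common currency that weighs competing policies.

Each option's desirability is the product of an *action-related* component
(a softmax over option action costs with inverse temperature lambda — the
probability that this option is the cheapest) and a *goods-related*
component (for targets, the probability of reward times the probability of
NOT colliding along the planned reach; for obstacles, the collision
probability itself).  A risk-aversion scalar alpha in [0,1] then splits the
mixture mass between target pursuit (alpha -> 1) and obstacle avoidance
(alpha -> 0).

Collision risk is state-conditional: it is estimated from a noise-free
rollout of the target-approach plan being vetted, so the same probability
discounts the target (1 - P) and energises avoidance (P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collision import CollisionZone, RolloutSpec, _indicator_batch, rollout_states
from .plant import PlantModel, State
from .policies import (
    ControlConfig,
    DEFAULT_CONTROL,
    FeedbackPolicy,
    Goal,
    ObstacleGoal,
    cost_to_go,
    negate_policy,
    synthesize_obstacle_policy,
    synthesize_target_policy,
    time_to_contact,
)

__all__ = [
    "Scene",
    "Obstacle",
    "DesirabilityBreakdown",
    "DegenerateSceneError",
    "action_component",
    "goods_component_target",
    "goods_component_obstacle",
    "relative_desirability",
    "mixture_weights",
    "evaluate_scene",
    "sweep_desirability",
    "SweepResult",
]


class DegenerateSceneError(ValueError):
    """All desirabilities are zero: the Eq.-of-motion mixture is undefined."""


@dataclass(frozen=True)
class Obstacle:
    """An obstacle option: the anti-target goal plus its collision zone."""

    goal: ObstacleGoal
    zone: CollisionZone


@dataclass
class Scene:
    """Full task specification: start, targets, obstacles, alpha and lambda."""

    goals: list[Goal]
    obstacles: list[Obstacle] = field(default_factory=list)
    alpha: float = 0.1
    lam: float = 1.0
    start: tuple[float, float] = (0.0, 0.0)
    mode: str = "cluttered"  # or "obstacle_free": goods term ignores collisions
    jumps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam <= 0.0:
            raise ValueError("lam (inverse temperature) must be positive")
        if len(self.goals) + len(self.obstacles) < 1:
            raise ValueError("scene needs at least one goal or obstacle")
        if self.mode not in ("cluttered", "obstacle_free"):
            raise ValueError("mode must be 'cluttered' or 'obstacle_free'")

    @property
    def n_goals(self) -> int:
        return len(self.goals)

    @property
    def n_obstacles(self) -> int:
        return len(self.obstacles)


@dataclass
class DesirabilityBreakdown:
    """Per-option components, desirabilities, and final mixture weights."""

    action_target: np.ndarray
    action_obstacle: np.ndarray
    goods_target: np.ndarray
    goods_obstacle: np.ndarray
    v_target: np.ndarray
    v_obstacle: np.ndarray
    weights_target: np.ndarray
    weights_obstacle: np.ndarray
    p_risk_target: np.ndarray    # collision risk of each target's planned reach
    degenerate: bool = False     # True when the alpha-split fallback was used


def action_component(costs, lam: float) -> np.ndarray:
    """Softmax probability that each option has the lowest action cost.

    exp(-V/lambda) / sum exp(-V/lambda), computed in shifted (log-sum-exp
    guarded) form; the lambda prefactor of the raw expression cancels.
    Lower cost => strictly higher probability.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ValueError("need at least one cost")
    if not np.all(np.isfinite(costs)):
        raise ValueError("costs must be finite")
    if lam <= 0:
        raise ValueError("lam must be positive")
    a = -costs / lam
    a -= a.max()
    w = np.exp(a)
    return w / w.sum()


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


def goods_component_target(
    p_collision: float,
    reward_probability: float = 1.0,
    mode: str = "cluttered",
) -> float:
    """Goods term for a target: P(not collide) x P(reward).

    In 'obstacle_free' mode the collision term is dropped and the reward
    probability alone remains (the multi-target special case).
    """
    p = _check_prob(p_collision, "p_collision")
    rw = _check_prob(reward_probability, "reward_probability")
    if mode == "obstacle_free":
        return rw
    return (1.0 - p) * rw


def goods_component_obstacle(p_collision: float) -> float:
    """Goods term for an obstacle: the collision probability itself."""
    return _check_prob(p_collision, "p_collision")


def relative_desirability(action: float, goods: float) -> float:
    """Combined desirability: product of the two probability components."""
    return _check_prob(action, "action") * _check_prob(goods, "goods")


def mixture_weights(v_target, v_obstacle, alpha: float):
    """Risk-aversion-weighted mixture weights.

    w_target[j]  = alpha   * v_target[j]  / D
    w_obstacle[k]= (1-alpha)* v_obstacle[k]/ D
    D = alpha * sum(v_target) + (1-alpha) * sum(v_obstacle)

    Raises DegenerateSceneError when D is zero (all desirabilities vanish).
    """
    vt = np.asarray(v_target, dtype=float)
    vo = np.asarray(v_obstacle, dtype=float)
    if np.any(vt < 0) or np.any(vo < 0):
        raise ValueError("desirabilities must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    D = alpha * vt.sum() + (1.0 - alpha) * vo.sum()
    if D <= 0.0:
        raise DegenerateSceneError(
            "all alpha-weighted desirabilities are zero; mixture weights undefined"
        )
    return alpha * vt / D, (1.0 - alpha) * vo / D


def _fallback_weights(n: int, m: int, alpha: float):
    """Uniform alpha-split used by the closed-loop simulator on degeneracy."""
    mass = alpha * (n > 0) + (1.0 - alpha) * (m > 0)
    if mass <= 0:
        # e.g. alpha=1 with no targets: fall back to plain uniform
        total = n + m
        return (np.full(n, 1.0 / total) if n else np.zeros(0),
                np.full(m, 1.0 / total) if m else np.zeros(0))
    wt = np.full(n, alpha / (n * mass)) if n else np.zeros(0)
    wo = np.full(m, (1.0 - alpha) / (m * mass)) if m else np.zeros(0)
    return wt, wo


def build_policies(
    scene: Scene,
    state: State,
    plant: PlantModel,
    config: ControlConfig = DEFAULT_CONTROL,
):
    """Synthesise (cached) per-option policies at the current state.

    Returns (target_policies, negated_obstacle_policies); horizons follow the
    per-state time-to-contact rule, so this is the receding-horizon refresh
    performed every simulation step.
    """
    target_policies = []
    for g in scene.goals:
        T = time_to_contact(state, g.position, plant.dt, config)
        target_policies.append(synthesize_target_policy(plant, g, T, config))
    obstacle_policies = []
    for ob in scene.obstacles:
        T = time_to_contact(state, ob.goal.position, plant.dt, config)
        obstacle_policies.append(negate_policy(synthesize_obstacle_policy(plant, ob.goal, T, config)))
    return target_policies, obstacle_policies


def _risk_matrix(
    scene: Scene,
    state: State,
    plant: PlantModel,
    target_policies: list[FeedbackPolicy],
    spec: RolloutSpec,
) -> np.ndarray:
    """P[j, k]: collision probability with zone k along target j's planned reach.

    With no targets (pure-avoidance scene) the prediction falls back to a
    ballistic zero-control rollout of the current state.
    """
    n, m = scene.n_goals, scene.n_obstacles
    if m == 0:
        return np.zeros((max(n, 1), 0))
    zones = [ob.zone for ob in scene.obstacles]
    if n == 0:
        x = state.vector()
        traj = np.empty((spec.n_steps, 4))
        for t in range(spec.n_steps):
            traj[t] = x
            x = plant.A @ x
        P = np.empty((1, m))
        for k, zone in enumerate(zones):
            P[0, k] = float(np.mean(_indicator_batch(traj[:, :2], traj[:, 2:], zone)))
        return P
    P = np.empty((n, m))
    for j, pol in enumerate(target_policies):
        traj = rollout_states(plant, pol, state.vector(), spec.n_steps)[:, 0, :]
        for k, zone in enumerate(zones):
            P[j, k] = float(np.mean(_indicator_batch(traj[:, :2], traj[:, 2:], zone)))
    return P


def evaluate_scene(
    scene: Scene,
    state: State,
    plant: PlantModel,
    policies: tuple[list[FeedbackPolicy], list[FeedbackPolicy]] | None = None,
    control_config: ControlConfig = DEFAULT_CONTROL,
    rollout_spec: RolloutSpec = RolloutSpec(),
    on_degenerate: str = "raise",
) -> DesirabilityBreakdown:
    """Full desirability pipeline at one state.

    Computes per-option cost-to-go, within-category action softmaxes,
    rollout-based collision risk, goods components, desirabilities and the
    alpha-weighted mixture weights.  ``policies`` may carry pre-synthesised
    (target, negated-obstacle) policies; otherwise they are built here with
    the receding-horizon rule.  ``on_degenerate`` is 'raise' (default) or
    'fallback' (uniform alpha-split, flagged in the breakdown).
    """
    if policies is None:
        policies = build_policies(scene, state, plant, control_config)
    target_policies, obstacle_policies = policies
    n, m = scene.n_goals, scene.n_obstacles
    if len(target_policies) != n or len(obstacle_policies) != m:
        raise ValueError("policies out of sync with scene options")

    cost_t = np.array([cost_to_go(p, state) for p in target_policies])
    cost_o = np.array([cost_to_go(p, state) for p in obstacle_policies])
    act_t = action_component(cost_t, scene.lam) if n else np.zeros(0)
    act_o = action_component(cost_o, scene.lam) if m else np.zeros(0)

    P = _risk_matrix(scene, state, plant, target_policies, rollout_spec)
    if m and n:
        p_target = P.max(axis=1)            # worst-case risk of each reach plan
        p_obstacle = P.max(axis=0)          # risk each obstacle poses to any plan
    elif m:
        p_target = np.zeros(0)
        p_obstacle = P[0]
    else:
        p_target = np.zeros(n)
        p_obstacle = np.zeros(0)

    goods_t = np.array([
        goods_component_target(p_target[j], scene.goals[j].reward_probability, scene.mode)
        for j in range(n)
    ])
    goods_o = np.array([goods_component_obstacle(p_obstacle[k]) for k in range(m)])
    v_t = act_t * goods_t
    v_o = act_o * goods_o

    degenerate = False
    try:
        w_t, w_o = mixture_weights(v_t, v_o, scene.alpha)
    except DegenerateSceneError:
        if on_degenerate != "fallback":
            raise
        degenerate = True
        w_t, w_o = _fallback_weights(n, m, scene.alpha)

    return DesirabilityBreakdown(
        action_target=act_t,
        action_obstacle=act_o,
        goods_target=goods_t,
        goods_obstacle=goods_o,
        v_target=v_t,
        v_obstacle=v_o,
        weights_target=w_t,
        weights_obstacle=w_o,
        p_risk_target=p_target,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Vectorised state sweeps (desirability cartography / bound checks)
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Dense sweep of the desirability pipeline over many states.

    Axes: lam index L, state index n, option index (N targets / M obstacles),
    alpha index A.  ``weight_sum`` is NaN where the Eq.-5 denominator is zero
    (degenerate states are reported, not silently normalised).
    """

    v_target: np.ndarray        # (L, n, N)
    v_obstacle: np.ndarray      # (L, n, M)
    action_target: np.ndarray   # (n, N) -- lam-dependent only through softmax
    p_risk_target: np.ndarray   # (n, N)
    weight_sum: np.ndarray      # (L, A, n)
    lams: np.ndarray
    alphas: np.ndarray

    @property
    def v_all(self) -> np.ndarray:
        parts = [a for a in (self.v_target, self.v_obstacle) if a.size]
        return np.concatenate([a.reshape(a.shape[0], -1) for a in parts], axis=1)

    @property
    def v_max(self) -> float:
        return float(self.v_all.max())

    @property
    def v_min(self) -> float:
        return float(self.v_all.min())


def _horizons(positions: np.ndarray, goal_xy, dt: float, cfg: ControlConfig) -> np.ndarray:
    d = np.linalg.norm(positions - np.asarray(goal_xy, float)[None, :], axis=1)
    return np.clip(np.round(d / (cfg.v_ref * dt)), cfg.t_min, cfg.t_max).astype(int)


def sweep_desirability(
    scene: Scene,
    positions: np.ndarray,
    velocities: np.ndarray,
    lams,
    alphas,
    plant: PlantModel,
    control_config: ControlConfig = DEFAULT_CONTROL,
    rollout_spec: RolloutSpec = RolloutSpec(),
) -> SweepResult:
    """Evaluate every option's desirability at many states at once.

    Semantically identical to looping ``evaluate_scene`` over states and the
    (lam, alpha) grid with noise-free rollouts; states sharing a planning
    horizon are batched through one Riccati solution for speed.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    velocities = np.atleast_2d(np.asarray(velocities, float))
    if positions.shape != velocities.shape or positions.shape[1] != 2:
        raise ValueError("positions and velocities must both be (n, 2)")
    lams = np.atleast_1d(np.asarray(lams, float))
    alphas = np.atleast_1d(np.asarray(alphas, float))
    n_states = positions.shape[0]
    N, M = scene.n_goals, scene.n_obstacles
    X = np.hstack([positions, velocities])
    zones = [ob.zone for ob in scene.obstacles]

    cost_t = np.empty((n_states, N))
    risk = np.zeros((n_states, N, M))
    for j, g in enumerate(scene.goals):
        hs = _horizons(positions, g.position, plant.dt, control_config)
        for h in np.unique(hs):
            idx = np.where(hs == h)[0]
            pol = synthesize_target_policy(plant, g, int(h), control_config)
            Z = X[idx] - pol.goal_offset[None, :]
            cost_t[idx, j] = np.einsum("bi,ij,bj->b", Z, pol.value[0], Z)
            if M:
                traj = rollout_states(plant, pol, X[idx], rollout_spec.n_steps)
                T, b, _ = traj.shape
                flat = traj.reshape(T * b, 4)
                for k, zone in enumerate(zones):
                    ind = _indicator_batch(flat[:, :2], flat[:, 2:], zone).reshape(T, b)
                    risk[idx, j, k] = ind.mean(axis=0)

    cost_o = np.empty((n_states, M))
    for k, ob in enumerate(scene.obstacles):
        hs = _horizons(positions, ob.goal.position, plant.dt, control_config)
        for h in np.unique(hs):
            idx = np.where(hs == h)[0]
            pol = synthesize_obstacle_policy(plant, ob.goal, int(h), control_config)
            Z = X[idx] - pol.goal_offset[None, :]
            cost_o[idx, k] = np.einsum("bi,ij,bj->b", Z, pol.value[0], Z)

    if N and M:
        p_target = risk.max(axis=2)                      # (n, N)
        p_obstacle = risk.max(axis=1)                    # (n, M)
    elif M:
        p_target = np.zeros((n_states, 0))
        p_obstacle = np.zeros((n_states, M))
    else:
        p_target = np.zeros((n_states, N))
        p_obstacle = np.zeros((n_states, 0))

    rewards = np.array([g.reward_probability for g in scene.goals])
    if scene.mode == "obstacle_free":
        goods_t = np.broadcast_to(rewards[None, :], (n_states, N)).copy()
    else:
        goods_t = (1.0 - p_target) * rewards[None, :]
    goods_o = p_obstacle

    def _softmax_rows(costs: np.ndarray, lam: float) -> np.ndarray:
        if costs.shape[1] == 0:
            return costs
        a = -costs / lam
        a = a - a.max(axis=1, keepdims=True)
        w = np.exp(a)
        return w / w.sum(axis=1, keepdims=True)

    L, A = len(lams), len(alphas)
    v_t = np.empty((L, n_states, N))
    v_o = np.empty((L, n_states, M))
    act_t_default = _softmax_rows(cost_t, lams[0])
    for li, lam in enumerate(lams):
        at = _softmax_rows(cost_t, lam)
        ao = _softmax_rows(cost_o, lam)
        v_t[li] = at * goods_t
        v_o[li] = ao * goods_o

    weight_sum = np.full((L, A, n_states), np.nan)
    for li in range(L):
        st = v_t[li].sum(axis=1) if N else np.zeros(n_states)
        so = v_o[li].sum(axis=1) if M else np.zeros(n_states)
        for ai, alpha in enumerate(alphas):
            D = alpha * st + (1.0 - alpha) * so
            ok = D > 0
            weight_sum[li, ai, ok] = (alpha * st[ok] + (1.0 - alpha) * so[ok]) / D[ok]

    return SweepResult(
        v_target=v_t,
        v_obstacle=v_o,
        action_target=act_t_default,
        p_risk_target=p_target,
        weight_sum=weight_sum,
        lams=lams,
        alphas=alphas,
    )
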