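"""Finite-horizon LQG feedback policies for target approach and obstacle avoidance.

Each candidate option (a reach target or an obstacle) gets its own optimal
controller: a backward Riccati recursion over the time-to-contact horizon T
with terminal cost on the residual between the hand state and the option's
location, and a running effort cost ``u' R u``.  Target policies additionally
penalise terminal velocity (arrive and stop); obstacle *approach* policies do
not (any arrival velocity collides just fine).  The avoidance policy is the
approach policy with its emitted control negated — an approximation that
turns the obstacle into an "anti-target" rather than solving an avoidance
cost directly.

Gains are certainty-equivalent: signal-dependent noise perturbs execution,
not synthesis.  Because the residual dynamics are goal-independent (the goal
enters only as a position offset with zero velocity), gain/value arrays are
cached per (plant, horizon, weights) and shared across goals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plant import PlantModel, State

__all__ = [
    "Goal",
    "ObstacleGoal",
    "ControlConfig",
    "FeedbackPolicy",
    "riccati_recursion",
    "synthesize_target_policy",
    "synthesize_obstacle_policy",
    "negate_policy",
    "cost_to_go",
    "time_to_contact",
]

#: Distance of the canonical (0,0) -> (30,30) reach; the default reference
#: speed completes it in one second.
_CANONICAL_REACH = float(np.hypot(30.0, 30.0))


@dataclass(frozen=True)
class Goal:
    """A reach target: location, reward probability and terminal weights."""

    position: tuple[float, float]
    reward_probability: float = 1.0
    terminal_position_weight: float = 1e4
    terminal_velocity_weight: float = 1e4

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))
        if not 0.0 <= self.reward_probability <= 1.0:
            raise ValueError("reward_probability must lie in [0, 1]")
        if self.terminal_position_weight <= 0 or self.terminal_velocity_weight < 0:
            raise ValueError("terminal weights must be positive (position) / >= 0 (velocity)")


@dataclass(frozen=True)
class ObstacleGoal:
    """The 'anti-target': the obstacle location an approach policy is built for."""

    position: tuple[float, float]
    terminal_position_weight: float = 1e4

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))
        if self.terminal_position_weight <= 0:
            raise ValueError("terminal_position_weight must be > 0")


@dataclass(frozen=True)
class ControlConfig:
    """Controller parameters shared by every option.

    r:       effort weight (R = r * I) in the running cost.
    v_ref:   reference speed (units/s) converting distance to a planning
             horizon; default covers the canonical reach in one second.
    t_min/t_max: clamp on the time-to-contact horizon, in steps.
    """

    r: float = 1e-4
    v_ref: float = _CANONICAL_REACH
    t_min: int = 10
    t_max: int = 500

    def __post_init__(self) -> None:
        if self.r <= 0 or self.v_ref <= 0:
            raise ValueError("r and v_ref must be positive")
        if not 1 <= self.t_min <= self.t_max:
            raise ValueError("need 1 <= t_min <= t_max")


DEFAULT_CONTROL = ControlConfig()


@dataclass(frozen=True)
class FeedbackPolicy:
    """A synthesised time-indexed feedback law u_t = sign * (-K_t (x - g)).

    ``gains`` holds exactly ``horizon`` matrices K_t (2x4); ``value`` holds the
    cost-to-go matrices P_t (t = 0..horizon).  ``goal_offset`` is the 4-vector
    [gx, gy, 0, 0] subtracted from the state, implementing the selection
    matrix that picks hand-minus-goal out of the state.  ``sign`` is +1 for
    approach, -1 for a negated avoidance policy; negation flips the emitted
    control but keeps the approach policy's cost-to-go machinery.
    """

    gains: np.ndarray          # (T, 2, 4)
    value: np.ndarray          # (T+1, 4, 4)
    horizon: int
    goal_offset: np.ndarray    # (4,)
    sign: int = 1
    control_weight: float = 1e-4
    terminal_velocity_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.gains.shape[0] != self.horizon:
            raise ValueError("gains must have exactly `horizon` entries")

    def control(self, state: State | np.ndarray, t: int = 0) -> np.ndarray:
        """Emitted control at internal policy time ``t`` (clamped to T-1)."""
        x = state.vector() if isinstance(state, State) else np.asarray(state, float).reshape(4)
        t = min(max(int(t), 0), self.horizon - 1)
        z = x - self.goal_offset
        return self.sign * (-(self.gains[t] @ z))

    def with_sign(self, sign: int) -> "FeedbackPolicy":
        p = replace(self, sign=sign)
        object.__setattr__(p, "_closed_loop", None)
        return p


def _riccati_cache_key(plant: PlantModel, horizon: int, wp: float, wv: float, r: float):
    return (plant.key(), horizon, wp, wv, r)


_RICCATI_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def riccati_recursion(A: np.ndarray, B: np.ndarray, Q_term: np.ndarray, R: np.ndarray, horizon: int):
    """Finite-horizon backward Riccati recursion for x' = A x + B u.

    Terminal cost x'Q_term x, running cost u'Ru (no state running cost).
    Returns (gains (T, m, n), value (T+1, n, n)); u_t = -gains[t] @ x is the
    optimal control and x' value[t] x the cost-to-go at stage t.
    """
    n, m = B.shape
    T = int(horizon)
    if T < 1:
        raise ValueError("horizon must be >= 1")
    gains = np.empty((T, m, n))
    value = np.empty((T + 1, n, n))
    P = np.asarray(Q_term, dtype=float).copy()
    value[T] = P
    for t in range(T - 1, -1, -1):
        BtP = B.T @ P
        try:
            K = np.linalg.solve(R + BtP @ B, BtP @ A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RuntimeError("singular (R + B'PB) in Riccati recursion") from exc
        Acl = A - B @ K
        P = Acl.T @ P @ Acl + K.T @ R @ K
        P = 0.5 * (P + P.T)
        gains[t] = K
        value[t] = P
    return gains, value


def _riccati(plant: PlantModel, horizon: int, wp: float, wv: float, r: float):
    """Cached planar recursion; returns (gains (T,2,4), value (T+1,4,4))."""
    key = _riccati_cache_key(plant, horizon, wp, wv, r)
    hit = _RICCATI_CACHE.get(key)
    if hit is not None:
        return hit
    out = riccati_recursion(
        plant.A, plant.B, np.diag([wp, wp, wv, wv]), r * np.eye(2), horizon
    )
    _RICCATI_CACHE[key] = out
    return out


def _make_policy(plant, position, wp, wv, cfg: ControlConfig, horizon: int) -> FeedbackPolicy:
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    gains, value = _riccati(plant, int(horizon), wp, wv, cfg.r)
    offset = np.array([position[0], position[1], 0.0, 0.0])
    pol = FeedbackPolicy(
        gains=gains,
        value=value,
        horizon=int(horizon),
        goal_offset=offset,
        sign=+1,
        control_weight=cfg.r,
        terminal_velocity_weight=wv,
    )
    # residual closed loop is sign-dependent; computed lazily in rollouts
    object.__setattr__(pol, "_closed_loop", None)
    return pol


def closed_loop_matrices(plant: PlantModel, policy: FeedbackPolicy) -> np.ndarray:
    """Residual dynamics z_{t+1} = (A - sign*B K_t) z_t for noise-free rollout.

    Valid because the goal offset has zero velocity, so (A - I) g = 0 and the
    residual evolves homogeneously.
    """
    cached = getattr(policy, "_closed_loop", None)
    if cached is not None:
        return cached
    M = plant.A[None, :, :] - policy.sign * np.einsum("ij,tjk->tik", plant.B, policy.gains)
    object.__setattr__(policy, "_closed_loop", M)
    return M


def synthesize_target_policy(
    plant: PlantModel,
    goal: Goal,
    horizon: int,
    config: ControlConfig = DEFAULT_CONTROL,
) -> FeedbackPolicy:
    """LQG policy that reaches ``goal`` with zero terminal velocity."""
    return _make_policy(
        plant, goal.position, goal.terminal_position_weight, goal.terminal_velocity_weight,
        config, horizon,
    )


def synthesize_obstacle_policy(
    plant: PlantModel,
    obs: ObstacleGoal,
    horizon: int,
    config: ControlConfig = DEFAULT_CONTROL,
) -> FeedbackPolicy:
    """LQG policy that reaches the obstacle with *no* terminal velocity cost.

    Returned un-negated (sign=+1); negation is a separate, explicit step.
    """
    return _make_policy(plant, obs.position, obs.terminal_position_weight, 0.0, config, horizon)


def negate_policy(p: FeedbackPolicy) -> FeedbackPolicy:
    """Flip the emitted control of an approach policy (sign -> -1).

    The cost-to-go machinery is retained from the approach policy: the
    avoidance action cost *is* the approach cost, which is what makes
    avoidance cheapest — maximally 'desirable' — near the obstacle.
    """
    if p.sign != +1:
        raise ValueError("policy is already negated; double negation is rejected")
    return p.with_sign(-1)


def cost_to_go(p: FeedbackPolicy, state: State | np.ndarray) -> float:
    """Quadratic value function z' P_0 z of the synthesised policy at ``state``."""
    x = state.vector() if isinstance(state, State) else np.asarray(state, float).reshape(4)
    z = x - p.goal_offset
    return float(z @ p.value[0] @ z)


def time_to_contact(
    state: State,
    goal_position,
    dt: float = 0.01,
    config: ControlConfig = DEFAULT_CONTROL,
) -> int:
    """Planning horizon (steps) to contact an option from the current state.

    Distance-proportional receding horizon: round(d / v_ref / dt) clamped to
    [t_min, t_max]; it shrinks (weakly) as the hand nears the option.
    """
    pos = state.position if isinstance(state, State) else np.asarray(state, float)[:2]
    d = float(np.linalg.norm(np.asarray(goal_position, float) - pos))
    steps = int(round(d / (config.v_ref * dt)))
    return int(np.clip(steps, config.t_min, config.t_max))
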