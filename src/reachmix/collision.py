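"""Expanded collision zone, collision cone, and rollout-based collision risk.

An obstacle is surrounded by two concentric circles: the inner one matches
its physical diameter, the outer one the tolerance boundary within which a
collision still feels likely.  The positional collision probability is 1
inside the inner circle, decays linearly to 0 at the outer circle, and is 0
beyond it.  Direction matters too: the probability only counts when the
velocity points into the *collision cone*, the angular sector bounded by the
tangent lines from the hand to the outer circle.  Risk along a plan is the
mean of this indicator over a noise-free rollout of the plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import PlantModel, State
from .policies import FeedbackPolicy, closed_loop_matrices

__all__ = [
    "CollisionZone",
    "RolloutSpec",
    "effective_diameter",
    "position_collision_probability",
    "in_collision_cone",
    "collision_indicator",
    "trajectory_collision_probability",
]

_CENTER_EPS = 1e-12


@dataclass(frozen=True)
class CollisionZone:
    """Concentric inner (physical) / outer (tolerance) circles of an obstacle."""

    center: tuple[float, float]
    d_inner: float
    d_outer: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if not 0.0 < self.d_inner < self.d_outer:
            raise ValueError("need 0 < d_inner < d_outer")

    @property
    def r_inner(self) -> float:
        return self.d_inner / 2.0

    @property
    def r_outer(self) -> float:
        return self.d_outer / 2.0


@dataclass(frozen=True)
class RolloutSpec:
    """Lookahead for trajectory risk: number of future steps and which policy
    drives the prediction (documentation tag; the policy object is passed in)."""

    n_steps: int = 50
    policy_source: str = "target"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def effective_diameter(hand_position, zone: CollisionZone) -> float:
    """Diameter of the smallest zone-centred circle through the hand.

    Equals twice the hand-centre distance, the reading that makes the
    comparisons with d_inner/d_outer dimensionally coherent.
    """
    p = np.asarray(hand_position, float).reshape(2)
    return 2.0 * float(np.linalg.norm(p - np.asarray(zone.center)))


def position_collision_probability(d: float, zone: CollisionZone) -> float:
    """Piecewise-linear positional collision probability at effective diameter d."""
    if d < 0:
        raise ValueError("effective diameter must be >= 0")
    if d <= zone.d_inner:
        return 1.0
    if d >= zone.d_outer:
        return 0.0
    return 1.0 - (d - zone.d_inner) / (zone.d_outer - zone.d_inner)


def in_collision_cone(hand_position, velocity, zone: CollisionZone) -> bool:
    """True iff the velocity points into the tangent cone of the outer circle.

    Outside the outer circle the half-angle is arcsin(r_outer / distance).
    Inside it the tangent construction degenerates; membership then means the
    velocity has a positive component toward the centre (at the centre itself,
    any nonzero velocity counts).  Zero velocity is never in the cone.
    """
    p = np.asarray(hand_position, float).reshape(2)
    v = np.asarray(velocity, float).reshape(2)
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return False
    to_center = np.asarray(zone.center) - p
    dist = float(np.linalg.norm(to_center))
    if dist < _CENTER_EPS:
        return True
    if dist < zone.r_outer:
        return float(v @ to_center) > 0.0
    cos_angle = float(v @ to_center) / (speed * dist)
    angle = float(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
    half_angle = float(np.arcsin(min(zone.r_outer / dist, 1.0)))
    return angle <= half_angle


def collision_indicator(state: State, zone: CollisionZone) -> float:
    """Per-state risk: positional probability gated by cone membership."""
    if not in_collision_cone(state.position, state.velocity, zone):
        return 0.0
    return position_collision_probability(effective_diameter(state.position, zone), zone)


def _indicator_batch(positions: np.ndarray, velocities: np.ndarray, zone: CollisionZone) -> np.ndarray:
    """Vectorised collision indicator over (n, 2) position/velocity arrays."""
    positions = np.atleast_2d(positions)
    velocities = np.atleast_2d(velocities)
    c = np.asarray(zone.center)
    to_c = c - positions
    dist = np.linalg.norm(to_c, axis=1)
    speed = np.linalg.norm(velocities, axis=1)
    dot = np.einsum("ij,ij->i", velocities, to_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_angle = np.where(speed * dist > 0, dot / np.maximum(speed * dist, _CENTER_EPS), -1.0)
        angle = np.arccos(np.clip(cos_angle, -1.0, 1.0))
        half = np.arcsin(np.clip(zone.r_outer / np.maximum(dist, _CENTER_EPS), 0.0, 1.0))
    in_cone = np.where(
        speed == 0.0,
        False,
        np.where(dist < _CENTER_EPS, True, np.where(dist < zone.r_outer, dot > 0.0, angle <= half)),
    )
    d_eff = 2.0 * dist
    p_pos = np.clip(1.0 - (d_eff - zone.d_inner) / (zone.d_outer - zone.d_inner), 0.0, 1.0)
    return np.where(in_cone, p_pos, 0.0)


def rollout_states(
    plant: PlantModel,
    policy: FeedbackPolicy,
    x0: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Noise-free closed-loop rollout; returns (n_steps, batch, 4) state vectors.

    ``x0`` may be a single 4-vector or a (batch, 4) array.  The sequence
    starts at the current state and spans the lookahead, clamped to the
    policy's horizon.
    """
    X = np.atleast_2d(np.asarray(x0, float))
    n = min(int(n_steps), policy.horizon)
    M = closed_loop_matrices(plant, policy)
    Z = X - policy.goal_offset[None, :]
    out = np.empty((n, Z.shape[0], 4))
    for t in range(n):
        out[t] = Z + policy.goal_offset[None, :]
        Z = Z @ M[t].T
    return out


def trajectory_collision_probability(
    plant: PlantModel,
    policy: FeedbackPolicy,
    state: State,
    zone: CollisionZone,
    spec: RolloutSpec = RolloutSpec(),
) -> float:
    """Mean collision indicator over an N-step noise-free rollout of ``policy``."""
    traj = rollout_states(plant, policy, state.vector(), spec.n_steps)[:, 0, :]
    ind = _indicator_batch(traj[:, :2], traj[:, 2:], zone)
    return float(np.mean(ind))
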