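"""State-space cartography: action-cost, desirability and collision-risk maps.

Projects the 4-D (position x velocity) desirability landscape onto the task
plane with the circular-sampling convention: every probed state gets a
velocity pointing radially outward from the movement origin through the
probed position, at the speed of an unobstructed optimal reach at a fixed
completion fraction.  Two renderings are supported:

* ``action_only``  — desirabilities from the action-cost softmax alone
  (goods terms = 1).  Target and obstacle compete in one pooled softmax, so
  the two fields sum to 1 everywhere; this is the rendering that exposes the
  "anti-target" artifact (avoidance maximally desirable near the obstacle).
* ``comprehensive`` — additionally estimates the rollout collision
  probability at every state and folds it into the goods terms, carving the
  collision cones out of the target-desirability field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .collision import RolloutSpec, _indicator_batch, rollout_states
from .desirability import Scene, mixture_weights, DegenerateSceneError
from .plant import PlantModel, State, make_point_mass_plant, step as plant_step
from .policies import (
    ControlConfig,
    DEFAULT_CONTROL,
    synthesize_obstacle_policy,
    synthesize_target_policy,
    time_to_contact,
)
__all__ = [
    "MapGrid",
    "circular_sampling_states",
    "reference_speed",
    "compute_map",
    "export_map",
]


@dataclass
class MapGrid:
    """Gridded scalar fields plus the circular sample states and vector field."""

    extent: tuple[float, float, float, float]   # xmin, xmax, ymin, ymax
    resolution: int
    xs: np.ndarray
    ys: np.ndarray
    sample_states: list[State]
    fields: dict[str, np.ndarray]               # each (resolution, resolution)
    vectors: np.ndarray                         # (resolution, resolution, 2)
    meta: dict = field(default_factory=dict)


def reference_speed(
    plant: PlantModel,
    origin,
    target,
    completion_fraction: float = 0.75,
    control_config: ControlConfig = DEFAULT_CONTROL,
) -> float:
    """Speed of the unobstructed zero-noise optimal reach at a path fraction.

    Simulates the single-target reach deterministically and reads the speed
    at the state where the travelled arc length first reaches the fraction.
    """
    if not 0.0 < completion_fraction <= 1.0:
        raise ValueError("completion_fraction must lie in (0, 1]")
    origin = np.asarray(origin, float)
    target = np.asarray(target, float)
    if np.linalg.norm(target - origin) == 0.0:
        raise ValueError("degenerate zero-length reach")
    from .policies import Goal

    noiseless = make_point_mass_plant(
        dt=plant.dt, damping=plant.damping, additive_noise=0.0, sdn_scale=0.0
    )
    start = State(position=origin, velocity=np.zeros(2))
    horizon = time_to_contact(start, target, noiseless.dt, control_config)
    pol = synthesize_target_policy(noiseless, Goal(position=tuple(target)), horizon, control_config)
    x = start.vector()
    traj = [x]
    for t in range(horizon):  # include the terminal state, where the hand stops
        x = noiseless.A @ x + noiseless.B @ pol.control(x, t)
        traj.append(x)
    traj = np.asarray(traj)
    pos = traj[:, :2]
    vel = traj[:, 2:]
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_target = completion_fraction * s[-1]
    idx = int(np.searchsorted(s, s_target))
    idx = min(idx, len(vel) - 1)
    return float(np.linalg.norm(vel[idx]))


def circular_sampling_states(
    origin,
    target,
    fraction: float = 0.75,
    n: int = 359,
    speed: float = 1.0,
) -> list[State]:
    """States on a target-centred circle with radially-outward velocities.

    The circle's radius is ``fraction`` of the origin-to-target distance;
    the ``n`` positions are evenly spaced in angle.  Each velocity points
    outward from the origin through the position, all at the same speed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    origin = np.asarray(origin, float)
    target = np.asarray(target, float)
    radius = fraction * float(np.linalg.norm(target - origin))
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    states = []
    for th in angles:
        pos = target + radius * np.array([np.cos(th), np.sin(th)])
        ray = pos - origin
        nrm = np.linalg.norm(ray)
        direction = ray / nrm if nrm > 0 else np.zeros(2)
        states.append(State(position=pos, velocity=speed * direction, t=0))
    return states


def _radial_velocities(positions: np.ndarray, origin, speed: float) -> np.ndarray:
    rays = positions - np.asarray(origin, float)[None, :]
    nrm = np.linalg.norm(rays, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(nrm > 0, rays / np.maximum(nrm, 1e-300), 0.0)
    return speed * dirs


def compute_map(
    scene: Scene,
    extent: tuple[float, float, float, float] = (-10.0, 50.0, -10.0, 50.0),
    resolution: int = 101,
    mode: str = "comprehensive",
    trials_per_state: int = 1,
    plant: PlantModel | None = None,
    control_config: ControlConfig = DEFAULT_CONTROL,
    rollout_spec: RolloutSpec = RolloutSpec(),
    seed: int = 0,
    n_samples: int = 359,
) -> MapGrid:
    """Build the gridded desirability landscape of a scene.

    Every grid state carries the circular-sampling velocity convention.
    Action components pool all target and obstacle costs into one softmax
    (cross-option competition); in ``comprehensive`` mode the rollout
    collision probability multiplies the goods terms.  ``trials_per_state``
    > 1 adds execution noise to the risk rollouts and averages (seeded);
    the default single rollout is noise-free.
    """
    if mode not in ("action_only", "comprehensive"):
        raise ValueError("mode must be 'action_only' or 'comprehensive'")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if trials_per_state < 1:
        raise ValueError("trials_per_state must be >= 1")
    if plant is None:
        plant = make_point_mass_plant()
    if not scene.goals or not scene.obstacles:
        raise ValueError("the map needs at least one goal and one obstacle")

    xmin, xmax, ymin, ymax = extent
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    XX, YY = np.meshgrid(xs, ys, indexing="xy")
    positions = np.column_stack([XX.ravel(), YY.ravel()])
    n_states = positions.shape[0]

    goal0 = scene.goals[0]
    speed = reference_speed(plant, scene.start, goal0.position, 0.75, control_config)
    velocities = _radial_velocities(positions, scene.start, speed)
    X = np.hstack([positions, velocities])
    zones = [ob.zone for ob in scene.obstacles]

    N, M = scene.n_goals, scene.n_obstacles
    cost_t = np.empty((n_states, N))
    cost_o = np.empty((n_states, M))
    risk = np.zeros((n_states, N, M))
    u_t = np.empty((n_states, N, 2))
    u_o = np.empty((n_states, M, 2))

    rng = np.random.default_rng(seed)
    seeds_used = [int(seed)]

    def _grouped(goal_xy):
        d = np.linalg.norm(positions - np.asarray(goal_xy, float)[None, :], axis=1)
        hs = np.clip(
            np.round(d / (control_config.v_ref * plant.dt)),
            control_config.t_min,
            control_config.t_max,
        ).astype(int)
        for h in np.unique(hs):
            yield int(h), np.where(hs == h)[0]

    for j, g in enumerate(scene.goals):
        for h, idx in _grouped(g.position):
            pol = synthesize_target_policy(plant, g, h, control_config)
            Z = X[idx] - pol.goal_offset[None, :]
            cost_t[idx, j] = np.einsum("bi,ij,bj->b", Z, pol.value[0], Z)
            u_t[idx, j] = -(Z @ pol.gains[0].T)
            if mode == "comprehensive":
                risk[idx, j, :] += _risk_group(
                    plant, pol, X[idx], zones, rollout_spec, trials_per_state, rng
                )

    for k, ob in enumerate(scene.obstacles):
        for h, idx in _grouped(ob.goal.position):
            pol = synthesize_obstacle_policy(plant, ob.goal, h, control_config)
            Z = X[idx] - pol.goal_offset[None, :]
            cost_o[idx, k] = np.einsum("bi,ij,bj->b", Z, pol.value[0], Z)
            u_o[idx, k] = +(Z @ pol.gains[0].T)  # negated avoidance control

    # pooled cross-option softmax (targets and obstacles compete directly)
    costs = np.hstack([cost_t, cost_o])
    a = -costs / scene.lam
    a -= a.max(axis=1, keepdims=True)
    w = np.exp(a)
    w /= w.sum(axis=1, keepdims=True)
    act_t, act_o = w[:, :N], w[:, N:]

    if mode == "comprehensive":
        p_target = risk.max(axis=2)
        p_obstacle = risk.max(axis=1)
        rewards = np.array([g.reward_probability for g in scene.goals])
        v_t = act_t * (1.0 - p_target) * rewards[None, :]
        v_o = act_o * p_obstacle
        p_field = p_obstacle.max(axis=1)
    else:
        v_t = act_t
        v_o = act_o
        p_field = np.zeros(n_states)

    vectors = np.zeros((n_states, 2))
    for i in range(n_states):
        try:
            wt, wo = mixture_weights(v_t[i], v_o[i], scene.alpha)
        except DegenerateSceneError:
            continue
        u = (wt[:, None] * u_t[i]).sum(axis=0) + (wo[:, None] * u_o[i]).sum(axis=0)
        nrm = np.linalg.norm(u)
        if nrm > 0:
            vectors[i] = u / nrm

    shape = (resolution, resolution)
    fields = {
        "cost_target": cost_t.min(axis=1).reshape(shape),
        "cost_obstacle": cost_o.min(axis=1).reshape(shape),
        "v_target": v_t.sum(axis=1).reshape(shape),
        "v_obstacle": v_o.sum(axis=1).reshape(shape),
        "p_collision": p_field.reshape(shape),
    }
    samples = circular_sampling_states(scene.start, goal0.position, 0.75, n_samples, speed)
    return MapGrid(
        extent=extent,
        resolution=resolution,
        xs=xs,
        ys=ys,
        sample_states=samples,
        fields=fields,
        vectors=vectors.reshape(resolution, resolution, 2),
        meta={
            "mode": mode,
            "alpha": scene.alpha,
            "lam": scene.lam,
            "seeds": seeds_used,
            "trials_per_state": trials_per_state,
            "reference_speed": speed,
            "scene": {
                "start": list(scene.start),
                "goals": [list(g.position) for g in scene.goals],
                "obstacles": [
                    {
                        "center": list(ob.zone.center),
                        "d_inner": ob.zone.d_inner,
                        "d_outer": ob.zone.d_outer,
                    }
                    for ob in scene.obstacles
                ],
            },
        },
    )


def _risk_group(plant, policy, X, zones, spec, trials, rng):
    """Collision probability per state/zone, optionally noise-averaged."""
    n = X.shape[0]
    out = np.zeros((n, len(zones)))
    if trials == 1 or plant.signal_dependent_noise_scale == 0.0:
        traj = rollout_states(plant, policy, X, spec.n_steps)
        T = traj.shape[0]
        flat = traj.reshape(T * n, 4)
        for k, zone in enumerate(zones):
            out[:, k] = _indicator_batch(flat[:, :2], flat[:, 2:], zone).reshape(T, n).mean(axis=0)
        return out
    for _ in range(trials):
        for i in range(n):
            st = State.from_vector(X[i])
            traj = [st.vector()]
            for t in range(min(spec.n_steps, policy.horizon) - 1):
                u = policy.control(traj[-1], t)
                st = plant_step(plant, State.from_vector(traj[-1], t=t), u, rng=rng)
                traj.append(st.vector())
            arr = np.array(traj)
            for k, zone in enumerate(zones):
                out[i, k] += _indicator_batch(arr[:, :2], arr[:, 2:], zone).mean()
    return out / trials


def export_map(grid: MapGrid, out_dir) -> list[Path]:
    """Write fields as CSV, render heat maps and the quiver plot, and drop a
    JSON sidecar with the scene, mode, alpha/lambda and seeds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not grid.fields:
        raise ValueError("map has no fields to export")
    written: list[Path] = []
    for name, arr in grid.fields.items():
        if arr.size == 0:
            raise ValueError(f"field {name!r} is empty")
        p = out_dir / f"{name}.csv"
        np.savetxt(p, arr, delimiter=",", fmt="%.17g")
        written.append(p)
        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(
            arr, origin="lower", extent=grid.extent, aspect="equal", cmap="viridis"
        )
        fig.colorbar(im, ax=ax, label=name)
        ax.set_xlabel("x (task units)")
        ax.set_ylabel("y (task units)")
        ax.set_title(name)
        fig.savefig(out_dir / f"{name}.png", dpi=120)
        plt.close(fig)
        written.append(out_dir / f"{name}.png")
    for comp, name in ((0, "vectors_x"), (1, "vectors_y")):
        p = out_dir / f"{name}.csv"
        np.savetxt(p, grid.vectors[:, :, comp], delimiter=",", fmt="%.17g")
        written.append(p)
    stride = max(1, grid.resolution // 25)
    fig, ax = plt.subplots(figsize=(5, 4.6))
    XX, YY = np.meshgrid(grid.xs, grid.ys, indexing="xy")
    ax.quiver(
        XX[::stride, ::stride],
        YY[::stride, ::stride],
        grid.vectors[::stride, ::stride, 0],
        grid.vectors[::stride, ::stride, 1],
        angles="xy",
    )
    ax.set_aspect("equal")
    ax.set_title("preferred direction (mixed policy)")
    fig.savefig(out_dir / "vectors.png", dpi=120)
    plt.close(fig)
    written.append(out_dir / "vectors.png")
    sidecar = out_dir / "map_meta.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "extent": list(grid.extent),
                "resolution": grid.resolution,
                **grid.meta,
            },
            fh,
            indent=2,
        )
    written.append(sidecar)
    return written
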