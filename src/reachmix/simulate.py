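"""Closed-loop trial execution of the desirability-weighted policy mixture.

Each step the simulator refreshes every option's planning horizon
(time-to-contact), fetches the cached LQG policy, evaluates the full
desirability breakdown at the current state, and applies the mixed command

    u = sum_j w_j^G u_j^G  +  sum_k w_k^O u_k^O

(obstacle controls already negated), then steps the noisy plant.  Trials end
at target attainment, optionally at collision, or at the step cap.  Multi-
trial experiments reproduce the obstacle-size ladder, the lateral-obstacle
conditions, and the mid-flight target-jump scenario, with kinematic
summaries (arc-length-resampled mean paths, SE bands, collision rates,
signed lateral deviations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .collision import CollisionZone, RolloutSpec
from .desirability import (
    DesirabilityBreakdown,
    Obstacle,
    Scene,
    build_policies,
    evaluate_scene,
)
from .plant import PlantModel, State, make_point_mass_plant, step
from .policies import ControlConfig, DEFAULT_CONTROL, Goal, ObstacleGoal

__all__ = [
    "SimConfig",
    "Trajectory",
    "ExperimentResult",
    "TargetJump",
    "simulate_trial",
    "apply_target_jump",
    "run_experiment",
    "preset_conditions",
    "reflect_scene_across_diagonal",
    "resample_path",
    "lateral_deviation",
]

N_RESAMPLE = 100  # points per arc-length-resampled path


@dataclass(frozen=True)
class TargetJump:
    """A mid-flight target displacement: at ``step`` the goal moves."""

    step: int
    new_position: tuple[float, float]
    goal_index: int = 0

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("jump step must be >= 0")
        object.__setattr__(self, "new_position", tuple(float(c) for c in self.new_position))


def apply_target_jump(scene: Scene, step: int, new_position, goal_index: int = 0) -> TargetJump:
    """Schedule a target jump on the scene; returns the recorded event.

    Multiple jumps are allowed; two jumps of the same goal at the same step
    are rejected as ambiguous.
    """
    if goal_index >= scene.n_goals:
        raise ValueError("goal_index out of range")
    for j in scene.jumps:
        if j.step == step and j.goal_index == goal_index:
            raise ValueError(f"a jump for goal {goal_index} at step {step} is already scheduled")
    ev = TargetJump(step=int(step), new_position=new_position, goal_index=goal_index)
    scene.jumps.append(ev)
    return ev


@dataclass(frozen=True)
class SimConfig:
    """Trial-execution parameters.

    Attainment is 'within target_tolerance task units of a goal and slower
    than speed_tolerance units/s'.  Collisions (hand inside an obstacle's
    physical radius) are logged; the trial continues unless
    stop_on_collision is set.
    """

    max_steps: int = 600
    target_tolerance: float = 1.0
    speed_tolerance: float = 1.0
    stop_on_collision: bool = False
    control: ControlConfig = DEFAULT_CONTROL
    rollout: RolloutSpec = RolloutSpec()


DEFAULT_SIM = SimConfig()


@dataclass
class Trajectory:
    """One executed trial: states, controls, per-step breakdowns and events."""

    states: list[State]
    controls: np.ndarray                 # (T, 2)
    breakdowns: list[DesirabilityBreakdown]
    events: list[tuple[int, str, object]]
    collided: bool
    collision_step: int | None
    reached_target: bool
    scene: Scene | None = None

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.states])

    def velocities(self) -> np.ndarray:
        return np.array([s.velocity for s in self.states])

    def path_length(self) -> float:
        p = self.positions()
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _current_goals(scene: Scene, t: int) -> list[Goal]:
    """Goal list with every jump scheduled at or before step t applied."""
    goals = list(scene.goals)
    for ev in sorted(scene.jumps, key=lambda e: e.step):
        if ev.step <= t and ev.goal_index < len(goals):
            goals[ev.goal_index] = replace(goals[ev.goal_index], position=ev.new_position)
    return goals


def simulate_trial(
    scene: Scene,
    plant: PlantModel | None = None,
    config: SimConfig = DEFAULT_SIM,
    seed: int | None = None,
    mirror_noise: bool = False,
) -> Trajectory:
    """Run one closed-loop trial; a fixed seed reproduces it bit-for-bit."""
    if plant is None:
        plant = make_point_mass_plant()
    rng = np.random.default_rng(seed)
    state = State(position=np.asarray(scene.start, float), velocity=np.zeros(2), t=0)
    states = [state]
    controls: list[np.ndarray] = []
    breakdowns: list[DesirabilityBreakdown] = []
    events: list[tuple[int, str, object]] = []
    collided = False
    collision_step: int | None = None
    reached = False
    jumps_fired: set[int] = set()

    for t in range(config.max_steps):
        goals_now = _current_goals(scene, t)
        for i, ev in enumerate(scene.jumps):
            if ev.step == t and i not in jumps_fired:
                events.append((t, "target_jump", ev))
                jumps_fired.add(i)
        scene_now = replace_goals(scene, goals_now)
        policies = build_policies(scene_now, state, plant, config.control)
        bd = evaluate_scene(
            scene_now, state, plant,
            policies=policies,
            control_config=config.control,
            rollout_spec=config.rollout,
            on_degenerate="fallback",
        )
        if bd.degenerate and not any(e[1] == "degenerate_weights" for e in events):
            events.append((t, "degenerate_weights", None))
        tp, op = policies
        u = np.zeros(2)
        for w, pol in zip(bd.weights_target, tp):
            u += w * pol.control(state)
        for w, pol in zip(bd.weights_obstacle, op):
            u += w * pol.control(state)
        controls.append(u)
        breakdowns.append(bd)
        state = step(plant, state, u, rng=rng, mirror_noise=mirror_noise)
        states.append(state)

        if not collided:
            for ob in scene.obstacles:
                if np.linalg.norm(state.position - np.asarray(ob.zone.center)) <= ob.zone.r_inner:
                    collided = True
                    collision_step = state.t
                    events.append((state.t, "collision", ob.zone.center))
                    break
        if collided and config.stop_on_collision:
            break
        for g in goals_now:
            if (
                np.linalg.norm(state.position - np.asarray(g.position)) <= config.target_tolerance
                and state.speed < config.speed_tolerance
            ):
                reached = True
                events.append((state.t, "target_reached", g.position))
                break
        if reached:
            break
    else:
        events.append((config.max_steps, "step_cap", None))

    events.sort(key=lambda e: e[0])
    return Trajectory(
        states=states,
        controls=np.array(controls).reshape(-1, 2),
        breakdowns=breakdowns,
        events=events,
        collided=collided,
        collision_step=collision_step,
        reached_target=reached,
        scene=scene,
    )


def replace_goals(scene: Scene, goals: list[Goal]) -> Scene:
    """Shallow scene copy with a new goal list (shares obstacles/jumps)."""
    out = Scene.__new__(Scene)
    out.goals = goals
    out.obstacles = scene.obstacles
    out.alpha = scene.alpha
    out.lam = scene.lam
    out.start = scene.start
    out.mode = scene.mode
    out.jumps = []
    return out


# ---------------------------------------------------------------------------
# Kinematic summaries
# ---------------------------------------------------------------------------

def resample_path(positions: np.ndarray, n: int = N_RESAMPLE) -> np.ndarray:
    """Resample a polyline to n points equally spaced in arc length."""
    positions = np.asarray(positions, float)
    seg = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(positions[:1], n, axis=0)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, positions[:, i]) for i in range(2)])


def lateral_deviation(positions: np.ndarray, start, goal) -> np.ndarray:
    """Signed perpendicular distance of each point from the start->goal chord.

    Positive is to the left of the chord direction.
    """
    start = np.asarray(start, float)
    goal = np.asarray(goal, float)
    u = goal - start
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate chord")
    u = u / norm
    nhat = np.array([-u[1], u[0]])
    return (np.asarray(positions, float) - start) @ nhat


@dataclass
class ExperimentResult:
    """Multi-trial summary for one experimental condition."""

    trajectories: list[Trajectory]
    mean_path: np.ndarray                # (N_RESAMPLE, 2), main (non-curved) subset
    se_path: np.ndarray                  # (N_RESAMPLE, 2); NaN when < 2 trials
    collision_rate: float
    max_lateral_deviation: np.ndarray    # per-trial signed extremum
    initial_deviation_sign: np.ndarray   # chord side at 25% of path, per trial
    curved_mask: np.ndarray              # trials that curved around the obstacle
    mean_path_curved: np.ndarray | None = None
    se_path_curved: np.ndarray | None = None
    se_defined: bool = True


def _curved_around(traj: Trajectory, scene: Scene, start, goal) -> bool:
    """Fig.-5 partition rule: approached within the outer zone, then crossed
    the chord.  Config-light; scenes without obstacles have no curved trials."""
    if not scene.obstacles:
        return False
    pos = traj.positions()
    dev = lateral_deviation(pos, start, goal)
    for ob in scene.obstacles:
        dist = np.linalg.norm(pos - np.asarray(ob.zone.center), axis=1)
        close = np.where(dist <= ob.zone.r_outer)[0]
        if close.size == 0:
            continue
        first = close[0]
        after = dev[first:]
        if after.size > 1 and np.any(np.sign(after[1:]) * np.sign(dev[first]) < 0):
            return True
    return False


def summarize_condition(
    trajectories: list[Trajectory],
    scene: Scene,
    goal_position=None,
) -> ExperimentResult:
    """Aggregate trials of one condition into the standard summary."""
    start = np.asarray(scene.start, float)
    goal = np.asarray(goal_position if goal_position is not None else scene.goals[0].position, float)
    n = len(trajectories)
    paths = np.stack([resample_path(tr.positions()) for tr in trajectories])
    devs = np.stack([lateral_deviation(p, start, goal) for p in paths])
    idx_ext = np.argmax(np.abs(devs), axis=1)
    max_dev = devs[np.arange(n), idx_ext]
    init_sign = np.sign(devs[:, N_RESAMPLE // 4])
    init_sign[init_sign == 0] = 1.0
    curved = np.array([_curved_around(tr, scene, start, goal) for tr in trajectories])
    main = paths[~curved] if (~curved).any() else paths
    mean_path = main.mean(axis=0)
    se_defined = main.shape[0] >= 2
    se_path = (
        main.std(axis=0, ddof=1) / np.sqrt(main.shape[0])
        if se_defined
        else np.full_like(mean_path, np.nan)
    )
    mean_c = se_c = None
    if curved.any():
        sub = paths[curved]
        mean_c = sub.mean(axis=0)
        se_c = (
            sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
            if sub.shape[0] >= 2
            else np.full_like(mean_path, np.nan)
        )
    return ExperimentResult(
        trajectories=trajectories,
        mean_path=mean_path,
        se_path=se_path,
        collision_rate=float(np.mean([tr.collided for tr in trajectories])),
        max_lateral_deviation=max_dev,
        initial_deviation_sign=init_sign,
        curved_mask=curved,
        mean_path_curved=mean_c,
        se_path_curved=se_c,
        se_defined=se_defined,
    )


# ---------------------------------------------------------------------------
# Presets mirroring the published experiments
# ---------------------------------------------------------------------------

_START = (0.0, 0.0)
_TARGET = (30.0, 30.0)
_MID = (15.0, 15.0)
#: obstacle-size ladder (inner diameters; outer = 2 x inner), chord midpoint
FIG4_DIAMETERS = {"none": 0.0, "small": 4.0, "medium": 8.0, "large": 12.0}
FIG5_LATERAL_OFFSET = 4.0
FIG6_JUMP_FRACTION = 0.4


def _canonical_scene(alpha: float, lam: float, obstacles: list[Obstacle]) -> Scene:
    return Scene(
        goals=[Goal(position=_TARGET)],
        obstacles=obstacles,
        alpha=alpha,
        lam=lam,
        start=_START,
    )


def _obstacle_at(center, d_inner=4.0, d_outer=None) -> Obstacle:
    if d_outer is None:
        d_outer = 2.0 * d_inner
    return Obstacle(
        goal=ObstacleGoal(position=tuple(center)),
        zone=CollisionZone(center=tuple(center), d_inner=d_inner, d_outer=d_outer),
    )


def preset_conditions(preset: str, alpha: float = 0.1, lam: float = 1.0):
    """Scene list for a named experiment preset.

    Returns [(condition_name, scene)]; target-jump events for 'fig6' are
    already scheduled on the returned scenes.
    """
    if preset == "fig4":
        conds = []
        for name, d in FIG4_DIAMETERS.items():
            obstacles = [] if d == 0.0 else [_obstacle_at(_MID, d_inner=d)]
            conds.append((name, _canonical_scene(alpha, lam, obstacles)))
        return conds
    if preset == "fig5":
        u = np.array(_TARGET) - np.array(_START)
        u = u / np.linalg.norm(u)
        nhat = np.array([-u[1], u[0]])  # left of the chord
        conds = []
        for name, s in (("left", +1.0), ("right", -1.0)):
            center = np.array(_MID) + s * FIG5_LATERAL_OFFSET * nhat
            conds.append((name, _canonical_scene(alpha, lam, [_obstacle_at(center)])))
        return conds
    if preset == "fig6":
        # jump at 40% of the nominal (1 s / dt=0.01 -> 100-step) movement
        jump_step = int(round(FIG6_JUMP_FRACTION * 100))
        u = np.array(_TARGET) - np.array(_START)
        u = u / np.linalg.norm(u)
        nhat = np.array([-u[1], u[0]])
        new_target = tuple(np.array(_TARGET) - 10.0 * nhat)  # lateral displacement
        hand_at_jump = FIG6_JUMP_FRACTION * np.array(_TARGET)
        mid_new = 0.5 * (hand_at_jump + np.array(new_target))
        conds = []
        for name, obstacles in (
            ("no_obstacle", []),
            ("blocking", [_obstacle_at(mid_new)]),
            ("nearby", [_obstacle_at(mid_new + 4.0 * nhat)]),
        ):
            sc = _canonical_scene(alpha, lam, obstacles)
            apply_target_jump(sc, jump_step, new_target)
            conds.append((name, sc))
        return conds
    raise ValueError(f"unknown preset {preset!r}")


def trial_seed(experiment_seed: int, condition_index: int, trial_index: int) -> np.random.SeedSequence:
    """Counter-based per-trial seed so conditions pair trial-by-trial."""
    return np.random.SeedSequence(entropy=experiment_seed, spawn_key=(condition_index, trial_index))


def run_experiment(
    preset,
    n_trials: int = 20,
    seed: int = 0,
    plant: PlantModel | None = None,
    config: SimConfig = DEFAULT_SIM,
    alpha: float = 0.1,
    lam: float = 1.0,
) -> dict[str, ExperimentResult]:
    """Run a preset (or custom [(name, scene)] list); returns per-condition results."""
    if isinstance(preset, str):
        conds = preset_conditions(preset, alpha=alpha, lam=lam)
    else:
        conds = list(preset)
    if plant is None:
        plant = make_point_mass_plant()
    out: dict[str, ExperimentResult] = {}
    for ci, (name, scene) in enumerate(conds):
        trs = []
        for ti in range(n_trials):
            rng_seed = trial_seed(seed, ci, ti)
            trs.append(simulate_trial(scene, plant, config, seed=rng_seed))
        goal0 = _current_goals(scene, 0)[0].position
        out[name] = summarize_condition(trs, scene, goal_position=goal0)
    return out


def reflect_scene_across_diagonal(scene: Scene) -> Scene:
    """Mirror a scene across the y = x line (the canonical chord).

    Together with mirror_noise in simulate_trial this produces the exactly
    reflected trajectory of the unmirrored run with the same seed.
    """
    def swap(p):
        return (p[1], p[0])

    goals = [replace(g, position=swap(g.position)) for g in scene.goals]
    obstacles = [
        Obstacle(
            goal=replace(ob.goal, position=swap(ob.goal.position)),
            zone=CollisionZone(
                center=swap(ob.zone.center),
                d_inner=ob.zone.d_inner,
                d_outer=ob.zone.d_outer,
            ),
        )
        for ob in scene.obstacles
    ]
    out = Scene(
        goals=goals,
        obstacles=obstacles,
        alpha=scene.alpha,
        lam=scene.lam,
        start=swap(scene.start),
        mode=scene.mode,
    )
    out.jumps = [replace(j, new_position=swap(j.new_position)) for j in scene.jumps]
    return out
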