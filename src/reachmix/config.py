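"""Run configuration: schema, validation, defaults, and scene construction.

Configs are structured text (YAML; JSON is a YAML subset) with named blocks
— scene, plant, control, collision, experiment, output.  Validation is
strict: unknown keys are rejected with their dotted path, alpha must lie in
[0, 1] and lambda must be positive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .collision import CollisionZone, RolloutSpec
from .desirability import Obstacle, Scene
from .plant import PlantModel, make_point_mass_plant
from .policies import ControlConfig, Goal, ObstacleGoal
from .simulate import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "canonical_fixture_path"]

log = logging.getLogger("reachmix")

_CANONICAL_V_REF = float((30.0**2 + 30.0**2) ** 0.5)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GoalBlock(_Strict):
    position: tuple[float, float]
    reward_probability: float = Field(default=1.0, ge=0.0, le=1.0)
    terminal_position_weight: float = Field(default=1e4, gt=0.0)
    terminal_velocity_weight: float = Field(default=1e4, ge=0.0)


class ObstacleBlock(_Strict):
    position: tuple[float, float]
    d_inner: float = Field(default=4.0, gt=0.0)
    d_outer: float = Field(default=8.0, gt=0.0)
    terminal_position_weight: float = Field(default=1e4, gt=0.0)


class SceneBlock(_Strict):
    start: tuple[float, float] = (0.0, 0.0)
    goals: list[GoalBlock] = Field(default_factory=list)
    obstacles: list[ObstacleBlock] = Field(default_factory=list)
    alpha: float = Field(default=0.1, ge=0.0, le=1.0)
    lam: float = Field(default=1.0, gt=0.0)
    mode: Literal["cluttered", "obstacle_free"] = "cluttered"


class PlantBlock(_Strict):
    dt: float = Field(default=0.01, gt=0.0)
    damping: float = Field(default=0.1, ge=0.0)
    additive_noise: float = Field(default=0.0, ge=0.0)
    sdn_scale: float = Field(default=0.2, ge=0.0)


class ControlBlock(_Strict):
    r: float = Field(default=1e-4, gt=0.0)
    v_ref: float = Field(default=_CANONICAL_V_REF, gt=0.0)
    t_min: int = Field(default=10, ge=1)
    t_max: int = Field(default=500, ge=1)


class CollisionBlock(_Strict):
    n_lookahead: int = Field(default=50, ge=1)


class ExperimentBlock(_Strict):
    preset: Literal["fig4", "fig5", "fig6", "custom"] = "custom"
    n_trials: int = Field(default=20, ge=1)
    seed: int = 0
    max_steps: int = Field(default=600, ge=1)
    target_tolerance: float = Field(default=1.0, gt=0.0)
    speed_tolerance: float = Field(default=1.0, gt=0.0)
    stop_on_collision: bool = False


class OutputBlock(_Strict):
    directory: str = "runs"
    formats: list[Literal["csv", "json", "png", "svg"]] = Field(
        default_factory=lambda: ["csv", "json", "png"]
    )


class RunConfig(_Strict):
    """Validated top-level configuration with defaults applied."""

    scene: SceneBlock = Field(default_factory=SceneBlock)
    plant: PlantBlock = Field(default_factory=PlantBlock)
    control: ControlBlock = Field(default_factory=ControlBlock)
    collision: CollisionBlock = Field(default_factory=CollisionBlock)
    experiment: ExperimentBlock = Field(default_factory=ExperimentBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    def build_scene(self) -> Scene:
        s = self.scene
        return Scene(
            goals=[
                Goal(
                    position=g.position,
                    reward_probability=g.reward_probability,
                    terminal_position_weight=g.terminal_position_weight,
                    terminal_velocity_weight=g.terminal_velocity_weight,
                )
                for g in s.goals
            ],
            obstacles=[
                Obstacle(
                    goal=ObstacleGoal(
                        position=o.position,
                        terminal_position_weight=o.terminal_position_weight,
                    ),
                    zone=CollisionZone(center=o.position, d_inner=o.d_inner, d_outer=o.d_outer),
                )
                for o in s.obstacles
            ],
            alpha=s.alpha,
            lam=s.lam,
            start=s.start,
            mode=s.mode,
        )

    def build_plant(self) -> PlantModel:
        p = self.plant
        return make_point_mass_plant(
            dt=p.dt, damping=p.damping, additive_noise=p.additive_noise, sdn_scale=p.sdn_scale
        )

    def build_control(self) -> ControlConfig:
        c = self.control
        return ControlConfig(r=c.r, v_ref=c.v_ref, t_min=c.t_min, t_max=c.t_max)

    def build_sim(self) -> SimConfig:
        e = self.experiment
        return SimConfig(
            max_steps=e.max_steps,
            target_tolerance=e.target_tolerance,
            speed_tolerance=e.speed_tolerance,
            stop_on_collision=e.stop_on_collision,
            control=self.build_control(),
            rollout=RolloutSpec(n_steps=self.collision.n_lookahead),
        )


class ConfigError(ValueError):
    """Schema violation, reported with dotted key paths."""


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"])
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file; defaults are logged."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {_format_errors(exc)}") from exc
    for key, value in cfg.model_dump().items():
        if key not in raw:
            log.debug("config default applied: %s = %r", key, value)
    if cfg.scene.goals or cfg.scene.obstacles:
        cfg.build_scene()  # surface Scene-level invariant violations early
    return cfg


def canonical_fixture_path() -> Path:
    """Path of the packaged canonical scene (start (0,0), target (30,30),
    obstacle (15,15))."""
    from importlib.resources import files

    return Path(str(files("reachmix") / "fixtures" / "canonical.yaml"))
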