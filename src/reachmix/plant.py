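"""Discrete-time point-mass hand plant with signal-dependent motor noise.

The hand is modelled as a unit point mass in the 2-D task plane, Euler
discretised at step ``dt``:

    position <- position + velocity * dt
    velocity <- velocity + (u - damping * velocity) * dt

The motor command ``u`` is corrupted multiplicatively (signal-dependent
noise, the hallmark of biological motor output) and optionally by a small
additive term:

    u_applied = u * (1 + sdn_scale * eps),   eps ~ N(0, I) per component

so noise vanishes at rest and grows with command magnitude.  With both
noise scales at zero the plant is a deterministic linear system
``x' = A x + B u``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["State", "PlantModel", "Control", "make_point_mass_plant", "step"]

#: A motor command: finite real 2-vector (task units / s^2 for a unit mass).
Control = np.ndarray


@dataclass
class State:
    """Hand state: planar position, velocity and the integer time index."""

    position: np.ndarray
    velocity: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2)
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.velocity))):
            raise ValueError("state position/velocity must be finite")
        if self.t < 0:
            raise ValueError("time index must be >= 0")

    def vector(self) -> np.ndarray:
        """Stacked state vector [px, py, vx, vy]."""
        return np.concatenate([self.position, self.velocity])

    @classmethod
    def from_vector(cls, x: np.ndarray, t: int = 0) -> "State":
        x = np.asarray(x, dtype=float).reshape(4)
        return cls(position=x[:2], velocity=x[2:], t=t)

    @property
    def speed(self) -> float:
        return float(np.linalg.norm(self.velocity))


@dataclass(frozen=True)
class PlantModel:
    """Linear plant ``x' = A x + B u`` plus its noise parameters."""

    A: np.ndarray
    B: np.ndarray
    dt: float
    additive_noise_scale: float = 0.0
    signal_dependent_noise_scale: float = 0.0
    damping: float = 0.0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.shape != (4, 4) or B.shape != (4, 2):
            raise ValueError("expected A (4,4) and B (4,2) for the planar point mass")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.additive_noise_scale < 0 or self.signal_dependent_noise_scale < 0:
            raise ValueError("noise scales must be >= 0")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    def key(self) -> tuple:
        """Hashable identity of the deterministic part (used for gain caching)."""
        return (self.A.tobytes(), self.B.tobytes(), self.dt)


def make_point_mass_plant(
    dt: float = 0.01,
    damping: float = 0.1,
    additive_noise: float = 0.0,
    sdn_scale: float = 0.2,
) -> PlantModel:
    """Build the Euler-discretised planar point-mass plant.

    Parameters
    ----------
    dt:
        Step duration in seconds; must be positive.
    damping:
        Viscous damping coefficient (1/s) on the velocity, >= 0.
    additive_noise:
        Standard deviation of additive per-step velocity noise (units/s).
    sdn_scale:
        Unitless multiplier of the signal-dependent (control-multiplicative)
        noise; 0 disables it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if damping < 0:
        raise ValueError("damping must be >= 0")
    eye = np.eye(2)
    A = np.block([[eye, dt * eye], [np.zeros((2, 2)), (1.0 - damping * dt) * eye]])
    B = np.vstack([np.zeros((2, 2)), dt * eye])
    return PlantModel(
        A=A,
        B=B,
        dt=dt,
        additive_noise_scale=float(additive_noise),
        signal_dependent_noise_scale=float(sdn_scale),
        damping=float(damping),
    )


def step(
    plant: PlantModel,
    state: State,
    u: Control,
    rng: np.random.Generator | None = None,
    mirror_noise: bool = False,
) -> State:
    """Advance the plant one step under command ``u``.

    With both noise scales zero the update is the exact deterministic
    ``A x + B u`` map.  Otherwise ``rng`` must be supplied; a fixed seed
    reproduces the trajectory bit-for-bit.  ``mirror_noise`` swaps the two
    noise components (x<->y), which together with a coordinate-swapped scene
    yields the exactly mirrored trajectory — used for symmetry checks.
    """
    u = np.asarray(u, dtype=float).reshape(2)
    if not np.all(np.isfinite(u)):
        raise ValueError("control must be finite")
    sdn = plant.signal_dependent_noise_scale
    add = plant.additive_noise_scale
    u_applied = u
    x = state.vector()
    if sdn > 0.0 or add > 0.0:
        if rng is None:
            raise ValueError("rng required when a noise scale is positive")
        if sdn > 0.0:
            eps = rng.standard_normal(2)
            if mirror_noise:
                eps = eps[::-1]
            u_applied = u * (1.0 + sdn * eps)
    x_next = plant.A @ x + plant.B @ u_applied
    if add > 0.0:
        eta = rng.standard_normal(2)
        if mirror_noise:
            eta = eta[::-1]
        x_next[2:] += add * eta
    return State.from_vector(x_next, t=state.t + 1)
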