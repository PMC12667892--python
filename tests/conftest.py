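import numpy as np
import pytest

import reachmix as rm


@pytest.fixture(scope="session")
def plant():
    """Default noisy plant (dt=0.01, damping=0.1, sdn=0.2)."""
    return rm.make_point_mass_plant()


@pytest.fixture(scope="session")
def quiet_plant():
    """Noise-free plant for deterministic closed-loop checks."""
    return rm.make_point_mass_plant(additive_noise=0.0, sdn_scale=0.0)


def make_canonical_scene(alpha=0.1, lam=1.0, d_inner=4.0, d_outer=8.0):
    """Start (0,0), target (30,30), obstacle (15,15) with a 4/8 zone."""
    return rm.Scene(
        goals=[rm.Goal(position=(30.0, 30.0))],
        obstacles=[
            rm.Obstacle(
                goal=rm.ObstacleGoal(position=(15.0, 15.0)),
                zone=rm.CollisionZone(center=(15.0, 15.0), d_inner=d_inner, d_outer=d_outer),
            )
        ],
        alpha=alpha,
        lam=lam,
        start=(0.0, 0.0),
    )


@pytest.fixture
def canonical_scene():
    return make_canonical_scene()


@pytest.fixture
def zone48():
    return rm.CollisionZone(center=(0.0, 0.0), d_inner=4.0, d_outer=8.0)


@pytest.fixture
def rest_state():
    return rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))


def rollout_closed_loop(plant, policy, state, n_steps=None):
    """Deterministic closed-loop rollout helper used by several tests."""
    n = policy.horizon if n_steps is None else n_steps
    st = state
    traj = [st]
    for t in range(n):
        u = policy.control(st, t)
        st = rm.step(plant, st, u)
        traj.append(st)
    return traj
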