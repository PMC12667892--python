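"""Writers and readers for trajectories, experiment summaries and manifests.

Trajectories and gridded fields go to CSV (inspectable, diffable,
language-neutral); metadata goes to JSON manifests carrying the config
snapshot, all seeds and the package version, enough to re-run a result
bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExperimentResult, Trajectory

__all__ = [
    "trajectory_frame",
    "write_trajectories",
    "read_trajectories",
    "write_experiment_summary",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def trajectory_frame(traj: Trajectory, trial: int = 0, dt: float = 0.01) -> pd.DataFrame:
    """Tidy per-step table of one trial.

    One row per state; the terminal state has no control or breakdown, so
    those columns are NaN there.  Per-option mixture weights and the maximum
    collision risk are logged alongside kinematics.
    """
    n_states = len(traj.states)
    nw_t = len(traj.breakdowns[0].weights_target) if traj.breakdowns else 0
    nw_o = len(traj.breakdowns[0].weights_obstacle) if traj.breakdowns else 0
    rows = []
    event_steps = {s: kind for s, kind, _ in traj.events}
    for i, st in enumerate(traj.states):
        row = {
            "trial": trial,
            "step": i,
            "t": i * dt,
            "px": st.position[0],
            "py": st.position[1],
            "vx": st.velocity[0],
            "vy": st.velocity[1],
        }
        if i < len(traj.controls):
            row["ux"], row["uy"] = traj.controls[i]
            bd = traj.breakdowns[i]
            for j in range(nw_t):
                row[f"w_target_{j}"] = bd.weights_target[j]
            for k in range(nw_o):
                row[f"w_obstacle_{k}"] = bd.weights_obstacle[k]
            row["p_collision"] = float(bd.p_risk_target.max()) if bd.p_risk_target.size else 0.0
        else:
            row["ux"] = row["uy"] = np.nan
            for j in range(nw_t):
                row[f"w_target_{j}"] = np.nan
            for k in range(nw_o):
                row[f"w_obstacle_{k}"] = np.nan
            row["p_collision"] = np.nan
        row["event"] = event_steps.get(i, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_trajectories(trajectories, path, dt: float = 0.01) -> Path:
    """Concatenate trials into one CSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [trajectory_frame(tr, trial=i, dt=dt) for i, tr in enumerate(trajectories)]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_experiment_summary(results: dict[str, ExperimentResult], path) -> Path:
    """Per-condition summary table (collision rates, deviation statistics)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "condition": name,
                "n_trials": len(res.trajectories),
                "collision_rate": res.collision_rate,
                "mean_abs_max_lateral_deviation": float(np.mean(np.abs(res.max_lateral_deviation))),
                "mean_signed_max_lateral_deviation": float(np.mean(res.max_lateral_deviation)),
                "frac_initial_deviation_positive": float(np.mean(res.initial_deviation_sign > 0)),
                "n_curved": int(res.curved_mask.sum()),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_manifest(path, config_snapshot: dict, seeds, extra: dict | None = None) -> Path:
    """JSON manifest: config snapshot + seeds + package version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "reachmix",
        "version": __version__,
        "config": config_snapshot,
        "seeds": list(np.atleast_1d(seeds).tolist()),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path
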