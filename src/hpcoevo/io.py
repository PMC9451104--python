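"""Trajectory serialisation: tidy CSV per time step plus a JSON summary."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import RunResult, Trajectory, summarize_trajectory

__all__ = ["trajectory_frame", "write_trajectory", "summary_path"]


def trajectory_frame(trajectory: Trajectory) -> pd.DataFrame:
    """One row per time step; columns named by the R notation of the model."""
    rows = []
    n_h = trajectory.params.number_types_humans
    n_p = trajectory.params.number_types_plants
    for state, diag in zip(trajectory.states, trajectory.diagnostics):
        row = {
            "time": state.time,
            "humans": state.humans,
            "plants": state.plants,
            "carrying_capacity_humans": diag.carrying_capacity_humans,
            "carrying_capacity_plants": diag.carrying_capacity_plants,
            "utility_humans_to_plants": diag.utility_humans_to_plants,
            "utility_plants_to_humans": diag.utility_plants_to_humans,
            "utility_other_to_humans": diag.utility_other_to_humans,
            "utility_other_to_plants": diag.utility_other_to_plants,
            "coevolution_coefficient_humans": diag.coevolution_coefficient_humans,
            "coevolution_coefficient_plants": diag.coevolution_coefficient_plants,
            "dependency_coefficient_humans": diag.dependency_coefficient_humans,
            "dependency_coefficient_plants": diag.dependency_coefficient_plants,
        }
        for i in range(n_h):
            row[f"type_proportions_humans_{i + 1}"] = state.type_proportions_humans[i]
        for i in range(n_p):
            row[f"type_proportions_plants_{i + 1}"] = state.type_proportions_plants[i]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_path(csv_path) -> Path:
    """Sidecar JSON path for a trajectory CSV (``x.csv`` -> ``x.summary.json``)."""
    csv_path = Path(csv_path)
    return csv_path.with_suffix(".summary.json")


def write_trajectory(
    trajectory: Trajectory, path, result: RunResult | None = None
) -> tuple[Path, Path]:
    """Write the per-step CSV and the run-summary sidecar JSON.

    The summary is recomputed from the trajectory when not supplied, so the
    two files are always mutually consistent. Returns both paths.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_frame(trajectory).to_csv(path, index=False)
    if result is None:
        result = summarize_trajectory(trajectory)
    sidecar = summary_path(path)
    sidecar.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    return path, sidecar
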