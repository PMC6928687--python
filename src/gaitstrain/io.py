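"""Dataset round-tripping: trial CSVs with JSON sidecars, marker-grid CSVs,
and YAML experiment configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    CHANNEL_NAMES,
    SENSOR_NAMES,
    Cohort,
    JointAngleSeries,
    MarkerGridSeries,
    SensorSeries,
    Trial,
)

__all__ = [
    "write_trial_csv",
    "read_trial_csv",
    "write_cohort",
    "write_marker_grid",
    "read_marker_grid",
    "load_yaml_config",
]

_V_COLS = [f"v{i + 1}" for i in range(9)]


def write_trial_csv(trial: Trial, path: str | Path) -> None:
    """One trial as CSV (t, v1..v9, six angle columns) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"t": trial.angles.t})
    for i, col in enumerate(_V_COLS):
        df[col] = trial.sensors.v[:, i]
    for i, col in enumerate(CHANNEL_NAMES):
        df[col] = trial.angles.angles[:, i]
    df.to_csv(path, index=False)
    sidecar = {
        "participant": trial.angles.participant_id,
        "speed": trial.angles.speed,
        "trial": trial.angles.trial_index,
        "v0": trial.sensors.v0.tolist(),
        "sensors": list(SENSOR_NAMES),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trial_csv(path: str | Path) -> Trial:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    angles = JointAngleSeries(
        participant_id=meta["participant"],
        speed=float(meta["speed"]),
        trial_index=int(meta["trial"]),
        t=df["t"].to_numpy(),
        angles=df[list(CHANNEL_NAMES)].to_numpy(),
    )
    sensors = SensorSeries(
        participant_id=meta["participant"],
        speed=float(meta["speed"]),
        trial_index=int(meta["trial"]),
        v=df[_V_COLS].to_numpy(),
        v0=np.asarray(meta["v0"], dtype=float),
    )
    return Trial(angles=angles, sensors=sensors)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """All trials plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in cohort.trials:
        name = (
            f"{trial.angles.participant_id}_trial{trial.angles.trial_index:02d}.csv"
        )
        write_trial_csv(trial, out / name)
        entries.append(
            {
                "file": name,
                "participant": trial.angles.participant_id,
                "speed": trial.angles.speed,
                "trial": trial.angles.trial_index,
                "frames": trial.angles.n_frames,
            }
        )
    manifest = {
        "protocol": {
            "speeds": list(cohort.protocol.speeds),
            "trial_duration": cohort.protocol.trial_duration,
            "repeats": cohort.protocol.repeats,
            "sample_rate": cohort.protocol.sample_rate,
        },
        "n_participants": len(cohort.profiles),
        "trials": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def write_marker_grid(grid: MarkerGridSeries, path: str | Path,
                      rate: float = 100.0) -> None:
    """Long-format marker CSV (t, marker_id, x, y, z) + neutral-posture CSV."""
    path = Path(path)
    n_frames, n_markers, _ = grid.positions.shape
    t = np.repeat(np.arange(n_frames) / rate, n_markers)
    marker = np.tile(np.arange(n_markers), n_frames)
    flat = grid.positions.reshape(-1, 3)
    pd.DataFrame(
        {"t": t, "marker_id": marker, "x": flat[:, 0], "y": flat[:, 1],
         "z": flat[:, 2]}
    ).to_csv(path, index=False)
    neutral = pd.DataFrame(grid.neutral_positions, columns=["x", "y", "z"])
    neutral.insert(0, "marker_id", np.arange(n_markers))
    neutral.to_csv(path.with_name(path.stem + "_neutral.csv"), index=False)


def read_marker_grid(
    path: str | Path, grid_rows: int, grid_cols: int,
    participant_id: str = "", speed: float = float("nan")
) -> MarkerGridSeries:
    path = Path(path)
    df = pd.read_csv(path)
    n_markers = grid_rows * grid_cols
    frames = len(df) // n_markers
    pos = df[["x", "y", "z"]].to_numpy().reshape(frames, n_markers, 3)
    neutral = (
        pd.read_csv(path.with_name(path.stem + "_neutral.csv"))[["x", "y", "z"]]
        .to_numpy()
    )
    return MarkerGridSeries(
        participant_id=participant_id,
        speed=speed,
        positions=pos,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        neutral_positions=neutral,
    )


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML config; raises ValueError with context on malformed input."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data
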