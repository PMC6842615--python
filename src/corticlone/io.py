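"""Readers, writers and run manifests for the package's file formats.

All tables are UTF-8 CSV with a header row and '.' decimals; structured
parameters and summaries are JSON. Readers validate required columns and
raise :class:`SchemaError` naming the first missing one. Writers refuse
to silently overwrite existing files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonestats import CloneCategory, CloneObservation, CohortSummary, classify_clone
from .lineage import Clone, LineageParams

__all__ = [
    "SchemaError",
    "write_table",
    "read_clone_table",
    "read_trajectory_table",
    "read_field_table",
    "clones_to_frame",
    "frame_to_observations",
    "observations_by_design",
    "summaries_to_frame",
    "write_json",
    "read_params",
    "write_manifest",
    "trajectories_to_tracks",
]

CLONE_COLUMNS = ["condition", "t_label", "t_obs", "clone_id", "n_total", "n_prog"]
COMPOSITION_COLUMNS = ["clone_id", "t_label", "t_obs", "n_rg", "n_ipc", "n_neuron"]
TRAJECTORY_COLUMNS = ["track_id", "t_h", "x_um", "y_um"]
FIELD_COLUMNS = ["field_id", "n_rosettes", "single_rosette", "center_x", "center_y"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column '{col}'")


def write_table(df: pd.DataFrame, path, overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path, overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_clone_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CLONE_COLUMNS, "clone")
    return df


def read_trajectory_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS, "trajectory")
    return df


def read_field_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, FIELD_COLUMNS, "field")
    return df


def clones_to_frame(clones: list[Clone]) -> pd.DataFrame:
    """Composition dialect: one row per simulated clone."""
    return pd.DataFrame(
        {
            "clone_id": [f"clone_{i:05d}" for i in range(len(clones))],
            "t_label": [c.t_label for c in clones],
            "t_obs": [c.t_obs for c in clones],
            "n_rg": [c.n_rg for c in clones],
            "n_ipc": [c.n_ipc for c in clones],
            "n_neuron": [c.n_neuron for c in clones],
        }
    )


def frame_to_observations(df: pd.DataFrame) -> list[CloneObservation]:
    _check_columns(df, CLONE_COLUMNS, "clone")
    obs = []
    for row in df.itertuples(index=False):
        n_total, n_prog = int(row.n_total), int(row.n_prog)
        obs.append(
            CloneObservation(
                n_total=n_total,
                n_prog=n_prog,
                category=classify_clone(n_prog, n_total),
                t_label=float(row.t_label),
                t_obs=float(row.t_obs),
                condition=str(row.condition),
            )
        )
    return obs


def observations_by_design(
    df: pd.DataFrame, condition: str | None = None
) -> dict[tuple[float, float], list[CloneObservation]]:
    """Group a clone table into the (t_label, t_obs) design cells."""
    if condition is not None:
        df = df[df["condition"] == condition]
    out: dict[tuple[float, float], list[CloneObservation]] = {}
    for obs in frame_to_observations(df):
        out.setdefault((obs.t_label, obs.t_obs), []).append(obs)
    return out


def summaries_to_frame(summaries: dict[tuple[float, float], CohortSummary]) -> pd.DataFrame:
    """Tidy summary table: one row per condition x t_label x t_obs."""
    rows = []
    for (t_label, t_obs), s in sorted(summaries.items()):
        row = {
            "condition": s.condition,
            "t_label": t_label,
            "t_obs": t_obs,
            "n_clones": s.n_clones,
            "mean_size": s.mean_size,
            "sem_size": s.sem_size,
            "mean_prog": s.mean_prog,
            "sem_prog": s.sem_prog,
            "persisting_fraction": s.persisting_fraction,
            "persisting_mean_size": s.persisting_mean_size,
        }
        for cat in CloneCategory:
            row[f"freq_{cat.value.lower()}"] = s.category_freqs[cat.value]
        rows.append(row)
    return pd.DataFrame(rows)


def read_params(path) -> LineageParams:
    return LineageParams.from_json(Path(path).read_text())


def write_manifest(out_dir, config: dict, seed: int, overwrite: bool = False) -> Path:
    """Record everything needed to reproduce a run next to its outputs."""
    manifest = {
        "package": "corticlone",
        "version": __version__,
        "seed": int(seed),
        "config": config,
    }
    return write_json(manifest, Path(out_dir) / "manifest.json", overwrite=overwrite)


def trajectories_to_tracks(df: pd.DataFrame) -> list[np.ndarray]:
    """Split a trajectory table into per-track (t, x, y) arrays."""
    _check_columns(df, TRAJECTORY_COLUMNS, "trajectory")
    return [
        g[["t_h", "x_um", "y_um"]].to_numpy(dtype=float)
        for _, g in df.sort_values(["track_id", "t_h"]).groupby("track_id", sort=True)
    ]
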