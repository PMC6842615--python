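"""Study-shaped synthetic datasets with known ground truth.

Emulates the structure of the lineage-tracing and micropattern
experiments: clones founded by single labeled progenitors at culture day
30 or 40 and observed 2, 6 or 10 days post-mixing (cohorts of 50-72
clones per summary point, 152-176 per histogram cohort); live-imaging
cell tracks as persistent random walks; and micropattern chip summaries
with optional center detection noise and rosette miss rate. Every
generator records the parameters and seeds needed to regenerate its
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import clonestats, lineage, rosette
from .lineage import LineageParams

__all__ = [
    "StudyDesign",
    "generate_clone_dataset",
    "generate_tracking_data",
    "generate_chip_dataset",
    "prw_msd_expectation",
]


@dataclass(frozen=True)
class StudyDesign:
    """Design of the clonal lineage-tracing study.

    Cohort sizes are drawn uniformly in ``n_range`` per summary point
    (``n_hist_range`` when ``histogram_cohorts`` is set), matching the
    reported cohort-size ranges.
    """

    conditions: tuple[str, ...] = ("control", "mutant")
    t_labels: tuple[float, ...] = (30.0, 40.0)
    t_obs: tuple[float, ...] = (2.0, 6.0, 10.0)
    n_range: tuple[int, int] = (50, 72)
    n_hist_range: tuple[int, int] = (152, 176)
    seed: int = 0
    histogram_cohorts: bool = False
    misclassification_rate: float = 0.0
    resample_shortfall: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.n_range, self.n_hist_range):
            if not (1 <= lo <= hi):
                raise ValueError("cohort-size ranges must satisfy 1 <= lo <= hi")


def generate_clone_dataset(
    design: StudyDesign,
    control_params: LineageParams | None = None,
    diff_multiplier: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Clone-observation table for every condition x t_label x t_obs cell.

    Clones are drawn from the lineage model (mutant = control with the
    differentiation multiplier applied) and reduced by the observation
    model; sub-2-cell clones are rejected. By default rejected draws are
    resampled until the cohort quota is met — the same conditioning the
    experiment applies by only counting clones. With
    ``design.resample_shortfall`` False, exactly ``n`` founders are
    drawn and the shortfall is reported in the ground truth.

    Returns the tidy table and a ground-truth dict sufficient to
    regenerate it exactly.
    """
    if control_params is None:
        control_params = LineageParams()
    if diff_multiplier < 1.0:
        raise ValueError("diff_multiplier must be >= 1")
    params_by_condition = {}
    for cond in design.conditions:
        params_by_condition[cond] = (
            control_params.with_multiplier(diff_multiplier) if cond == "mutant" else control_params
        )

    lo, hi = design.n_hist_range if design.histogram_cohorts else design.n_range
    rows = []
    shortfalls = {}
    for ci, cond in enumerate(design.conditions):
        params = params_by_condition[cond]
        for li, t_label in enumerate(design.t_labels):
            for oi, t_obs in enumerate(design.t_obs):
                cell_seed = lineage._clone_seed(design.seed, ci, li, oi)
                rng = np.random.default_rng(cell_seed)
                n_target = int(rng.integers(lo, hi + 1))
                accepted = 0
                attempt = 0
                max_attempts = n_target if not design.resample_shortfall else 1000 * n_target
                while accepted < n_target and attempt < max_attempts:
                    clone = lineage.simulate_clone(
                        params, t_label, t_obs, lineage._clone_seed(cell_seed, attempt)
                    )
                    obs = clonestats.observe_clone(
                        clone,
                        design.misclassification_rate,
                        seed=lineage._clone_seed(cell_seed, attempt, 1),
                        condition=cond,
                    )
                    attempt += 1
                    if obs is None:
                        continue
                    accepted += 1
                    rows.append(
                        {
                            "condition": cond,
                            "t_label": t_label,
                            "t_obs": t_obs,
                            "clone_id": f"{cond}_d{int(t_label)}_o{int(t_obs)}_{accepted:04d}",
                            "n_total": obs.n_total,
                            "n_prog": obs.n_prog,
                            "category": obs.category.value,
                        }
                    )
                if accepted < n_target:
                    shortfalls[f"{cond}/d{t_label}/o{t_obs}"] = n_target - accepted
    table = pd.DataFrame(rows)
    ground_truth = {
        "design": dataclasses.asdict(design),
        "control_params": dataclasses.asdict(control_params),
        "diff_multiplier": diff_multiplier,
        "shortfalls": shortfalls,
    }
    return table, ground_truth


def prw_msd_expectation(motility: rosette.MotilityParams, n_steps: int) -> float:
    """Exact expected squared displacement of the discrete-step PRW.

    For heading increments Normal(0, turn_sd) per step the directional
    correlation is a = exp(-turn_sd^2 / 2) and
    E|r_m|^2 = l^2 [ m (1+a)/(1-a) - 2a (1-a^m)/(1-a)^2 ],  l = speed*dt
    (a Kareiva-Shigesada-type formula); the ballistic limit l^2 m^2 is
    returned when turn_sd = 0.
    """
    l = motility.speed * motility.dt
    a = math.exp(-motility.turn_sd**2 / 2.0)
    m = n_steps
    if a >= 1.0:
        return (l * m) ** 2
    return l * l * (m * (1 + a) / (1 - a) - 2 * a * (1 - a**m) / (1 - a) ** 2)


def generate_tracking_data(
    n_tracks: int,
    motility: rosette.MotilityParams | None = None,
    duration: float = 48.0,
    seed: int = 0,
    sample_interval: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Live-imaging-like cell tracks: unconfined persistent random walks.

    Tracks start at the origin with uniform initial headings and are
    reported every ``sample_interval`` hours (defaults to the motility
    step). Returns a tidy (track_id, t_h, x_um, y_um) table plus ground
    truth.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if motility is None:
        motility = rosette.MotilityParams()
    dt = motility.dt
    n_steps = int(round(duration / dt))
    keep = max(1, int(round((sample_interval or dt) / dt)))
    frames = []
    for k in range(n_tracks):
        rng = default_rng(SeedSequence([int(seed), k]))
        turns = rng.normal(0.0, motility.turn_sd, size=n_steps - 1) if n_steps > 1 else []
        headings = rng.random() * 2 * np.pi + np.concatenate([[0.0], np.cumsum(turns)])
        steps = motility.speed * dt * np.column_stack([np.cos(headings), np.sin(headings)])
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        t = np.arange(n_steps + 1) * dt
        sel = np.arange(0, n_steps + 1, keep)
        frames.append(
            pd.DataFrame(
                {"track_id": k, "t_h": t[sel], "x_um": xy[sel, 0], "y_um": xy[sel, 1]}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    ground_truth = {
        "n_tracks": n_tracks,
        "motility": dataclasses.asdict(motility),
        "duration": duration,
        "seed": seed,
        "sample_interval": sample_interval or dt,
    }
    return table, ground_truth


def generate_chip_dataset(
    n_fields: int,
    spec: rosette.FieldSpec | None = None,
    motility: rosette.MotilityParams | None = None,
    adhesion: rosette.AdhesionParams | None = None,
    detection_noise: float = 0.0,
    miss_rate: float = 0.0,
    t_end: float = 48.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Rosette field summaries with an imperfect-detection overlay.

    Runs the agent-based model per field, then perturbs each detected
    center with isotropic Gaussian noise of sd ``detection_noise`` (um)
    and drops each rosette independently with ``miss_rate``. Field-level
    counts are recomputed from the recorded rosettes, so the recorded
    single-rosette fraction follows the binomial-thinning expectation.
    One row per recorded rosette; fields with none keep a row with
    ``n_rosettes = 0`` and empty centers.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError("miss_rate must be in [0, 1]")
    spec = spec or rosette.FieldSpec()
    motility = motility or rosette.MotilityParams()
    adhesion = adhesion or rosette.AdhesionParams()
    chip = rosette.simulate_chip(n_fields, spec, motility, adhesion, t_end=t_end, seed=seed)
    noise_rng = default_rng(SeedSequence([int(seed), 10**6]))
    rows = []
    for fid, fr in enumerate(chip.fields):
        recorded = []
        for r in fr.rosettes:
            if miss_rate > 0.0 and noise_rng.random() < miss_rate:
                continue
            cx, cy = r.center
            if detection_noise > 0.0:
                cx += noise_rng.normal(0.0, detection_noise)
                cy += noise_rng.normal(0.0, detection_noise)
            recorded.append((cx, cy))
        if recorded:
            for cx, cy in recorded:
                rows.append(
                    {
                        "field_id": fid,
                        "n_rosettes": len(recorded),
                        "single_rosette": len(recorded) == 1,
                        "center_x": cx,
                        "center_y": cy,
                    }
                )
        else:
            rows.append(
                {
                    "field_id": fid,
                    "n_rosettes": 0,
                    "single_rosette": False,
                    "center_x": float("nan"),
                    "center_y": float("nan"),
                }
            )
    table = pd.DataFrame(rows)
    ground_truth = {
        "n_fields": n_fields,
        "field": dataclasses.asdict(spec),
        "motility": dataclasses.asdict(motility),
        "adhesion": dataclasses.asdict(adhesion),
        "detection_noise": detection_noise,
        "miss_rate": miss_rate,
        "t_end": t_end,
        "seed": seed,
        "true_single_rosette_fraction": chip.single_rosette_fraction,
    }
    return table, ground_truth
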