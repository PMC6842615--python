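"""Observation model and cohort summary statistics for clone data.

Clone rosters are reduced to what the experiment measures: total cell
count and number of Ki67+ (cycling progenitor) cells per clone, after
immunostaining for Ki67 and the neuronal marker beta-III-tubulin. Clones
with fewer than 2 cells are excluded throughout, matching the counting
rule of the lineage-tracing assay. Summaries cover mean clone size, mean
progenitor count, the three-way clone-category frequencies
(all-progenitor / all-neuron / mixed), persisting-clone statistics
(clones retaining at least one Ki67+ cell), and integer size histograms.
"""

from __future__ import annotations

import enum
import math
import random
from dataclasses import dataclass, field

import numpy as np

from .lineage import CellKind, Clone

__all__ = [
    "CloneCategory",
    "CloneObservation",
    "CohortSummary",
    "observe_clone",
    "observe_counts",
    "classify_clone",
    "summarize_cohort",
    "growth_shape_statistic",
    "GrowthShape",
    "DEFAULT_HIST_CAP",
]

DEFAULT_HIST_CAP = 32


class CloneCategory(enum.Enum):
    ALL_PROG = "ALL_PROG"
    ALL_NEURON = "ALL_NEURON"
    MIXED = "MIXED"


@dataclass(frozen=True)
class CloneObservation:
    """The measurable reduction of one clone: (total cells, Ki67+ cells)."""

    n_total: int
    n_prog: int
    category: CloneCategory
    t_label: float = 0.0
    t_obs: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("observations require n_total >= 2 (clone filter)")
        if not (0 <= self.n_prog <= self.n_total):
            raise ValueError("n_prog must lie in [0, n_total]")
        if self.category is not classify_clone(self.n_prog, self.n_total):
            raise ValueError("category inconsistent with counts")


def classify_clone(n_prog: int, n_total: int) -> CloneCategory:
    """Three-way classification by Ki67+ content."""
    if n_prog > n_total:
        raise ValueError("n_prog cannot exceed n_total")
    if n_total < 2:
        raise ValueError("classification requires n_total >= 2")
    if n_prog == n_total:
        return CloneCategory.ALL_PROG
    if n_prog == 0:
        return CloneCategory.ALL_NEURON
    return CloneCategory.MIXED


def observe_counts(
    n_prog_true: int,
    n_neuron_true: int,
    misclassification_rate: float = 0.0,
    rng: random.Random | None = None,
    t_label: float = 0.0,
    t_obs: float = 0.0,
    condition: str = "",
) -> CloneObservation | None:
    """Observation model on raw counts; returns None for rejected clones.

    True progenitors (cycling RG + IPC) score Ki67+, neurons Ki67-;
    each cell independently flips label with ``misclassification_rate``.
    Clones of fewer than 2 cells are rejected after (label-preserving)
    misclassification, exactly as an experimenter would count them.
    """
    if not (0.0 <= misclassification_rate < 0.5):
        raise ValueError("misclassification_rate must be in [0, 0.5)")
    n_total = n_prog_true + n_neuron_true
    if n_total < 2:
        return None
    n_prog = n_prog_true
    if misclassification_rate > 0.0:
        if rng is None:
            raise ValueError("misclassification requires an rng")
        flips_pos = sum(
            1 for _ in range(n_prog_true) if rng.random() < misclassification_rate
        )
        flips_neg = sum(
            1 for _ in range(n_neuron_true) if rng.random() < misclassification_rate
        )
        n_prog = n_prog_true - flips_pos + flips_neg
    return CloneObservation(
        n_total=n_total,
        n_prog=n_prog,
        category=classify_clone(n_prog, n_total),
        t_label=t_label,
        t_obs=t_obs,
        condition=condition,
    )


def observe_clone(
    clone: Clone,
    misclassification_rate: float = 0.0,
    seed: int | None = None,
    condition: str = "",
) -> CloneObservation | None:
    """Reduce a simulated clone roster to a :class:`CloneObservation`.

    Ki67+ means a cycling RG or IPC (quiescent progenitors, if the
    optional quiescence rate is on, score Ki67- like neurons). Returns
    None (REJECTED) for clones below the 2-cell filter.
    """
    n_prog_true = sum(
        1 for c in clone.cells if c.kind is not CellKind.NEURON and c.cycling
    )
    n_neg_true = len(clone.cells) - n_prog_true
    rng = random.Random(seed) if misclassification_rate > 0.0 else None
    return observe_counts(
        n_prog_true,
        n_neg_true,
        misclassification_rate,
        rng,
        t_label=clone.t_label,
        t_obs=clone.t_obs,
        condition=condition,
    )


@dataclass
class CohortSummary:
    """Per-cohort statistics of a set of clone observations.

    ``size_histogram[i]`` counts clones of size ``i + 2`` for
    ``i < hist_cap - 1``; the final bin collects sizes above the cap.
    ``persisting_*`` statistics are over clones with at least one Ki67+
    cell (all-progenitor or mixed).
    """

    n_clones: int
    mean_size: float
    sem_size: float
    mean_prog: float
    sem_prog: float
    category_freqs: dict[str, float]
    persisting_fraction: float
    persisting_mean_size: float
    persisting_sem_size: float
    size_histogram: np.ndarray
    hist_cap: int = DEFAULT_HIST_CAP
    t_label: float | None = None
    t_obs: float | None = None
    condition: str = ""

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "size_histogram"}
        d["size_histogram"] = [int(x) for x in self.size_histogram]
        return d


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def histogram_bin_labels(cap: int = DEFAULT_HIST_CAP) -> list[str]:
    return [str(s) for s in range(2, cap + 1)] + [f">{cap}"]


def summarize_cohort(
    observations: list[CloneObservation], hist_cap: int = DEFAULT_HIST_CAP
) -> CohortSummary:
    """All cohort statistics; SEM = sample SD / sqrt(n).

    Permutation-invariant in the input list. Raises on an empty cohort.
    """
    if not observations:
        raise ValueError("cannot summarize an empty cohort")
    sizes = np.array([o.n_total for o in observations], dtype=float)
    progs = np.array([o.n_prog for o in observations], dtype=float)
    n = len(observations)
    cats = np.array([o.category.value for o in observations])
    freqs = {c.value: float((cats == c.value).mean()) for c in CloneCategory}
    persisting = sizes[cats != CloneCategory.ALL_NEURON.value]
    hist = np.zeros(hist_cap, dtype=int)  # bins 2..cap, then overflow
    for s in sizes.astype(int):
        hist[min(s, hist_cap + 1) - 2] += 1
    t_labels = {o.t_label for o in observations}
    t_obss = {o.t_obs for o in observations}
    conds = {o.condition for o in observations}
    return CohortSummary(
        n_clones=n,
        mean_size=float(sizes.mean()),
        sem_size=_sem(sizes),
        mean_prog=float(progs.mean()),
        sem_prog=_sem(progs),
        category_freqs=freqs,
        persisting_fraction=float(len(persisting) / n),
        persisting_mean_size=float(persisting.mean()) if len(persisting) else float("nan"),
        persisting_sem_size=_sem(persisting) if len(persisting) else float("nan"),
        size_histogram=hist,
        hist_cap=hist_cap,
        t_label=t_labels.pop() if len(t_labels) == 1 else None,
        t_obs=t_obss.pop() if len(t_obss) == 1 else None,
        condition=conds.pop() if len(conds) == 1 else "",
    )


@dataclass
class GrowthShape:
    """Log-space curvature of a growth time course.

    ``index`` is the mean difference of successive log-size slopes per
    unit time: ~0 for exponential growth, negative for sub-exponential
    (e.g. linear) growth.
    """

    index: float
    ci_low: float | None = None
    ci_high: float | None = None


def _curvature(times: np.ndarray, log_sizes: np.ndarray) -> float:
    slopes = np.diff(log_sizes) / np.diff(times)
    return float(np.mean(np.diff(slopes)))


def growth_shape_statistic(
    times,
    sizes,
    n_boot: int = 200,
    seed: int = 0,
) -> GrowthShape:
    """Convexity index of persisting-clone growth in log space.

    ``sizes`` may be scalar mean sizes per time point (no CI), or
    per-time-point arrays of individual persisting-clone sizes, in which
    case a case-resampling bootstrap CI (95%) is attached. Requires at
    least 3 time points.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 3 or len(sizes) != len(times):
        raise ValueError("growth shape needs >= 3 matched time points")
    per_point = [np.atleast_1d(np.asarray(s, dtype=float)) for s in sizes]
    means = np.array([p.mean() for p in per_point])
    if np.any(means <= 0):
        raise ValueError("mean sizes must be positive for log-space curvature")
    index = _curvature(times, np.log(means))
    if n_boot <= 0 or all(len(p) == 1 for p in per_point):
        return GrowthShape(index=index)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        m = np.array([rng.choice(p, size=len(p), replace=True).mean() for p in per_point])
        boot[b] = _curvature(times, np.log(np.maximum(m, 1e-12)))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return GrowthShape(index=index, ci_low=float(lo), ci_high=float(hi))
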