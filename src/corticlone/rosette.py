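"""Agent-based model of neural rosette self-assembly on micropatterned discs.

Dissociated neural progenitors plated on a circular adhesive field
(default 140 um diameter) are modeled as point agents performing a
persistent random walk; whenever two agents from different clusters come
within an attachment radius, they form an (by default irreversible)
apical attachment with a per-step probability. Attached clusters stop
moving independently. Rosettes are the connected components of the
attachment graph with at least ``min_rosette_size`` members; their
centers are the member centroids. The model asks whether random motion
plus proximity-triggered apical attachment suffices to reproduce rosette
counts and center distributions, and how lowering attachment efficiency
(the mutant phenotype) degrades single-rosette formation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

__all__ = [
    "FieldSpec",
    "MotilityParams",
    "AdhesionParams",
    "AgentField",
    "Rosette",
    "FieldRosettes",
    "ChipSummary",
    "step_field",
    "detect_rosettes",
    "simulate_field",
    "simulate_chip",
    "compare_center_distributions",
    "trajectory_directionality",
    "DirectionalityResult",
    "connected_components",
]


@dataclass(frozen=True)
class FieldSpec:
    """Circular micropattern field; origin at the field center."""

    diameter: float = 140.0  # um
    n_cells: int = 8
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.boundary != "reflecting":
            raise ValueError("only the reflecting boundary is implemented")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class MotilityParams:
    """Persistent random walk: heading diffuses, speed is constant."""

    speed: float = 10.0  # um/h
    turn_sd: float = 0.6  # rad per step
    dt: float = 0.1  # h per step

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class AdhesionParams:
    """Proximity-triggered apical attachment."""

    radius: float = 8.0  # um
    p_attach: float = 0.1  # per step, per eligible pair (control-like default)
    irreversible: bool = True
    detach_rate: float = 0.0  # per hour, only if not irreversible
    min_rosette_size: int = 3
    cluster_speed: float = 0.0  # um/h rigid-body diffusion of clusters

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not (0.0 <= self.p_attach <= 1.0):
            raise ValueError("p_attach must be in [0, 1]")


class _DSU:
    """Union-find over agent ids (the rosette-detection primitive)."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]
        return True


def connected_components(n: int, edges) -> list[set[int]]:
    """Connected components of an undirected graph via union-find."""
    dsu = _DSU(n)
    for i, j in edges:
        dsu.union(i, j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(dsu.find(i), set()).add(i)
    return list(comps.values())


@dataclass
class AgentField:
    """State of all agents on one field.

    ``edges`` is the symmetric attachment graph as a set of sorted id
    pairs; cluster membership is derived from it.
    """

    positions: np.ndarray  # (n, 2) um
    headings: np.ndarray  # (n,) rad
    edges: set[tuple[int, int]]
    spec: FieldSpec

    @classmethod
    def seeded(cls, spec: FieldSpec, rng: np.random.Generator) -> "AgentField":
        """Uniform random positions on the disc, uniform headings."""
        n = spec.n_cells
        r = spec.radius * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * np.pi
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        headings = rng.random(n) * 2 * np.pi
        return cls(positions=pos, headings=headings, edges=set(), spec=spec)

    @property
    def n(self) -> int:
        return len(self.positions)

    def cluster_labels(self) -> np.ndarray:
        dsu = _DSU(self.n)
        for i, j in self.edges:
            dsu.union(i, j)
        return np.array([dsu.find(i) for i in range(self.n)])

    def attachment_sets(self) -> list[set[int]]:
        """Per-agent sets of directly attached partners (symmetric)."""
        out: list[set[int]] = [set() for _ in range(self.n)]
        for i, j in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out


def _reflect_into_disc(pos: np.ndarray, headings: np.ndarray, radius: float) -> None:
    """Radial reflection at the circular boundary, in place.

    An agent ending at r > R is folded to 2R - r along the same ray and
    its heading reflected about the boundary tangent.
    """
    r = np.hypot(pos[:, 0], pos[:, 1])
    out = r > radius
    if not np.any(out):
        return
    r_out = r[out]
    scale = np.clip((2 * radius - r_out), 0.0, radius) / r_out
    pos[out] *= scale[:, None]
    phi = np.arctan2(pos[out, 1], pos[out, 0])
    headings[out] = 2 * phi + np.pi - headings[out]


def step_field(
    agents: AgentField,
    motility: MotilityParams,
    adhesion: AdhesionParams,
    rng: np.random.Generator,
) -> AgentField:
    """Advance the field by one time step ``motility.dt`` (in place).

    Unattached agents take a persistent-random-walk step and reflect at
    the disc boundary; attached clusters stay put (or take a rigid-body
    diffusion step if ``cluster_speed`` > 0). Every pair of agents in
    different clusters within the attachment radius then attaches with
    probability ``p_attach``.
    """
    n = agents.n
    spec = agents.spec
    pos, headings = agents.positions, agents.headings

    if not adhesion.irreversible and adhesion.detach_rate > 0 and agents.edges:
        p_det = 1.0 - math.exp(-adhesion.detach_rate * motility.dt)
        keep = {e for e in agents.edges if rng.random() >= p_det}
        agents.edges = keep

    labels = agents.cluster_labels()
    counts = np.bincount(labels, minlength=n)
    free = counts[labels] == 1

    headings[free] = headings[free] + rng.normal(0.0, motility.turn_sd, size=int(free.sum()))
    step = motility.speed * motility.dt
    pos[free, 0] += step * np.cos(headings[free])
    pos[free, 1] += step * np.sin(headings[free])

    if adhesion.cluster_speed > 0.0:
        sigma = adhesion.cluster_speed * motility.dt
        for lab in np.unique(labels[~free]):
            members = labels == lab
            shift = rng.normal(0.0, sigma, size=2)
            pos[members] += shift
            # keep the whole cluster on the field
            r = np.hypot(pos[members, 0], pos[members, 1])
            worst = r.max()
            if worst > spec.radius:
                pos[members] *= spec.radius / worst

    _reflect_into_disc(pos, headings, spec.radius)

    if adhesion.p_attach > 0.0 and n > 1:
        d = squareform(pdist(pos))
        close_i, close_j = np.where(np.triu(d <= adhesion.radius, k=1))
        if len(close_i):
            dsu = _DSU(n)
            for i, j in agents.edges:
                dsu.union(i, j)
            for i, j in zip(close_i.tolist(), close_j.tolist()):
                if dsu.find(i) != dsu.find(j) and rng.random() < adhesion.p_attach:
                    dsu.union(i, j)
                    agents.edges.add((i, j))
    return agents


@dataclass(frozen=True)
class Rosette:
    members: frozenset[int]
    center: tuple[float, float]


@dataclass
class FieldRosettes:
    """Rosettes detected on one field."""

    rosettes: list[Rosette]
    n_rosettes: int
    single_rosette: bool
    n_cells: int

    def center_distances(self) -> np.ndarray:
        """Distances of rosette centers to the field center (origin)."""
        return np.array([math.hypot(*r.center) for r in self.rosettes])


def detect_rosettes(agents: AgentField, adhesion: AdhesionParams) -> FieldRosettes:
    """Rosettes = attachment-graph components with >= min_rosette_size members."""
    comps = connected_components(agents.n, agents.edges)
    rosettes = []
    for comp in comps:
        if len(comp) >= adhesion.min_rosette_size:
            idx = sorted(comp)
            center = agents.positions[idx].mean(axis=0)
            rosettes.append(Rosette(members=frozenset(comp), center=(float(center[0]), float(center[1]))))
    return FieldRosettes(
        rosettes=rosettes,
        n_rosettes=len(rosettes),
        single_rosette=len(rosettes) == 1,
        n_cells=agents.n,
    )


def simulate_field(
    spec: FieldSpec,
    motility: MotilityParams,
    adhesion: AdhesionParams,
    t_end: float,
    seed,
) -> AgentField:
    """Run one field for ``t_end`` hours from random initial positions."""
    rng = default_rng(seed)
    agents = AgentField.seeded(spec, rng)
    n_steps = int(round(t_end / motility.dt))
    for _ in range(n_steps):
        step_field(agents, motility, adhesion, rng)
    return agents


@dataclass
class ChipSummary:
    """Chip-level rosette statistics pooled over independent fields."""

    n_fields: int
    single_rosette_fraction: float
    mean_rosettes_per_field: float
    center_distances: np.ndarray  # pooled rosette-center distances to field centers
    fields: list[FieldRosettes]


def simulate_chip(
    n_fields: int,
    spec: FieldSpec,
    motility: MotilityParams,
    adhesion: AdhesionParams,
    t_end: float = 48.0,
    seed: int = 0,
) -> ChipSummary:
    """Independent micropattern fields; order-independent per-field seeds."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    fields = []
    for f in range(n_fields):
        agents = simulate_field(spec, motility, adhesion, t_end, SeedSequence([int(seed), f]))
        fields.append(detect_rosettes(agents, adhesion))
    dists = (
        np.concatenate([fr.center_distances() for fr in fields])
        if any(fr.n_rosettes for fr in fields)
        else np.array([])
    )
    return ChipSummary(
        n_fields=n_fields,
        single_rosette_fraction=float(np.mean([fr.single_rosette for fr in fields])),
        mean_rosettes_per_field=float(np.mean([fr.n_rosettes for fr in fields])),
        center_distances=dists,
        fields=fields,
    )


def compare_center_distributions(simulated, observed) -> tuple[float, float]:
    """Two-sample KS test between rosette-center distance samples."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(simulated) == 0 or len(observed) == 0:
        raise ValueError("both center-distance samples must be non-empty")
    res = ks_2samp(simulated, observed, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DirectionalityResult:
    """Per-track straightness and a Rayleigh test for directional bias.

    ``ratios`` is net displacement / path length in [0, 1] per track;
    the Rayleigh test asks whether net-displacement angles concentrate
    in one direction (p > alpha: no evidence of directed migration).
    """

    ratios: np.ndarray
    angles: np.ndarray
    rayleigh_z: float
    rayleigh_p: float
    n_tracks: int
    n_skipped: int


def trajectory_directionality(tracks) -> DirectionalityResult:
    """Directionality analysis of (t, x, y) cell tracks.

    Tracks with fewer than 3 points are skipped with a warning; tracks
    with zero path length contribute no angle and a 0 ratio.
    """
    ratios, angles = [], []
    n_skipped = 0
    for tr in tracks:
        arr = np.asarray(tr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3:
            warnings.warn("skipping track with fewer than 3 points", stacklevel=2)
            n_skipped += 1
            continue
        xy = arr[:, 1:3]
        seg = np.diff(xy, axis=0)
        path = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        net_vec = xy[-1] - xy[0]
        net = float(np.hypot(*net_vec))
        if path == 0.0:
            ratios.append(0.0)
            continue
        ratios.append(net / path)
        if net > 0:
            angles.append(math.atan2(net_vec[1], net_vec[0]))
    if not angles:
        raise ValueError("no usable tracks for the directionality analysis")
    import pingouin  # deferred: heavy import

    z, p = pingouin.circ_rayleigh(np.asarray(angles))
    return DirectionalityResult(
        ratios=np.asarray(ratios),
        angles=np.asarray(angles),
        rayleigh_z=float(z),
        rayleigh_p=float(p),
        n_tracks=len(ratios),
        n_skipped=n_skipped,
    )
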