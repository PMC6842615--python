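"""Stochastic clonal-lineage model of human cortical progenitors.

The model tracks clones founded by a single radial glial cell (RG). RGs
first divide symmetrically (RG -> RG + RG); after a neurogenic switch time
``t_switch`` (measured in absolute culture days) each RG division is drawn
from a three-way fate mix:

* symmetric proliferative  RG -> RG + RG       (prob ``p_rg_sym``)
* asymmetric neurogenic    RG -> RG + IPC      (prob ``p_rg_asym``)
* differentiative          RG -> IPC + IPC     (prob ``p_rg_diff``)

Intermediate progenitor cells (IPCs) carry a limited neurogenic potential:
each new IPC draws a number of remaining division rounds from
{1, ..., k_max}. An IPC division is terminal (IPC -> NEURON + NEURON) with
probability ``p_ipc_terminal``, or forced terminal once its potential is
exhausted; otherwise it divides asymmetrically (IPC -> IPC + NEURON) and
its potential decrements. Neurons never divide.

The mutant condition is the same model with a single changed quantity: the
two IPC-producing RG channels are up-weighted by ``diff_multiplier`` and
the fate mix renormalized ("differentiation into IPCs at a higher rate").

Time is continuous: every cycling cell waits an exponential time at its
kind-specific division rate. Two independent oracles for the simulator are
provided: :func:`mean_field_expectations` (exact linear-ODE compartment
means) and :func:`enumerate_small_clones` (exhaustive enumeration of the
embedded fate-choice chain).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import random
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence
from scipy.linalg import expm

__all__ = [
    "CellKind",
    "LineageParams",
    "Cell",
    "Clone",
    "simulate_clone",
    "simulate_clone_synchronous",
    "simulate_cohort",
    "simulate_compositions",
    "mean_field_expectations",
    "enumerate_small_clones",
    "MAX_ENUM_EVENTS",
]

MAX_ENUM_EVENTS = 12


class CellKind(enum.Enum):
    """The three cell kinds of the lineage model; NEURON is terminal."""

    RG = "RG"
    IPC = "IPC"
    NEURON = "NEURON"


class ParameterError(ValueError):
    """Raised when lineage parameters violate the model invariants."""


@dataclass(frozen=True)
class LineageParams:
    """All rates and fate probabilities of the RG/IPC/neuron model.

    Rates are per day; ``t_switch`` is in absolute culture days so that
    day-30 and day-40 labeling probe different phases of one parameter
    set. ``diff_multiplier`` (>= 1 for the mutant, 1 for control) scales
    the weights of the two IPC-producing RG channels before the fate mix
    is renormalized.
    """

    lambda_rg: float = 0.45
    lambda_ipc: float = 0.6
    t_switch: float = 30.0
    p_rg_sym: float = 0.45
    p_rg_asym: float = 0.20
    p_rg_diff: float = 0.35
    k_max: int = 3
    p_ipc_terminal: float = 0.3
    diff_multiplier: float = 1.0
    # optional extensions, all off by default
    ipc_potential_dist: str = "uniform"  # "uniform" or "geometric"
    ipc_potential_p: float = 0.5  # success prob of the geometric option
    rg_diff_mode: str = "division"  # "division" (RG->IPC+IPC) or "conversion" (RG->IPC)
    death_rate: float = 0.0
    quiescence_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda_rg > 0 and self.lambda_ipc > 0):
            raise ParameterError("division rates must be strictly positive")
        probs = (self.p_rg_sym, self.p_rg_asym, self.p_rg_diff, self.p_ipc_terminal)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("probabilities must lie in [0, 1]")
        if abs(self.p_rg_sym + self.p_rg_asym + self.p_rg_diff - 1.0) > 1e-9:
            raise ParameterError("RG fate probabilities must sum to 1")
        if self.k_max < 1:
            raise ParameterError("k_max must be an integer >= 1")
        if self.diff_multiplier < 1.0:
            raise ParameterError("diff_multiplier must be >= 1")
        if self.ipc_potential_dist not in ("uniform", "geometric"):
            raise ParameterError("ipc_potential_dist must be 'uniform' or 'geometric'")
        if self.rg_diff_mode not in ("division", "conversion"):
            raise ParameterError("rg_diff_mode must be 'division' or 'conversion'")
        if self.death_rate < 0 or self.quiescence_rate < 0:
            raise ParameterError("death and quiescence rates must be >= 0")

    def effective_fate_probs(self) -> tuple[float, float, float]:
        """RG fate mix after applying ``diff_multiplier`` and renormalizing."""
        m = self.diff_multiplier
        w = (self.p_rg_sym, m * self.p_rg_asym, m * self.p_rg_diff)
        tot = sum(w)
        return (w[0] / tot, w[1] / tot, w[2] / tot)

    def with_multiplier(self, m: float) -> "LineageParams":
        """Same parameters with a different mutant multiplier."""
        return dataclasses.replace(self, diff_multiplier=float(m))

    def potential_pmf(self) -> np.ndarray:
        """pmf over the initial IPC potential values 1..k_max.

        Uniform by default; the geometric option puts mass
        (1-p)^(j-1) * p on j with the tail folded into k_max.
        """
        k = self.k_max
        if self.ipc_potential_dist == "uniform":
            return np.full(k, 1.0 / k)
        p = self.ipc_potential_p
        pmf = np.array([(1.0 - p) ** (j - 1) * p for j in range(1, k + 1)])
        pmf[-1] += (1.0 - p) ** k  # tail mass at the cap
        return pmf

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LineageParams":
        return cls(**json.loads(text))


@dataclass
class Cell:
    """A single cell in a clone roster.

    ``potential`` is the remaining IPC division rounds (None for RG and
    NEURON); ``cycling`` is False only for quiescent progenitors.
    """

    kind: CellKind
    potential: int | None = None
    birth_time: float = 0.0
    cycling: bool = True


@dataclass
class Clone:
    """Full cell roster of one simulated clone."""

    cells: list[Cell]
    t_label: float
    t_obs: float
    rng_seed: int
    n_events: int = 0

    @property
    def n_rg(self) -> int:
        return sum(1 for c in self.cells if c.kind is CellKind.RG)

    @property
    def n_ipc(self) -> int:
        return sum(1 for c in self.cells if c.kind is CellKind.IPC)

    @property
    def n_neuron(self) -> int:
        return sum(1 for c in self.cells if c.kind is CellKind.NEURON)

    @property
    def size(self) -> int:
        return len(self.cells)

    def composition(self) -> tuple[int, int, int]:
        return (self.n_rg, self.n_ipc, self.n_neuron)

    def to_roster_json(self) -> str:
        return json.dumps(
            {
                "t_label": self.t_label,
                "t_obs": self.t_obs,
                "rng_seed": self.rng_seed,
                "n_events": self.n_events,
                "cells": [
                    {
                        "kind": c.kind.value,
                        "potential": c.potential,
                        "birth_time": c.birth_time,
                        "cycling": c.cycling,
                    }
                    for c in self.cells
                ],
            }
        )


def _clone_seed(master_seed: int, *index: int) -> int:
    """Counter-based per-clone seed: independent of cohort ordering."""
    ss = SeedSequence([int(master_seed), *[int(i) for i in index]])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _draw_potential(params: LineageParams, rng: random.Random) -> int:
    if params.ipc_potential_dist == "uniform":
        return rng.randint(1, params.k_max)
    # truncated geometric on {1..k_max}
    p = params.ipc_potential_p
    j = 1
    while j < params.k_max and rng.random() >= p:
        j += 1
    return j


def _simulate(
    params: LineageParams,
    t_label: float,
    t_obs: float,
    rng: random.Random,
    record: bool,
    max_events: int | None = None,
):
    """Event-driven core shared by all simulation entry points.

    Returns ``(n_rg, ipc_potentials, n_neuron, n_events, cells)`` where
    ``cells`` is None unless ``record``. A single code path serves both
    the roster-building and the fast composition-only modes so that the
    oracle tests cover everything downstream.
    """
    lam_rg, lam_ipc = params.lambda_rg, params.lambda_ipc
    d, q = params.death_rate, params.quiescence_rate
    p_sym, p_asym, p_diff = params.effective_fate_probs()
    t_end = t_label + t_obs

    n_rg = 1
    ipc_pot: list[int] = []
    n_neuron = 0
    n_events = 0
    t = t_label

    cells: list[Cell] | None = None
    rg_cells: list[Cell] = []
    ipc_cells: list[Cell] = []
    done_cells: list[Cell] = []
    if record:
        rg_cells = [Cell(CellKind.RG, None, t_label)]

    rg_rate = lam_rg + d + q
    ipc_rate = lam_ipc + d + q

    while True:
        n_ipc = len(ipc_pot)
        total = n_rg * rg_rate + n_ipc * ipc_rate
        if total <= 0.0:
            break
        if max_events is not None and n_events >= max_events:
            break
        t_next = t + rng.expovariate(total)
        if t_next > t_end:
            break
        t = t_next
        u = rng.random() * total
        if u < n_rg * rg_rate:
            # event on an RG; sub-type by rate shares
            v = rng.random() * rg_rate
            if v < lam_rg:
                n_events += 1
                if t < params.t_switch:
                    fate = "sym"
                else:
                    w = rng.random()
                    fate = "sym" if w < p_sym else ("asym" if w < p_sym + p_asym else "diff")
                if fate == "sym":
                    n_rg += 1
                    if record:
                        rg_cells.append(Cell(CellKind.RG, None, t))
                elif fate == "asym":
                    pot = _draw_potential(params, rng)
                    ipc_pot.append(pot)
                    if record:
                        ipc_cells.append(Cell(CellKind.IPC, pot, t))
                else:  # differentiative channel
                    n_rg -= 1
                    n_new = 2 if params.rg_diff_mode == "division" else 1
                    idx = rng.randrange(n_rg + 1)  # which RG differentiates
                    if record:
                        rg_cells.pop(idx)
                    for _ in range(n_new):
                        pot = _draw_potential(params, rng)
                        ipc_pot.append(pot)
                        if record:
                            ipc_cells.append(Cell(CellKind.IPC, pot, t))
            elif v < lam_rg + d:
                n_rg -= 1
                idx = rng.randrange(n_rg + 1)
                if record:
                    rg_cells.pop(idx)
            else:  # quiescence: retained but stops cycling
                n_rg -= 1
                idx = rng.randrange(n_rg + 1)
                if record:
                    c = rg_cells.pop(idx)
                    c.cycling = False
                    done_cells.append(c)
        else:
            idx = rng.randrange(n_ipc)
            v = rng.random() * ipc_rate
            if v < lam_ipc:
                n_events += 1
                pot = ipc_pot[idx]
                terminal = pot <= 0 or rng.random() < params.p_ipc_terminal
                if terminal:
                    ipc_pot[idx] = ipc_pot[-1]
                    ipc_pot.pop()
                    n_neuron += 2
                    if record:
                        ipc_cells[idx] = ipc_cells[-1]
                        ipc_cells.pop()
                        done_cells.append(Cell(CellKind.NEURON, None, t))
                        done_cells.append(Cell(CellKind.NEURON, None, t))
                else:
                    ipc_pot[idx] = pot - 1
                    n_neuron += 1
                    if record:
                        ipc_cells[idx].potential = pot - 1
                        done_cells.append(Cell(CellKind.NEURON, None, t))
            elif v < lam_ipc + d:
                ipc_pot[idx] = ipc_pot[-1]
                ipc_pot.pop()
                if record:
                    ipc_cells[idx] = ipc_cells[-1]
                    ipc_cells.pop()
            else:
                ipc_pot[idx] = ipc_pot[-1]
                ipc_pot.pop()
                if record:
                    c = ipc_cells[idx]
                    ipc_cells[idx] = ipc_cells[-1]
                    ipc_cells.pop()
                    c.cycling = False
                    done_cells.append(c)

    if record:
        cells = rg_cells + ipc_cells + done_cells
    return n_rg, ipc_pot, n_neuron, n_events, cells


def simulate_clone(
    params: LineageParams,
    t_label: float,
    t_obs: float,
    seed: int,
    max_events: int | None = None,
) -> Clone:
    """Simulate one clone founded by a single RG at ``t_label``.

    Returns the full cell roster at absolute time ``t_label + t_obs``.
    ``max_events`` optionally stops the realization after that many
    division events (used to expose the embedded fate-choice chain).
    """
    if t_obs < 0:
        raise ParameterError("t_obs must be >= 0")
    rng = random.Random(seed)
    _, _, _, n_events, cells = _simulate(
        params, t_label, t_obs, rng, record=True, max_events=max_events
    )
    return Clone(cells=cells, t_label=t_label, t_obs=t_obs, rng_seed=seed, n_events=n_events)


def simulate_cohort(
    params: LineageParams,
    t_label: float,
    t_obs_list: list[float],
    n_clones: int,
    seed: int,
) -> list[Clone]:
    """Independent clones for each observation time, one substream each.

    Clone ``i`` at observation-time index ``j`` is driven by a seed
    derived from ``(seed, j, i)``, so cohorts are reproducible and
    order-independent.
    """
    if n_clones < 1:
        raise ParameterError("n_clones must be >= 1")
    clones: list[Clone] = []
    for j, t_obs in enumerate(t_obs_list):
        for i in range(n_clones):
            clones.append(simulate_clone(params, t_label, t_obs, _clone_seed(seed, j, i)))
    return clones


def simulate_compositions(
    params: LineageParams,
    t_label: float,
    t_obs: float,
    n_clones: int,
    seed: int,
) -> np.ndarray:
    """Fast path: (n_clones, 3) array of (n_RG, n_IPC, n_NEURON) counts.

    Runs the same event engine as :func:`simulate_clone` without building
    cell objects; clone ``i`` uses the seed derived from ``(seed, 0, i)``
    so it matches ``simulate_cohort(params, t_label, [t_obs], n, seed)``.
    """
    if n_clones < 1:
        raise ParameterError("n_clones must be >= 1")
    out = np.empty((n_clones, 3), dtype=np.int64)
    for i in range(n_clones):
        rng = random.Random(_clone_seed(seed, 0, i))
        n_rg, ipc_pot, n_neuron, _, _ = _simulate(params, t_label, t_obs, rng, record=False)
        out[i, 0] = n_rg
        out[i, 1] = len(ipc_pot)
        out[i, 2] = n_neuron
    return out


def simulate_clone_synchronous(
    params: LineageParams, generations: int, seed: int, t_label: float = 0.0
) -> Clone:
    """Synchronous-generation variant for closed-form tests.

    All cycling cells divide simultaneously each generation; generation g
    occurs at time ``t_label + g / lambda_rg`` for the purpose of the
    neurogenic switch. With ``t_switch = inf`` this is pure symmetric
    doubling: g generations give exactly 2**g RGs.
    """
    rng = random.Random(seed)
    p_sym, p_asym, p_diff = params.effective_fate_probs()
    cells: list[Cell] = [Cell(CellKind.RG, None, t_label)]
    n_events = 0
    for g in range(1, generations + 1):
        t = t_label + g / params.lambda_rg
        new_cells: list[Cell] = []
        for c in cells:
            if c.kind is CellKind.NEURON or not c.cycling:
                new_cells.append(c)
                continue
            n_events += 1
            if c.kind is CellKind.RG:
                if t < params.t_switch:
                    fate = "sym"
                else:
                    w = rng.random()
                    fate = "sym" if w < p_sym else ("asym" if w < p_sym + p_asym else "diff")
                if fate == "sym":
                    new_cells.append(c)
                    new_cells.append(Cell(CellKind.RG, None, t))
                elif fate == "asym":
                    new_cells.append(c)
                    new_cells.append(Cell(CellKind.IPC, _draw_potential(params, rng), t))
                else:
                    n_new = 2 if params.rg_diff_mode == "division" else 1
                    n_events -= 1 if params.rg_diff_mode == "conversion" else 0
                    for _ in range(n_new):
                        new_cells.append(Cell(CellKind.IPC, _draw_potential(params, rng), t))
            else:  # IPC
                pot = c.potential or 0
                if pot <= 0 or rng.random() < params.p_ipc_terminal:
                    new_cells.append(Cell(CellKind.NEURON, None, t))
                    new_cells.append(Cell(CellKind.NEURON, None, t))
                else:
                    c.potential = pot - 1
                    new_cells.append(c)
                    new_cells.append(Cell(CellKind.NEURON, None, t))
        cells = new_cells
    return Clone(cells=cells, t_label=t_label, t_obs=generations / params.lambda_rg,
                 rng_seed=seed, n_events=n_events)


# ---------------------------------------------------------------------------
# Oracle 1: exact compartment means via the linear ODE system
# ---------------------------------------------------------------------------

def _rate_matrix_post(params: LineageParams) -> np.ndarray:
    """Generator of expected counts in the neurogenic phase.

    State vector: [RG, IPC(k_max), ..., IPC(1), IPC(0), NEURON]; IPC
    compartments are stratified by remaining potential, so the system is
    linear and the means are exact by linearity of expectation.
    """
    k = params.k_max
    p_sym, p_asym, p_diff = params.effective_fate_probs()
    pt = params.p_ipc_terminal
    pmf = params.potential_pmf()  # over potentials 1..k
    dim = 1 + (k + 1) + 1
    A = np.zeros((dim, dim))

    def ipc_idx(pot: int) -> int:
        return 1 + (k - pot)

    n_idx = dim - 1
    lam_rg, lam_ipc = params.lambda_rg, params.lambda_ipc
    ipc_per_diff = 2.0 if params.rg_diff_mode == "division" else 1.0

    # RG compartment
    A[0, 0] = lam_rg * (p_sym - p_diff)
    # IPC influx from RG divisions, spread over initial potentials
    flux = lam_rg * (p_asym + ipc_per_diff * p_diff)
    for pot in range(1, k + 1):
        A[ipc_idx(pot), 0] += flux * pmf[pot - 1]
    # IPC dynamics
    for pot in range(0, k + 1):
        i = ipc_idx(pot)
        A[i, i] -= lam_ipc
        p_term = 1.0 if pot == 0 else pt
        if pot > 0:
            A[ipc_idx(pot - 1), i] += lam_ipc * (1.0 - p_term)
        A[n_idx, i] += lam_ipc * (2.0 * p_term + (1.0 - p_term))
    return A


def mean_field_expectations(
    params: LineageParams, t_label: float, t_obs: float
) -> tuple[float, float, float]:
    """Exact expected (E[RG], E[IPC], E[NEURON]) at ``t_label + t_obs``.

    Solves the piecewise-linear ODE system for compartment means (matrix
    exponential before and after the neurogenic switch). Only valid for
    the default no-death, no-quiescence model.
    """
    if params.death_rate != 0.0 or params.quiescence_rate != 0.0:
        raise ParameterError("mean-field oracle requires death_rate = quiescence_rate = 0")
    if t_obs < 0:
        raise ParameterError("t_obs must be >= 0")
    k = params.k_max
    dim = 1 + (k + 1) + 1
    x = np.zeros(dim)
    x[0] = 1.0

    t0, t1 = t_label, t_label + t_obs
    # pre-switch phase: pure symmetric RG doubling
    if t0 < params.t_switch:
        dt_pre = min(t1, params.t_switch) - t0
        x[0] *= math.exp(params.lambda_rg * dt_pre)
        t0 += dt_pre
    if t1 > t0:
        A = _rate_matrix_post(params)
        x = expm(A * (t1 - t0)) @ x
    e_rg = float(x[0])
    e_ipc = float(x[1 : 1 + k + 1].sum())
    e_neuron = float(x[-1])
    return (e_rg, e_ipc, e_neuron)


# ---------------------------------------------------------------------------
# Oracle 2: exhaustive enumeration of the embedded fate-choice chain
# ---------------------------------------------------------------------------

def enumerate_small_clones(
    params: LineageParams, max_events: int
) -> dict[tuple[int, int, int], float]:
    """Exact composition distribution after up to ``max_events`` divisions.

    Enumerates every fate-choice sequence of the embedded discrete chain
    (the fate mix conditional on which cell divides next, with division
    order weighted by the kind-specific rates). Time plays no role, so
    the neurogenic fate mix is assumed throughout — compare against
    simulations with ``t_switch <= t_label``. States where no cell can
    divide are absorbing. Probabilities sum to 1 exactly.
    """
    if max_events > MAX_ENUM_EVENTS:
        raise ParameterError(f"max_events must be <= {MAX_ENUM_EVENTS} for exhaustive enumeration")
    if params.death_rate != 0.0 or params.quiescence_rate != 0.0:
        raise ParameterError("enumeration oracle requires death_rate = quiescence_rate = 0")
    p_sym, p_asym, p_diff = params.effective_fate_probs()
    pt = params.p_ipc_terminal
    pmf = params.potential_pmf()
    lam_rg, lam_ipc = params.lambda_rg, params.lambda_ipc
    ipc_per_diff = 2 if params.rg_diff_mode == "division" else 1

    out: dict[tuple[int, int, int], float] = {}

    def add(state, prob):
        n_rg, ipc, n_neuron = state
        key = (n_rg, len(ipc), n_neuron)
        out[key] = out.get(key, 0.0) + prob

    def spread_new_ipcs(ipc: tuple[int, ...], n_new: int):
        """Yield (new_ipc_tuple, prob) over the potential draws of n_new IPCs."""
        states = [(ipc, 1.0)]
        for _ in range(n_new):
            nxt = []
            for s, pr in states:
                for pot in range(1, params.k_max + 1):
                    nxt.append((tuple(sorted(s + (pot,))), pr * pmf[pot - 1]))
            states = nxt
        return states

    def recurse(n_rg: int, ipc: tuple[int, ...], n_neuron: int, events_left: int, prob: float):
        if prob <= 0.0:
            return
        total = n_rg * lam_rg + len(ipc) * lam_ipc
        if events_left == 0 or total <= 0.0:
            add((n_rg, ipc, n_neuron), prob)
            return
        p_rg_event = n_rg * lam_rg / total
        if p_rg_event > 0.0:
            base = prob * p_rg_event
            if p_sym > 0:
                recurse(n_rg + 1, ipc, n_neuron, events_left - 1, base * p_sym)
            if p_asym > 0:
                for new_ipc, pr in spread_new_ipcs(ipc, 1):
                    recurse(n_rg, new_ipc, n_neuron, events_left - 1, base * p_asym * pr)
            if p_diff > 0:
                for new_ipc, pr in spread_new_ipcs(ipc, ipc_per_diff):
                    recurse(n_rg - 1, new_ipc, n_neuron, events_left - 1, base * p_diff * pr)
        if len(ipc) > 0:
            # group identical potentials: selection is uniform among IPCs
            from collections import Counter

            counts = Counter(ipc)
            for pot, c in counts.items():
                p_this = prob * (c * lam_ipc / total)
                removed = list(ipc)
                removed.remove(pot)
                p_term = 1.0 if pot <= 0 else pt
                if p_term > 0:
                    recurse(n_rg, tuple(removed), n_neuron + 2, events_left - 1, p_this * p_term)
                if p_term < 1.0:
                    kept = tuple(sorted(removed + [pot - 1]))
                    recurse(n_rg, kept, n_neuron + 1, events_left - 1, p_this * (1.0 - p_term))

    recurse(1, (), 0, max_events, 1.0)
    return out
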