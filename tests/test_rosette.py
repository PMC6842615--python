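"""Tests for the agent-based rosette model and spatial statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.random import default_rng

from corticlone.rosette import (
    AdhesionParams,
    AgentField,
    FieldSpec,
    MotilityParams,
    compare_center_distributions,
    connected_components,
    detect_rosettes,
    simulate_chip,
    simulate_field,
    step_field,
    trajectory_directionality,
)


def _field(positions, spec=None):
    pos = np.asarray(positions, dtype=float)
    return AgentField(
        positions=pos,
        headings=np.zeros(len(pos)),
        edges=set(),
        spec=spec or FieldSpec(n_cells=len(pos)),
    )


class TestStep:
    def test_frozen_system_is_a_fixed_point(self):
        f = _field([[0, 0], [30, 0], [0, 30]])
        before = f.positions.copy()
        step_field(f, MotilityParams(speed=0.0), AdhesionParams(p_attach=0.0), default_rng(0))
        assert np.allclose(f.positions, before)
        assert f.edges == set()

    def test_close_pair_attaches_with_certainty(self):
        f = _field([[0, 0], [3, 0], [50, 0]])
        step_field(f, MotilityParams(speed=0.0), AdhesionParams(radius=8, p_attach=1.0),
                   default_rng(0))
        assert (0, 1) in f.edges and len(f.edges) == 1

    def test_attached_agents_stop_moving(self):
        f = _field([[0, 0], [3, 0], [50, 0]])
        mot = MotilityParams(speed=20.0)
        adh = AdhesionParams(radius=8, p_attach=1.0)
        rng = default_rng(1)
        step_field(f, mot, adh, rng)
        attached = f.positions[:2].copy()
        step_field(f, mot, adh, rng)
        assert np.allclose(f.positions[:2], attached)
        assert not np.allclose(f.positions[2], [50, 0])

    def test_reflection_keeps_agents_on_the_disc(self):
        spec = FieldSpec(n_cells=1)
        f = _field([[69.0, 0.0]], spec)
        f.headings[:] = 0.0  # aimed straight at the boundary
        step_field(f, MotilityParams(speed=50.0, turn_sd=0.0, dt=0.1),
                   AdhesionParams(p_attach=0.0), default_rng(0))
        r = math.hypot(*f.positions[0])
        assert r <= spec.radius + 1e-9
        assert f.positions[0][0] == pytest.approx(2 * spec.radius - 74.0)

    def test_attachment_graph_stays_symmetric(self):
        rng = default_rng(3)
        f = AgentField.seeded(FieldSpec(n_cells=12), rng)
        for _ in range(200):
            step_field(f, MotilityParams(), AdhesionParams(p_attach=0.5), rng)
        partners = f.attachment_sets()
        for i, s in enumerate(partners):
            for j in s:
                assert i in partners[j]

    def test_component_count_never_increases_when_irreversible(self):
        rng = default_rng(4)
        f = AgentField.seeded(FieldSpec(n_cells=10), rng)
        n_comps = [len(connected_components(f.n, f.edges))]
        for _ in range(300):
            step_field(f, MotilityParams(), AdhesionParams(p_attach=0.3), rng)
            n_comps.append(len(connected_components(f.n, f.edges)))
        assert all(a >= b for a, b in zip(n_comps, n_comps[1:]))

    def test_detachment_can_split_clusters(self):
        f = _field([[0, 0], [3, 0], [6, 0]])
        adh = AdhesionParams(radius=4, p_attach=1.0, irreversible=False, detach_rate=50.0)
        rng = default_rng(5)
        step_field(f, MotilityParams(speed=0.0), adh, rng)
        assert len(f.edges) > 0
        for _ in range(50):
            step_field(f, MotilityParams(speed=0.0, turn_sd=0.0), adh, rng)
        # with a huge detachment rate the graph keeps churning rather than freezing
        assert len(connected_components(f.n, f.edges)) >= 1


class TestDetection:
    def test_no_attachments_means_no_rosettes(self):
        f = _field([[0, 0], [10, 0], [20, 0], [30, 0]])
        assert detect_rosettes(f, AdhesionParams()).n_rosettes == 0

    def test_single_component_is_a_single_rosette(self):
        f = _field([[0, 0], [4, 0], [8, 0]])
        f.edges = {(0, 1), (1, 2)}
        res = detect_rosettes(f, AdhesionParams(min_rosette_size=3))
        assert res.n_rosettes == 1 and res.single_rosette
        assert res.rosettes[0].center == pytest.approx((4.0, 0.0))

    def test_pairs_below_min_size_are_not_rosettes(self):
        f = _field([[0, 0], [4, 0], [30, 0], [34, 0], [38, 0]])
        f.edges = {(0, 1), (2, 3), (3, 4)}
        res = detect_rosettes(f, AdhesionParams(min_rosette_size=3))
        assert res.n_rosettes == 1
        assert res.rosettes[0].members == frozenset({2, 3, 4})

    def test_components_match_networkx_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = default_rng(10)
        for _ in range(300):
            n = int(rng.integers(2, 21))
            m = int(rng.integers(0, n * 2 + 1))
            edges = {tuple(sorted(rng.choice(n, size=2, replace=False))) for _ in range(m)}
            ours = {frozenset(c) for c in connected_components(n, edges)}
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            theirs = {frozenset(c) for c in nx.connected_components(g)}
            assert ours == theirs


class TestChip:
    def test_no_attachment_means_no_single_rosettes(self):
        chip = simulate_chip(20, FieldSpec(n_cells=6), MotilityParams(),
                             AdhesionParams(p_attach=0.0), t_end=5.0, seed=0)
        assert chip.single_rosette_fraction == 0.0

    def test_global_adhesion_forces_one_rosette(self):
        spec = FieldSpec(n_cells=6)
        adh = AdhesionParams(radius=spec.diameter, p_attach=1.0)
        chip = simulate_chip(20, spec, MotilityParams(), adh, t_end=2.0, seed=1)
        assert chip.single_rosette_fraction == 1.0

    def test_seed_determinism_and_field_independence(self):
        a = simulate_chip(10, FieldSpec(), MotilityParams(), AdhesionParams(), t_end=6.0, seed=3)
        b = simulate_chip(10, FieldSpec(), MotilityParams(), AdhesionParams(), t_end=6.0, seed=3)
        assert a.single_rosette_fraction == b.single_rosette_fraction
        assert np.array_equal(a.center_distances, b.center_distances)
        # field f of a 5-field chip equals field f of a 10-field chip (same substreams)
        c = simulate_chip(5, FieldSpec(), MotilityParams(), AdhesionParams(), t_end=6.0, seed=3)
        for fa, fc in zip(b.fields[:5], c.fields):
            assert fa.n_rosettes == fc.n_rosettes


class TestCenterComparison:
    def test_identical_samples_have_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = compare_center_distributions(x, x)
        assert d == 0.0

    def test_disjoint_supports_have_distance_one(self):
        d, _ = compare_center_distributions([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_matches_brute_force_ecdf_gap(self):
        a = np.array([0.5, 1.1, 2.0, 3.3, 5.0])
        b = np.array([0.9, 1.0, 1.2, 4.1])
        grid = np.concatenate([a, b])
        gap = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        d, _ = compare_center_distributions(a, b)
        assert d == pytest.approx(gap)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_center_distributions([], [1.0])


class TestDirectionality:
    def test_straight_line_scores_exactly_one(self):
        t = np.arange(5.0)
        tracks = [np.column_stack([t, 3.0 * t, 4.0 * t])]
        res = trajectory_directionality(tracks)
        assert res.ratios[0] == 1.0

    def test_closed_loop_scores_zero(self):
        theta = np.linspace(0, 2 * np.pi, 20)
        loop = np.column_stack([np.arange(20.0), np.cos(theta), np.sin(theta)])
        res = trajectory_directionality([loop, loop[: len(loop) // 2]])
        assert res.ratios[0] == pytest.approx(0.0, abs=1e-12)

    def test_short_tracks_skipped_with_warning(self):
        good = np.column_stack([np.arange(4.0), np.arange(4.0), np.zeros(4)])
        with pytest.warns(UserWarning):
            res = trajectory_directionality([good, good[:2]])
        assert res.n_skipped == 1 and res.n_tracks == 1

    def test_rayleigh_agrees_with_closed_form(self):
        rng = default_rng(0)
        n = 60
        tracks = []
        for _ in range(n):
            ang = rng.random() * 2 * np.pi
            t = np.arange(3.0)
            tracks.append(np.column_stack([t, np.cos(ang) * t, np.sin(ang) * t]))
        res = trajectory_directionality(tracks)
        r = np.hypot(np.cos(res.angles).sum(), np.sin(res.angles).sum()) / n
        z = n * r * r
        assert res.rayleigh_z == pytest.approx(z, rel=1e-6)
        assert res.rayleigh_p > 0.05  # uniform angles: no directional bias


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16), p=st.floats(0.0, 1.0), speed=st.floats(0.0, 40.0))
def test_agents_stay_on_the_field_property(seed, p, speed):
    """Cell number is conserved and no agent ever leaves the disc."""
    rng = default_rng(seed)
    spec = FieldSpec(n_cells=6)
    f = AgentField.seeded(spec, rng)
    for _ in range(40):
        step_field(f, MotilityParams(speed=speed, dt=0.2), AdhesionParams(p_attach=p), rng)
        assert f.n == 6
        assert np.all(np.hypot(f.positions[:, 0], f.positions[:, 1]) <= spec.radius + 1e-9)
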