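"""Unit and property tests for the stochastic lineage simulator."""

import dataclasses
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from corticlone.lineage import (
    CellKind,
    LineageParams,
    ParameterError,
    _clone_seed,
    enumerate_small_clones,
    mean_field_expectations,
    simulate_clone,
    simulate_clone_synchronous,
    simulate_cohort,
    simulate_compositions,
)


class TestParams:
    @pytest.mark.parametrize(
        "bad",
        [
            {"lambda_rg": 0.0},
            {"lambda_ipc": -1.0},
            {"p_rg_sym": 0.5, "p_rg_asym": 0.5, "p_rg_diff": 0.5},
            {"p_ipc_terminal": 1.5},
            {"k_max": 0},
            {"diff_multiplier": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            LineageParams(**bad)

    def test_multiplier_renormalizes_fate_mix(self):
        p = LineageParams(p_rg_sym=0.5, p_rg_asym=0.3, p_rg_diff=0.2, diff_multiplier=2.0)
        probs = p.effective_fate_probs()
        assert probs == pytest.approx((0.5 / 1.5, 0.6 / 1.5, 0.4 / 1.5))
        assert sum(probs) == pytest.approx(1.0)

    def test_potential_pmf_sums_to_one(self):
        for dist in ("uniform", "geometric"):
            p = LineageParams(ipc_potential_dist=dist, k_max=4)
            assert p.potential_pmf().sum() == pytest.approx(1.0)


class TestSimulateClone:
    def test_vanishing_rates_leave_founder_untouched(self, control_params):
        p = dataclasses.replace(control_params, lambda_rg=1e-12, lambda_ipc=1e-12)
        clone = simulate_clone(p, 30.0, 10.0, seed=1)
        assert clone.composition() == (1, 0, 0)

    def test_synchronous_symmetric_doubling(self, control_params):
        p = dataclasses.replace(control_params, t_switch=math.inf)
        clone = simulate_clone_synchronous(p, generations=3, seed=0)
        assert clone.composition() == (8, 0, 0)

    def test_forced_sequence_yields_four_neurons(self, forced_params):
        for seed in range(10):
            clone = simulate_clone(forced_params, 0.0, 500.0, seed=seed)
            assert clone.composition() == (0, 0, 4)

    def test_size_equals_one_plus_events_division_mode(self, neurogenic_params):
        for seed in range(20):
            clone = simulate_clone(neurogenic_params, 40.0, 6.0, seed=seed)
            assert clone.size == 1 + clone.n_events

    def test_clone_size_monotone_in_observation_time(self, neurogenic_params):
        # same seed shares the event-sequence prefix, so sizes are nested
        for seed in range(10):
            sizes = [
                simulate_clone(neurogenic_params, 40.0, t, seed=seed).size
                for t in (0.0, 2.0, 6.0, 10.0)
            ]
            assert sizes == sorted(sizes)
            assert sizes[0] == 1

    def test_composition_matches_fast_path(self, neurogenic_params):
        comps = simulate_compositions(neurogenic_params, 40.0, 6.0, 50, seed=9)
        for i in range(50):
            clone = simulate_clone(neurogenic_params, 40.0, 6.0, seed=_clone_seed(9, 0, i))
            assert tuple(comps[i]) == clone.composition()

    def test_neurons_never_divide(self, neurogenic_params):
        clone = simulate_clone(neurogenic_params, 40.0, 10.0, seed=3)
        for cell in clone.cells:
            if cell.kind is CellKind.NEURON:
                assert cell.potential is None

    def test_death_rate_allows_shrinkage_and_zero_rate_does_not(self, neurogenic_params):
        p = dataclasses.replace(neurogenic_params, death_rate=2.0)
        sizes = [simulate_clone(p, 40.0, 20.0, seed=s).size for s in range(200)]
        assert min(sizes) == 0 or any(s < 2 for s in sizes)


class TestCohort:
    def test_zero_clones_is_an_error(self, control_params):
        with pytest.raises(ParameterError):
            simulate_cohort(control_params, 40.0, [2.0], 0, seed=1)

    def test_same_seed_reproduces_cohort(self, control_params):
        a = simulate_cohort(control_params, 40.0, [2.0, 6.0], 5, seed=7)
        b = simulate_cohort(control_params, 40.0, [2.0, 6.0], 5, seed=7)
        assert [c.composition() for c in a] == [c.composition() for c in b]

    def test_monte_carlo_means_match_ode_oracle(self, control_params):
        n = 10_000
        mf = np.array(mean_field_expectations(control_params, 40.0, 6.0))
        comps = simulate_compositions(control_params, 40.0, 6.0, n, seed=11)
        mc = comps.mean(axis=0)
        se = comps.std(axis=0, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(mc - mf) <= 3.0 * np.maximum(se, 1e-12))


class TestMeanField:
    def test_initial_condition(self, control_params):
        assert mean_field_expectations(control_params, 40.0, 0.0) == pytest.approx((1, 0, 0))

    def test_yule_closed_form_before_the_switch(self, control_params):
        p = dataclasses.replace(control_params, t_switch=math.inf)
        e_rg, e_ipc, e_n = mean_field_expectations(p, 0.0, 4.0)
        assert e_rg == pytest.approx(math.exp(p.lambda_rg * 4.0))
        assert e_ipc == 0.0 and e_n == 0.0

    def test_raising_multiplier_depletes_radial_glia(self, neurogenic_params):
        for t_obs in (2.0, 6.0, 10.0):
            e_rg = [
                mean_field_expectations(neurogenic_params.with_multiplier(m), 40.0, t_obs)[0]
                for m in (1.0, 1.5, 2.0, 3.0)
            ]
            assert all(a > b for a, b in zip(e_rg, e_rg[1:]))

    def test_raising_multiplier_reduces_late_clone_size(self, neurogenic_params):
        totals = [
            sum(mean_field_expectations(neurogenic_params.with_multiplier(m), 40.0, 10.0))
            for m in (1.0, 2.0, 4.0)
        ]
        assert totals[0] > totals[1] > totals[2]


class TestEnumeration:
    def test_zero_events_is_the_founder(self, control_params):
        assert enumerate_small_clones(control_params, 0) == {(1, 0, 0): 1.0}

    def test_single_event_reproduces_fate_mix(self, neurogenic_params):
        dist = enumerate_small_clones(neurogenic_params, 1)
        p_sym, p_asym, p_diff = neurogenic_params.effective_fate_probs()
        assert dist[(2, 0, 0)] == pytest.approx(p_sym)
        assert dist[(1, 1, 0)] == pytest.approx(p_asym)
        assert dist[(0, 2, 0)] == pytest.approx(p_diff)

    def test_forced_tree_is_deterministic(self, forced_params):
        assert enumerate_small_clones(forced_params, 3) == pytest.approx({(0, 0, 4): 1.0})

    def test_event_bound_is_enforced(self, control_params):
        with pytest.raises(ParameterError):
            enumerate_small_clones(control_params, 13)

    @pytest.mark.parametrize("max_events", [2, 3, 4])
    def test_probabilities_sum_to_one(self, neurogenic_params, max_events):
        dist = enumerate_small_clones(neurogenic_params, max_events)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_embedded_chain_matches_enumeration(self, neurogenic_params):
        n, max_events = 20_000, 3
        dist = enumerate_small_clones(neurogenic_params, max_events)
        counts = Counter()
        for i in range(n):
            clone = simulate_clone(
                neurogenic_params, 40.0, 1e9, seed=_clone_seed(77, i), max_events=max_events
            )
            counts[clone.composition()] += 1
        keys = sorted(dist)
        assert set(counts) <= set(keys)
        observed = np.array([counts.get(k, 0) for k in keys])
        expected = np.array([dist[k] * n for k in keys])
        assert chisquare(observed, expected).pvalue > 0.01


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    p_sym=st.floats(0.1, 0.8),
    p_diff_frac=st.floats(0.0, 1.0),
    k_max=st.integers(1, 4),
    p_term=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**20),
)
def test_composition_conservation_property(p_sym, p_diff_frac, k_max, p_term, seed):
    """Every division adds exactly one cell: size = 1 + events, never decreasing."""
    rest = 1.0 - p_sym
    p_diff = rest * p_diff_frac
    p_asym = rest - p_diff
    params = LineageParams(
        p_rg_sym=p_sym, p_rg_asym=p_asym, p_rg_diff=p_diff,
        k_max=k_max, p_ipc_terminal=p_term, t_switch=0.0,
    )
    clone = simulate_clone(params, 40.0, 5.0, seed=seed)
    assert clone.size == 1 + clone.n_events
    assert clone.size >= 1
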