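import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heteropd.dynamics import (
    elementary_step,
    fermi_probability,
    mcs_sweep,
    selection_probabilities,
)
from heteropd.model_core import LatticeState, SimulationParams

from .conftest import random_state


def _h_grid(neighbor_h, L=5):
    """h field whose neighbours of the centre site carry the given values."""
    h = np.zeros((L, L))
    h[1, 2], h[3, 2], h[2, 1], h[2, 3] = neighbor_h
    return h


class TestSelectionProbabilities:
    def test_alpha_zero_is_uniform(self, rng):
        h = rng.choice(np.arange(41) * 0.1, size=(5, 5))
        np.testing.assert_allclose(
            selection_probabilities(h, (2, 2), 0.0), np.full(4, 0.25)
        )

    def test_equal_h_is_uniform(self):
        p = selection_probabilities(np.full((5, 5), 1.0), (2, 2), 3.0)
        np.testing.assert_allclose(p, np.full(4, 0.25))

    def test_strong_preference_for_high_h(self):
        # exp(12)/(3 + exp(12)) and 1/(3 + exp(12)), evaluated directly
        p = selection_probabilities(_h_grid([0.0, 0.0, 0.0, 4.0]), (2, 2), 3.0)
        big = math.exp(12) / (3 + math.exp(12))
        small = 1.0 / (3 + math.exp(12))
        np.testing.assert_allclose(p, [small, small, small, big], rtol=1e-12)
        assert p[3] == pytest.approx(0.99998, abs=1e-5)

    def test_no_overflow_at_large_alpha(self):
        p = selection_probabilities(_h_grid([0.0, 0.0, 0.0, 4.0]), (2, 2), 30.0)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        hs=st.lists(st.integers(0, 40), min_size=4, max_size=4),
        alpha=st.floats(0, 50, allow_nan=False),
    )
    def test_normalized_and_positive(self, hs, alpha):
        p = selection_probabilities(_h_grid([v * 0.1 for v in hs]), (2, 2), alpha)
        assert abs(p.sum() - 1.0) < 1e-12
        assert ((p > 0) & (p <= 1)).all()


class TestFermiProbability:
    def test_equal_fitness_is_half(self):
        assert fermi_probability(2.3, 2.3, 0.1) == 0.5

    def test_large_fitness_deficit(self):
        # 1/(1 + e^-10), evaluated directly
        assert fermi_probability(0.0, 1.0, 0.1) == pytest.approx(
            1.0 / (1.0 + math.exp(-10)), rel=1e-12
        )
        assert fermi_probability(0.0, 1.0, 0.1) == pytest.approx(0.9999546, abs=1e-7)

    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        K=st.floats(0.01, 10, allow_nan=False),
    )
    def test_symmetry(self, a, b, K):
        """W(a,b) + W(b,a) = 1: one direction's gain is the other's loss."""
        assert fermi_probability(a, b, K) + fermi_probability(b, a, K) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_in_neighbor_fitness(self):
        ws = [fermi_probability(1.0, f, 0.1) for f in np.linspace(-2, 4, 25)]
        assert all(b >= a for a, b in zip(ws, ws[1:]))


class TestElementaryStep:
    def test_all_defector_lattice_is_absorbing(self, rng):
        state = random_state(rng, 6)
        state.strategies[:] = 0
        params = SimulationParams(L=6, b=1.3, u=0.3, alpha=2.0, total_mcs=10, avg_window=5)
        for _ in range(200):
            elementary_step(state, params, rng)
        assert not state.strategies.any()

    def test_event_record_is_consistent(self, rng):
        state = random_state(rng, 6)
        params = SimulationParams(L=6, b=1.2, u=0.4, alpha=1.0, total_mcs=10, avg_window=5)
        ev = elementary_step(state, params, rng, focal=(2, 3))
        assert ev.focal == (2, 3)
        dr = (ev.chosen_neighbor[0] - 2) % 6, (ev.chosen_neighbor[1] - 3) % 6
        assert dr in {(5, 0), (1, 0), (0, 5), (0, 1)}
        if ev.adopted:
            assert state.strategies[ev.focal] == state.strategies[ev.chosen_neighbor]

    def test_u1_adoption_independent_of_b(self):
        """At u=1 fitness is purely environmental, so b cannot matter."""
        base = dict(L=10, u=1.0, alpha=2.0, total_mcs=10, avg_window=5)
        trajs = {}
        for b in (1.1, 1.45):
            rng = np.random.default_rng(77)
            state = random_state(np.random.default_rng(5), 10)
            params = SimulationParams(b=b, **base)
            trajs[b] = [mcs_sweep(state, params, rng) for _ in range(5)]
        assert trajs[1.1] == trajs[1.45]


class TestMcsSweep:
    def test_all_cooperator_lattice_stays_full(self, rng):
        state = random_state(rng, 8)
        state.strategies[:] = 1
        params = SimulationParams(L=8, b=1.5, u=0.5, alpha=3.0, total_mcs=10, avg_window=5)
        for _ in range(5):
            assert mcs_sweep(state, params, rng) == 1.0

    def test_seeded_bit_reproducibility(self):
        params = SimulationParams(L=8, b=1.2, u=0.3, alpha=1.5, total_mcs=10, avg_window=5)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            state = random_state(np.random.default_rng(1), 8)
            out.append([mcs_sweep(state, params, rng) for _ in range(6)])
        assert out[0] == out[1]

    def test_compiled_and_reference_paths_are_bit_identical(self):
        """The numba kernel replays the exact random stream of the Python step."""
        params = SimulationParams(L=8, b=1.25, u=0.4, alpha=2.0, total_mcs=10, avg_window=5)
        results = {}
        for compiled in (True, False):
            rng = np.random.default_rng(2024)
            state = random_state(np.random.default_rng(3), 8)
            rhos = [mcs_sweep(state, params, rng, compiled=compiled) for _ in range(3)]
            results[compiled] = (rhos, state.strategies.copy())
        assert results[True][0] == results[False][0]
        np.testing.assert_array_equal(results[True][1], results[False][1])

    def test_rho_change_bounded_by_flip_count(self, rng):
        state = random_state(rng, 8)
        params = SimulationParams(L=8, b=1.2, u=0.2, alpha=1.0, total_mcs=10, avg_window=5)
        prev = state.rho_c()
        before = state.strategies.copy()
        rho = mcs_sweep(state, params, rng)
        flips = int((before != state.strategies).sum())
        assert abs(rho - prev) <= flips / 64 + 1e-12
        assert 0.0 <= rho <= 1.0
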