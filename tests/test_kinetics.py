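"""Kinetic network model: stationary states, cycle free energy, fluxes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretflux import (
    CiSet,
    CycleSpec,
    RateMatrix,
    average_ci,
    build_cycle_rates,
    cycle_free_energy,
    delta_g_with_errors,
    detailed_balance_residuals,
    entropy_production,
    net_flux,
    probabilities_from_rates,
    rates_from_probabilities,
    stationary_distribution,
)

RING_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0)]


def ring(rates: dict) -> RateMatrix:
    return RateMatrix.ring(rates)


def uniform_pi_driven_ring(fwd=2.0, bwd=1.0) -> RateMatrix:
    """Ring with equal forward and equal backward rates; uniform stationary pi."""
    d = {}
    for i, j in RING_EDGES:
        d[(i, j)] = fwd
        d[(j, i)] = bwd
    return ring(d)


def random_ring(rng) -> RateMatrix:
    d = {}
    for i, j in RING_EDGES:
        d[(i, j)] = rng.uniform(0.1, 3.0)
        d[(j, i)] = rng.uniform(0.1, 3.0)
    return ring(d)


# ---------------------------------------------------------------------------
# stationary distribution

def power_iteration_stationary(rates: RateMatrix, n_iter=200_000, dt=0.01):
    """Independent oracle: power iteration on the embedded transition matrix."""
    p = np.eye(rates.n_states) * (1 - dt * rates.k.sum(1)) + dt * rates.k
    pi = np.full(rates.n_states, 1.0 / rates.n_states)
    for _ in range(n_iter):
        new = pi @ p
        if np.abs(new - pi).max() < 1e-14:
            pi = new
            break
        pi = new
    return pi / pi.sum()


class TestStationaryDistribution:
    def test_symmetric_ring_is_uniform(self):
        rm = uniform_pi_driven_ring(1.0, 1.0)
        assert np.allclose(stationary_distribution(rm), 0.25)

    def test_two_state_detailed_balance(self):
        rm = RateMatrix(np.array([[0.0, 1.0], [3.0, 0.0]]))
        assert np.allclose(stationary_distribution(rm), [0.75, 0.25])

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(3):
            rm = random_ring(rng)
            pi = stationary_distribution(rm)
            assert np.allclose(pi, power_iteration_stationary(rm), atol=1e-6)

    def test_reducible_chain_names_components(self):
        k = np.zeros((4, 4))
        k[0, 1] = k[1, 0] = 1.0
        k[2, 3] = k[3, 2] = 1.0
        with pytest.raises(ValueError, match=r"\[0, 1\].*\[2, 3\]"):
            stationary_distribution(RateMatrix(k))

    def test_agrees_with_long_simulated_chain(self, db_ring):
        """Occupancy of a 10^6-step chain matches within 3 standard errors."""
        from fretflux import simulate_state_sequence
        n = 1_000_000
        seq = simulate_state_sequence(db_ring, n, frame_rate=2.0, rng=8)
        occ = np.bincount(seq, minlength=4) / n
        pi = stationary_distribution(db_ring)
        # crude SE accounting for autocorrelation via dwell length
        tau = 1.0 / (db_ring.exit_rates().min() / 2.0)
        se = np.sqrt(pi * (1 - pi) / (n / (2 * tau)))
        assert np.all(np.abs(occ - pi) < 3 * se + 1e-3)


# ---------------------------------------------------------------------------
# detailed balance and fluxes

class TestDetailedBalance:
    def test_equilibrium_two_state_residual_zero(self):
        rm = RateMatrix(np.array([[0.0, 1.0], [3.0, 0.0]]))
        res = detailed_balance_residuals(rm, np.array([0.75, 0.25]))
        assert res[(0, 1)] == pytest.approx(0.0)

    def test_uniform_pi_driven_ring_residuals(self):
        rm = uniform_pi_driven_ring(2.0, 1.0)
        res = detailed_balance_residuals(rm, np.full(4, 0.25))
        # oriented along the driven direction every edge carries 0.25/s
        oriented = [res[(0, 1)], res[(1, 2)], res[(2, 3)], -res[(0, 3)]]
        assert np.allclose(oriented, 0.25 * 2 - 0.25 * 1)

    def test_residuals_sum_to_zero_at_stationarity(self):
        rng = np.random.default_rng(5)
        rm = random_ring(rng)
        pi = stationary_distribution(rm)
        res = detailed_balance_residuals(rm, pi)
        # around the oriented ring the net gains cancel
        oriented = [res[(0, 1)], res[(1, 2)], res[(2, 3)], -res[(0, 3)]]
        # stationarity: inflow = outflow at each node
        assert np.allclose(np.diff(oriented), 0.0, atol=1e-9)


class TestNetFlux:
    def test_figure_example_net_flux_of_six(self):
        """Three-state cycle, 9 forward and 3 backward per interval -> flux 6."""
        k = np.zeros((3, 3))
        for i in range(3):
            k[i, (i + 1) % 3] = 27.0   # pi_i * k = 9 at pi = 1/3
            k[i, (i - 1) % 3] = 9.0    # pi_i * k = 3
        rm = RateMatrix(k)
        flux = net_flux(rm, np.full(3, 1 / 3))
        assert flux[(0, 1)] == pytest.approx(6.0)

    def test_detailed_balance_flux_zero(self, db_ring):
        pi = stationary_distribution(db_ring)
        flux = net_flux(db_ring, pi)
        assert all(abs(v) < 1e-12 for v in flux.values())

    def test_driven_ring_flux_equal_on_all_edges(self):
        rm = uniform_pi_driven_ring(2.0, 1.0)
        flux = net_flux(rm, np.full(4, 0.25))
        vals = [flux[(0, 1)], flux[(1, 2)], flux[(2, 3)], -flux[(0, 3)]]
        assert np.allclose(vals, 0.25)

    def test_non_stationary_pi_warns(self, db_ring):
        with pytest.warns(UserWarning, match="not stationary"):
            net_flux(db_ring, np.array([0.7, 0.1, 0.1, 0.1]))


# ---------------------------------------------------------------------------
# cycle free energy

class TestCycleFreeEnergy:
    def test_threefold_ratio_three_edge_cycle(self):
        """Forward:backward ratio of 3 on every edge of a 3-cycle: -3 ln 3."""
        k = np.zeros((3, 3))
        for i in range(3):
            k[i, (i + 1) % 3] = 3.0
            k[i, (i - 1) % 3] = 1.0
        dg = cycle_free_energy(RateMatrix(k), CycleSpec((0, 1, 2)))
        assert dg == pytest.approx(-3 * math.log(3))
        assert round(dg, 1) == -3.3

    def test_symmetric_rates_zero(self):
        rm = uniform_pi_driven_ring(1.5, 1.5)
        assert cycle_free_energy(rm) == pytest.approx(0.0)

    def test_single_unbalanced_edge_sign_convention(self):
        d = {}
        for i, j in RING_EDGES:
            d[(i, j)] = d[(j, i)] = 1.0
        d[(0, 1)], d[(1, 0)] = 1.0, 2.0
        assert cycle_free_energy(ring(d)) == pytest.approx(math.log(2))

    def test_zero_backward_rate_raises_without_floor(self):
        d = {e: 1.0 for e in RING_EDGES}
        with pytest.raises(ValueError, match="no backward transitions"):
            cycle_free_energy(ring(d))

    def test_flooring_makes_missing_backward_rates_finite(self):
        d = {e: 1.0 for e in RING_EDGES}
        dg = cycle_free_energy(ring(d), floor=1e-4)
        assert dg == pytest.approx(-4 * math.log(1.0 / 1e-4))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_reversal_antisymmetry(self, seed):
        rm = random_ring(np.random.default_rng(seed))
        cyc = CycleSpec()
        assert cycle_free_energy(rm, cyc.reversed()) == pytest.approx(
            -cycle_free_energy(rm, cyc), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_kolmogorov_criterion_equivalence(self, seed):
        """dG = 0 iff forward and backward rate products match on the ring."""
        rng = np.random.default_rng(seed)
        rm = random_ring(rng)
        fwd = np.prod([rm.k[i, j] for i, j in RING_EDGES])
        bwd = np.prod([rm.k[j, i] for i, j in RING_EDGES])
        dg = cycle_free_energy(rm)
        assert (abs(dg) < 1e-9) == (abs(math.log(fwd / bwd)) < 1e-9)
        # and an explicitly balanced matrix satisfies both
        balanced = uniform_pi_driven_ring(1.7, 1.7)
        assert abs(cycle_free_energy(balanced)) < 1e-9


# ---------------------------------------------------------------------------
# entropy production

class TestEntropyProduction:
    def test_equilibrium_zero(self, db_ring):
        pi = stationary_distribution(db_ring)
        assert entropy_production(db_ring, pi) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_driven_ring_hand_value(self):
        rm = uniform_pi_driven_ring(2.0, 1.0)
        ep = entropy_production(rm, np.full(4, 0.25))
        assert ep == pytest.approx(4 * 0.25 * math.log(2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_zero_iff_detailed_balance(self, seed):
        rng = np.random.default_rng(seed)
        rm = random_ring(rng)
        pi = stationary_distribution(rm)
        ep = entropy_production(rm, pi)
        assert ep >= 0.0
        res = detailed_balance_residuals(rm, pi)
        balanced = all(abs(v) < 1e-9 for v in res.values())
        assert (ep < 1e-12) == balanced


# ---------------------------------------------------------------------------
# constructing driven matrices and converting probabilities

class TestBuildCycleRates:
    def test_zero_target_returns_base(self, db_ring):
        assert build_cycle_rates(db_ring, 0.0) is db_ring

    def test_minus_two_scales_driven_edge(self, db_ring):
        out = build_cycle_rates(db_ring, -2.0, driven_edge=(2, 3))
        assert out.k[2, 3] == pytest.approx(db_ring.k[2, 3] * math.exp(2))
        assert cycle_free_energy(out) == pytest.approx(-2.0)

    def test_minus_ten_exact(self, db_ring):
        out = build_cycle_rates(db_ring, -10.0)
        assert cycle_free_energy(out) == pytest.approx(-10.0)

    def test_unbalanced_base_rejected(self):
        rm = uniform_pi_driven_ring(2.0, 1.0)
        with pytest.raises(ValueError, match="detailed balance"):
            build_cycle_rates(rm, -1.0)


class TestProbabilityRateConversion:
    def test_linear_conversion(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        rm = rates_from_probabilities(p, frame_rate=2.0)
        assert rm.k[0, 1] == pytest.approx(0.2)
        assert rm.k[1, 0] == pytest.approx(0.4)
        assert rm.k[0, 0] == 0.0

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            rates_from_probabilities(np.array([[1.1, -0.1], [0.2, 0.8]]), 2.0)

    def test_roundtrip_identity(self, db_ring):
        p = probabilities_from_rates(db_ring, 2.0)
        back = rates_from_probabilities(p, 2.0, db_ring.structural_zeros)
        assert np.allclose(back.k, db_ring.k, rtol=1e-12)

    def test_too_fast_rates_rejected(self):
        rm = uniform_pi_driven_ring(3.0, 2.0)   # exit 5/s
        with pytest.raises(ValueError, match="frame rate too low"):
            probabilities_from_rates(rm, 2.0)


# ---------------------------------------------------------------------------
# confidence-interval averaging and error propagation

class TestAverageCi:
    def test_two_replicates_hand_value(self):
        # (1/sqrt 2) * sqrt((9 + 16) / 1) = 5 / sqrt 2
        assert average_ci([3.0, 4.0]) == pytest.approx(5 / math.sqrt(2))

    def test_zero_lengths(self):
        assert average_ci([0.0, 0.0, 0.0]) == 0.0

    def test_five_equal_lengths(self):
        # (1/sqrt 5) * sqrt(5 * 4 / 4) = 1
        assert average_ci([2.0] * 5) == pytest.approx(1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="single replicate"):
            average_ci([2.0])

    def test_elementwise_arrays(self):
        out = average_ci([np.full((2, 2), 3.0), np.full((2, 2), 4.0)])
        assert np.allclose(out, 5 / math.sqrt(2))


class TestDeltaGWithErrors:
    def brute_force_bounds(self, rm, ci, cycle, floor=None):
        """Exhaustive enumeration over all 2^(2*edges) CI sign choices."""
        edges = cycle.edges()
        vals = []
        for signs in itertools.product((-1, 1), repeat=2 * len(edges)):
            total = 0.0
            for e, (i, j) in enumerate(edges):
                kf = rm.k[i, j] + signs[2 * e] * ci.half_widths[i, j]
                kb = rm.k[j, i] + signs[2 * e + 1] * ci.half_widths[j, i]
                if floor is not None:
                    kf, kb = max(kf, floor), max(kb, floor)
                total += math.log(kf / kb)
            vals.append(-total)
        return min(vals), max(vals)

    def test_zero_ci_collapses_bounds(self, db_ring):
        summary = delta_g_with_errors(db_ring, CiSet.zeros(4))
        assert summary.delta_g_lo == summary.delta_g == summary.delta_g_hi

    def test_symmetric_rates_symmetric_interval(self):
        rm = uniform_pi_driven_ring(1.0, 1.0)
        ci = CiSet(np.full((4, 4), 0.1))
        s = delta_g_with_errors(rm, ci)
        assert s.delta_g == pytest.approx(0.0)
        assert s.delta_g_hi == pytest.approx(-s.delta_g_lo)

    def test_bounds_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        rm = random_ring(rng)
        hw = np.zeros((4, 4))
        for i, j in RING_EDGES:
            hw[i, j] = 0.3 * rng.random() * rm.k[i, j]
            hw[j, i] = 0.3 * rng.random() * rm.k[j, i]
        ci = CiSet(hw)
        cyc = CycleSpec()
        s = delta_g_with_errors(rm, ci, cyc)
        lo, hi = self.brute_force_bounds(rm, ci, cyc)
        assert s.delta_g_lo == pytest.approx(lo, abs=1e-12)
        assert s.delta_g_hi == pytest.approx(hi, abs=1e-12)

    def test_directional_verdict_threshold(self, driven_ring):
        s = delta_g_with_errors(driven_ring, CiSet.zeros(4))
        assert s.delta_g == pytest.approx(-2.0)
        assert s.directional

    def test_ci_exceeding_rate_without_floor_raises(self, db_ring):
        ci = CiSet(np.full((4, 4), 10.0))
        with pytest.raises(ValueError, match="flooring"):
            delta_g_with_errors(db_ring, ci)


def test_rate_matrix_json_roundtrip(db_ring):
    rt = RateMatrix.from_dict(db_ring.to_dict())
    assert np.allclose(rt.k, db_ring.k)
    assert rt.structural_zeros == db_ring.structural_zeros
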