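"""Macroscopic measures, credible bands, and significant-edge detection."""

import numpy as np
import pytest

from dynising.exact import _tables, exact_moments, state_log_probs
from dynising.macro import (
    credible_band,
    entropy,
    entropy_fraction,
    evaluate_measure,
    heat_capacity,
    population_rate,
    significant_edges,
    silence_probability,
)
from dynising.params import NaturalParams, concat_block_thetas, pair_index, theta_dim
from tests.conftest import random_weak_theta


class TestPointMeasures:
    def test_population_rate_arithmetic(self):
        assert population_rate(np.array([0.2, 0.4])) == pytest.approx(0.3)
        assert population_rate(np.full(5, 0.5)) == pytest.approx(0.5)
        assert population_rate(np.zeros(3)) == 0.0

    def test_silence_probability(self, log5_model):
        assert silence_probability(0.0) == 1.0
        assert silence_probability(10 * np.log(2)) == pytest.approx(2.0 ** -10)
        m = exact_moments(log5_model)
        assert silence_probability(m.psi) == pytest.approx(0.2)

    def test_entropy_against_enumeration(self, log5_model):
        m = exact_moments(log5_model)
        S = entropy(log5_model.theta, m.eta, m.psi)
        lp = state_log_probs(log5_model)
        assert S == pytest.approx(float(-(np.exp(lp) @ lp)), abs=1e-12)
        assert S == pytest.approx(np.log(5) - 0.4 * np.log(2))

    def test_entropy_limits(self):
        assert entropy(np.zeros(theta_dim(4)), exact_moments(NaturalParams.zeros(4)).eta,
                       4 * np.log(2)) == pytest.approx(4 * np.log(2))
        # near-deterministic single neuron: entropy -> 0
        nat = NaturalParams(np.array([-50.0]), 1)
        m = exact_moments(nat)
        assert entropy(nat.theta, m.eta, m.psi) == pytest.approx(0.0, abs=1e-12)

    def test_entropy_bounds_random_model(self):
        nat = random_weak_theta(61, 6, field_sd=1.5, coupling_max=1.0)
        m = exact_moments(nat)
        S = entropy(nat.theta, m.eta, m.psi)
        assert 0.0 <= S <= 6 * np.log(2)


class TestHeatCapacity:
    def test_uniform_model_is_insensitive(self):
        assert heat_capacity(NaturalParams.zeros(3), "exact") == pytest.approx(0.0, abs=1e-8)

    def test_single_neuron_closed_form(self):
        nat = NaturalParams(np.array([1.0]), 1)
        eta = np.e / (1 + np.e)
        assert heat_capacity(nat, "exact") == pytest.approx(eta * (1 - eta), rel=1e-4)

    def test_matches_variance_of_hamiltonian(self):
        for seed in (1, 2, 3):
            nat = random_weak_theta(seed, 6, field_sd=1.0, coupling_max=0.5)
            _, F = _tables(6)
            lp = state_log_probs(nat)
            p = np.exp(lp)
            ham = F @ nat.theta
            var = float(p @ ham ** 2 - (p @ ham) ** 2)
            assert heat_capacity(nat, "exact") == pytest.approx(var, rel=1e-4)

    def test_second_order_accuracy_in_eps(self):
        nat = random_weak_theta(62, 5, field_sd=0.8)
        c1 = heat_capacity(nat, "exact", eps=1e-3)
        c2 = heat_capacity(nat, "exact", eps=5e-4)
        assert abs(c2 - c1) <= abs(c1) * 1e-4 + 1e-12


class TestEntropyFraction:
    def test_independent_model_has_zero_fraction(self):
        theta = np.concatenate([np.array([0.5, -0.5, 0.2]), np.zeros(3)])
        nat = NaturalParams(theta, 3)
        m = exact_moments(nat)
        assert entropy_fraction(nat.theta, m.eta, m.psi, 3) == pytest.approx(0.0, abs=1e-12)

    def test_log5_model_fraction(self, log5_model):
        m = exact_moments(log5_model)
        frac = entropy_fraction(log5_model.theta, m.eta, m.psi, 2)
        s_ind = -2 * (0.6 * np.log(0.6) + 0.4 * np.log(0.4))
        s_pair = np.log(5) - 0.4 * np.log(2)
        assert frac == pytest.approx((s_ind - s_pair) / s_ind)
        assert frac == pytest.approx(0.0103, abs=2e-4)

    def test_nonnegative_under_exact_moments(self):
        for seed in range(5):
            nat = random_weak_theta(seed, 5, field_sd=1.0, coupling_max=1.0)
            m = exact_moments(nat)
            assert entropy_fraction(nat.theta, m.eta, m.psi, 5) >= -1e-12


class TestExtensivity:
    def test_independent_subpopulations_add_and_multiply(self):
        blocks = [random_weak_theta(70 + k, 5, field_sd=0.5, coupling_max=0.3)
                  for k in range(3)]
        combined = NaturalParams(
            concat_block_thetas([b.theta for b in blocks], [5, 5, 5]), 15)
        ms = [exact_moments(b) for b in blocks]
        mc = exact_moments(combined)
        S_sum = sum(entropy(b.theta, m.eta, m.psi) for b, m in zip(blocks, ms))
        assert entropy(combined.theta, mc.eta, mc.psi) == pytest.approx(S_sum, abs=1e-8)
        silence_prod = np.prod([np.exp(-m.psi) for m in ms])
        assert np.exp(-mc.psi) == pytest.approx(silence_prod, rel=1e-8)
        C_sum = sum(heat_capacity(b, "exact") for b in blocks)
        assert heat_capacity(combined, "exact") == pytest.approx(C_sum, abs=1e-8)


class TestCredibleBand:
    def test_zero_covariance_band_collapses(self):
        nat = random_weak_theta(63, 3)
        theta_s = np.tile(nat.theta, (4, 1))
        W = np.zeros((4, nat.d, nat.d))
        band = credible_band(theta_s, W, 3, "entropy", "exact", n_samples=20, seed=1)
        np.testing.assert_allclose(band.lower, band.point, atol=1e-10)
        np.testing.assert_allclose(band.upper, band.point, atol=1e-10)

    def test_same_seed_identical_band(self):
        nat = random_weak_theta(64, 3)
        theta_s = np.tile(nat.theta, (3, 1))
        W = np.tile(0.01 * np.eye(nat.d), (3, 1, 1))
        b1 = credible_band(theta_s, W, 3, "silence", "exact", n_samples=30, seed=9)
        b2 = credible_band(theta_s, W, 3, "silence", "exact", n_samples=30, seed=9)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_brackets_point(self):
        nat = random_weak_theta(65, 4)
        theta_s = np.tile(nat.theta, (2, 1))
        W = np.tile(0.005 * np.eye(nat.d), (2, 1, 1))
        band = credible_band(theta_s, W, 4, "population_rate", "exact",
                             n_samples=200, seed=2)
        assert np.all(band.lower <= band.point + 1e-6)
        assert np.all(band.upper >= band.point - 1e-6)


class TestSignificantEdges:
    def test_exact_zero_never_significant(self):
        d = theta_dim(3)
        flags, _ = significant_edges(np.zeros((5, d)), np.tile(np.eye(d), (5, 1, 1)), 3)
        assert not flags.any()

    def test_normal_quantile_arithmetic(self):
        # coupling 3 with sd 1 at 98%: interval (0.674, 5.326) excludes 0
        d = theta_dim(2)
        theta_s = np.zeros((1, d))
        theta_s[0, 2] = 3.0
        W = np.tile(np.eye(d), (1, 1, 1))
        flags, pairs = significant_edges(theta_s, W, 2, level=0.98)
        assert flags[0, 0]
        theta_s[0, 2] = 2.0                          # z = 2.326 > 2 -> not significant
        flags, _ = significant_edges(theta_s, W, 2, level=0.98)
        assert not flags[0, 0]

    def test_level_one_flags_nothing(self):
        d = theta_dim(3)
        theta_s = np.full((2, d), 5.0)
        W = np.tile(0.01 * np.eye(d), (2, 1, 1))
        flags, _ = significant_edges(theta_s, W, 3, level=1.0)
        assert not flags.any()


def test_engine_evaluation_consistency():
    # approximate engines track the exact measures in the weak-coupling regime
    nat = random_weak_theta(66, 6)
    for measure in ("entropy", "silence", "population_rate"):
        ref = evaluate_measure(measure, nat.theta, 6, "exact")
        for eng in ("bethe", "tap"):
            assert evaluate_measure(measure, nat.theta, 6, eng) == pytest.approx(ref, rel=5e-3)
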