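"""Filter, smoother, marginal likelihood, EM updates, and AIC comparison."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from dynising.engines import ExactEngine
from dynising.params import theta_dim
from dynising.statespace import (
    GaussianState,
    Hyperparams,
    _lambda_update,
    aic,
    em_fit,
    filter_update,
    fit_stationary_aic,
    forward_filter,
    predict,
    smooth,
)
from dynising.synthetic import TrajectoryConfig, generate_trajectories, simulate_dataset


class TestPredict:
    def test_covariance_inflated_by_inverse_lambda(self):
        d = 3
        state = GaussianState(np.ones(d), 0.1 * np.eye(d))
        hyp = Hyperparams(lam=100.0, mu=np.zeros(d), sigma=np.eye(d))
        pred = predict(state, hyp)
        np.testing.assert_allclose(pred.cov, 0.11 * np.eye(d))
        np.testing.assert_array_equal(pred.mean, state.mean)

    def test_infinite_precision_keeps_state(self):
        state = GaussianState(np.array([0.5]), np.array([[0.2]]))
        pred = predict(state, Hyperparams(np.inf, np.zeros(1), np.eye(1)))
        np.testing.assert_array_equal(pred.cov, state.cov)


class TestFilterUpdate:
    def test_no_data_returns_prediction(self):
        d = theta_dim(2)
        pred = GaussianState(np.arange(d, dtype=float), np.eye(d))
        out, _ = filter_update(pred, np.zeros((2, 0)), ExactEngine(), "exact")
        np.testing.assert_array_equal(out.mean, pred.mean)
        np.testing.assert_array_equal(out.cov, pred.cov)

    def test_single_neuron_bernoulli_closed_form(self):
        rng = np.random.default_rng(0)
        R = 1000
        X = (rng.random((1, R)) < 0.3).astype(np.uint8)
        pred = GaussianState(np.zeros(1), 1e6 * np.eye(1))
        out, _ = filter_update(pred, X, ExactEngine(), "exact", tol=1e-10)
        p = X.mean()
        assert out.mean[0] == pytest.approx(np.log(p / (1 - p)), abs=1e-4)
        assert out.cov[0, 0] == pytest.approx(1.0 / (R * p * (1 - p)), rel=1e-2)

    def test_pseudo_and_exact_filters_agree_small_population(self):
        # evoked-activity protocol scaled down; rates sit in the 0.10-0.21
        # band where the pseudolikelihood approximation is accurate
        cfg = TrajectoryConfig(n_sub=1, n_per_sub=5, T=60, onset_bin=12,
                               tau_decay=30, seed=5)
        X, _ = simulate_dataset(generate_trajectories(cfg), 500, seed=6)
        hyp_mu = np.zeros(theta_dim(5))
        hyp_mu[:5] = -2.0
        hyp = Hyperparams.default(hyp_mu)
        f_ex, _, _ = forward_filter(X.X, hyp, ExactEngine(), "exact")
        from dynising.engines import BetheEngine
        f_be, _, _ = forward_filter(X.X, hyp, BetheEngine(), "pseudo")
        means_ex = np.stack([s.mean for s in f_ex])
        means_be = np.stack([s.mean for s in f_be])
        assert np.sqrt(np.mean((means_ex - means_be) ** 2)) < 0.05
        cov_ex = np.stack([np.diag(s.cov) for s in f_ex])
        cov_be = np.stack([np.diag(s.cov) for s in f_be])
        assert np.sqrt(np.mean((cov_ex - cov_be) ** 2)) < 0.05


class TestSmoother:
    def _run(self, lam=100.0, T=6, seed=4):
        cfg = TrajectoryConfig(n_sub=1, n_per_sub=3, T=T, seed=seed)
        X, _ = simulate_dataset(generate_trajectories(cfg), 80, seed=seed + 1)
        d = theta_dim(3)
        mu = np.zeros(d)
        mu[:3] = -2.0
        hyp = Hyperparams(lam=lam, mu=mu, sigma=10.0 * np.eye(d))
        filt, preds, _ = forward_filter(X.X, hyp, ExactEngine(), "exact")
        return filt, preds

    def test_final_bin_equals_filter(self):
        filt, preds = self._run()
        sm, _ = smooth(filt, preds)
        np.testing.assert_array_equal(sm[-1].mean, filt[-1].mean)
        np.testing.assert_array_equal(sm[-1].cov, filt[-1].cov)

    def test_smoother_variance_never_exceeds_filter_variance(self):
        filt, preds = self._run()
        sm, _ = smooth(filt, preds)
        for s, f in zip(sm, filt):
            assert np.all(np.diag(s.cov) <= np.diag(f.cov) + 1e-10)

    def test_deterministic_state_gives_constant_smoothed_means(self):
        # lambda -> inf: Q = 0, the state is constant, every smoothed mean
        # equals the final filter mean
        filt, preds = self._run(lam=np.inf)
        sm, _ = smooth(filt, preds)
        for s in sm:
            np.testing.assert_allclose(s.mean, filt[-1].mean, atol=1e-8)


class TestMarginalLikelihood:
    def test_no_data_single_bin_is_zero(self):
        d = theta_dim(2)
        hyp = Hyperparams(100.0, np.zeros(d), np.eye(d))
        _, _, mll = forward_filter(np.zeros((2, 0, 1), dtype=np.uint8), hyp,
                                   ExactEngine(), "exact")
        assert mll == 0.0

    def test_single_neuron_single_bin_matches_quadrature(self):
        # Laplace evidence vs 1-d numerical integration of the
        # Bernoulli-logistic likelihood under a Gaussian prior
        rng = np.random.default_rng(5)
        R = 400                                      # Laplace error is O(1/R)
        X = (rng.random((1, R, 1)) < 0.4).astype(np.uint8)
        k = int(X.sum())
        mu0, s2 = -0.3, 0.8
        hyp = Hyperparams(100.0, np.array([mu0]), np.array([[s2]]))
        _, _, mll = forward_filter(X, hyp, ExactEngine(), "exact", tol=1e-10)

        def log_post(th):
            ll = k * th - R * np.log1p(np.exp(th))
            pr = -0.5 * (th - mu0) ** 2 / s2 - 0.5 * np.log(2 * np.pi * s2)
            return ll + pr

        shift = max(log_post(th) for th in np.linspace(-3, 3, 601))
        evidence, _ = quad(lambda th: np.exp(log_post(th) - shift), -15, 15)
        assert mll == pytest.approx(np.log(evidence) + shift, abs=1e-3)


class TestEM:
    def test_lambda_update_closed_form(self):
        # T = 2, d = 1, <(theta_2 - theta_1)^2> = 0.04 -> lambda* = 25
        sm = [GaussianState(np.array([0.0]), np.zeros((1, 1))),
              GaussianState(np.array([0.2]), np.zeros((1, 1)))]
        cross = [np.zeros((1, 1))]
        assert _lambda_update(sm, cross) == pytest.approx(25.0)

    def test_lambda_update_includes_covariance_terms(self):
        sm = [GaussianState(np.array([0.0]), np.array([[0.01]])),
              GaussianState(np.array([0.2]), np.array([[0.01]]))]
        cross = [np.array([[0.005]])]
        # trace term: 0.04 + 0.01 + 0.01 - 2*0.005 = 0.05
        assert _lambda_update(sm, cross) == pytest.approx(20.0)

    def test_exact_em_marginal_likelihood_nondecreasing(self):
        cfg = TrajectoryConfig(n_sub=1, n_per_sub=5, T=40, seed=6)
        X, _ = simulate_dataset(generate_trajectories(cfg), 120, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(X, engine="exact", likelihood="exact",
                         em_tol=1e-7, max_em_iter=12)
        diffs = np.diff(fit.mll_trace)
        assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(fit.mll_trace[:-1])))

    def test_volatile_data_yield_smaller_lambda_than_constant_data(self):
        common = dict(n_sub=1, n_per_sub=4, T=80, seed=1)
        cfg_vol = TrajectoryConfig(field_sd=1.0, coupling_sd=0.5, kernel_scale=2,
                                   **common)
        cfg_con = TrajectoryConfig(field_sd=0.0, coupling_sd=0.0, **common)
        lams = {}
        for name, cfg in [("volatile", cfg_vol), ("constant", cfg_con)]:
            X, _ = simulate_dataset(generate_trajectories(cfg), 150, seed=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = em_fit(X, engine="exact", likelihood="exact",
                             em_tol=1e-6, max_em_iter=40)
            lams[name] = fit.hyperparams.lam
        assert lams["constant"] >= 10 * lams["volatile"]


class TestAIC:
    def test_aic_arithmetic(self):
        assert aic(-100.0, 1) == pytest.approx(202.0)

    def test_prefers_dynamic_on_dynamic_data(self):
        cfg = TrajectoryConfig(n_sub=1, n_per_sub=4, T=80, field_sd=0.6,
                               coupling_sd=0.4, kernel_scale=5, seed=1)
        X, _ = simulate_dataset(generate_trajectories(cfg), 150, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, aic_dyn, aic_stat = fit_stationary_aic(
                X, engine="exact", likelihood="exact", em_tol=1e-5, max_em_iter=25)
        assert aic_dyn < aic_stat

    def test_stationary_not_worse_on_constant_data(self):
        cfg = TrajectoryConfig(n_sub=1, n_per_sub=4, T=80, field_sd=0.0,
                               coupling_sd=0.0, seed=1)
        X, _ = simulate_dataset(generate_trajectories(cfg), 150, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, aic_dyn, aic_stat = fit_stationary_aic(
                X, engine="exact", likelihood="exact", em_tol=1e-5, max_em_iter=25)
        assert aic_stat <= aic_dyn + 2.0
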