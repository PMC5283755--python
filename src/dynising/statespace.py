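"""State-space estimation of time-varying Ising parameters.

The latent state theta_t (fields and couplings) follows a Gaussian random
walk theta_t = theta_{t-1} + xi_t, xi_t ~ N(0, Q) with Q = I / lambda, and
the observations at bin t are R i.i.d. patterns from the pairwise
maximum-entropy model p(x | theta_t).  Inference is the classic approximate
recursive scheme:

* prediction: theta_{t|t-1} = theta_{t-1|t-1}, W_{t|t-1} = W_{t-1|t-1} + Q;
* filtering: Laplace approximation around the MAP of the (pseudo-)log
  posterior, with covariance W_{t|t} = (R G_t + W_{t|t-1}^{-1})^{-1};
* fixed-interval smoothing with gain A_t = W_{t|t} W_{t+1|t}^{-1} and
  cross-covariance W_{t,t+1|T} = A_t W_{t+1|T};
* empirical-Bayes EM over the noise precision lambda and initial mean mu,
  monitored through the Laplace-approximate marginal likelihood.

The likelihood used for the MAP step is either "exact" (gradient uses the
exact expectation parameters; feasible for small populations) or "pseudo"
(the pseudolikelihood of :mod:`dynising.pseudolikelihood`).  The moment
engine ("exact" | "bethe" | "tap") supplies eta, psi, and the Fisher matrix
at the MAP point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .engines import MomentEngine, get_engine
from .params import NaturalParams, theta_dim
from .pseudolikelihood import PLObjectiveContext, _newton_polish, pl_map
from .spikedata import SpikeTensor

logger = logging.getLogger(__name__)

_JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)


def _cho_factor_jittered(A: np.ndarray):
    """Cholesky with adaptive diagonal jitter (degeneracy policy)."""
    for jit in _JITTERS:
        try:
            M = A if jit == 0.0 else A + jit * np.eye(A.shape[0])
            c = cho_factor(M, lower=True)
            if jit > 0.0:
                logger.debug("covariance solve needed jitter %g", jit)
            return c
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("matrix not positive definite even with jitter 1e-6")


def _logdet_from_cho(c) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(c[0]))))


@dataclass(frozen=True)
class GaussianState:
    """Gaussian density over the natural parameters (mean, covariance)."""

    mean: np.ndarray
    cov: np.ndarray


@dataclass
class Hyperparams:
    """State-noise precision lambda and initial-state prior N(mu, sigma).

    ``lam = inf`` encodes the stationary model (Q = 0: the prediction
    covariance is never inflated and theta_t is constant in distribution).
    """

    lam: float
    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def default(cls, mu: np.ndarray, lam: float = 100.0, sigma_scale: float = 10.0) -> "Hyperparams":
        d = len(mu)
        return cls(lam=lam, mu=np.asarray(mu, dtype=float), sigma=sigma_scale * np.eye(d))


@dataclass
class FitResult:
    """Output of a (single E-step or full EM) state-space fit."""

    n_neurons: int
    theta_filter: np.ndarray        # (T, d)
    W_filter: np.ndarray            # (T, d, d)
    theta_pred: np.ndarray          # (T, d)
    W_pred: np.ndarray              # (T, d, d)
    theta_smooth: np.ndarray        # (T, d)
    W_smooth: np.ndarray            # (T, d, d)
    cross_cov: np.ndarray           # (T-1, d, d): W_{t,t+1|T}
    marginal_ll: float
    hyperparams: Hyperparams
    engine: str
    likelihood: str
    mll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    lambda_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    em_converged: bool = True

    @property
    def T(self) -> int:
        return self.theta_filter.shape[0]


def predict(prev: GaussianState, hyp: Hyperparams) -> GaussianState:
    """One-step prediction of the random walk: mean kept, covariance inflated by Q."""
    q = 0.0 if np.isinf(hyp.lam) else 1.0 / hyp.lam
    cov = prev.cov + q * np.eye(prev.cov.shape[0])
    return GaussianState(mean=prev.mean.copy(), cov=cov)


def _suff_stats(X_t: np.ndarray) -> np.ndarray:
    """sum_r F(X^{t,r}) for one bin; X_t is (N, R)."""
    N = X_t.shape[0]
    S_fields = X_t.sum(axis=1)
    C = X_t @ X_t.T
    iu = np.triu_indices(N, k=1)
    return np.concatenate([S_fields, C[iu]])


def _exact_map(X_t: np.ndarray, pred: GaussianState, engine: MomentEngine,
               tol: float, max_iter: int) -> np.ndarray:
    """MAP of the exact-likelihood log posterior (gradient uses exact eta)."""
    N, R = X_t.shape
    S = _suff_stats(X_t)
    c = _cho_factor_jittered(pred.cov)

    def negpost(th: np.ndarray):
        psi, eta = engine.psi_eta(NaturalParams(th, N))
        delta = th - pred.mean
        solved = cho_solve(c, delta)
        f = -(float(th @ S) - R * psi - 0.5 * float(delta @ solved))
        g = -(S - R * eta - solved)
        return f, g

    res = minimize(negpost, pred.mean, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14})
    theta = res.x
    if np.max(np.abs(negpost(theta)[1])) >= tol:
        # Newton polish with the exact Hessian -(R G + W_pred^{-1})
        def hess(th):
            G = engine.moments(NaturalParams(th, N)).G
            return -(R * G + cho_solve(c, np.eye(len(th))))

        theta, _, _ = _newton_polish(
            theta,
            lambda th: -negpost(th)[1],
            hess,
            lambda th: -negpost(th)[0],
            tol,
        )
    return theta


def filter_update(pred: GaussianState, X_t: np.ndarray, engine: MomentEngine,
                  likelihood: str = "pseudo", tol: float = 1e-6,
                  max_iter: int = 500) -> tuple[GaussianState, dict]:
    """Laplace filter update at one bin.

    Returns the filter density and a dict with the pieces of the
    approximate marginal likelihood (data term, penalty, log-dets).
    """
    N, R = X_t.shape
    if R == 0:
        return GaussianState(pred.mean.copy(), pred.cov.copy()), {
            "data_term": 0.0, "penalty": 0.0,
            "logdet_filter": None, "logdet_pred": None}
    if likelihood == "pseudo":
        ctx = PLObjectiveContext(X_t, pred.mean, pred.cov)
        theta_map = pl_map(ctx, tol=tol, max_iter=max_iter).theta
    elif likelihood == "exact":
        theta_map = _exact_map(X_t, pred, engine, tol, max_iter)
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")

    m = engine.moments(NaturalParams(theta_map, N))
    c_pred = _cho_factor_jittered(pred.cov)
    d = pred.mean.shape[0]
    Wpred_inv = cho_solve(c_pred, np.eye(d))
    H = R * m.G + Wpred_inv
    c_post = _cho_factor_jittered(H)
    W_filt = cho_solve(c_post, np.eye(d))
    W_filt = 0.5 * (W_filt + W_filt.T)

    delta = theta_map - pred.mean
    S = _suff_stats(X_t)
    info = {
        "data_term": float(theta_map @ S) - R * m.psi,
        "penalty": 0.5 * float(delta @ cho_solve(c_pred, delta)),
        "logdet_filter": -_logdet_from_cho(c_post),   # log det W_{t|t}
        "logdet_pred": _logdet_from_cho(c_pred),      # log det W_{t|t-1}
    }
    return GaussianState(theta_map, W_filt), info


def forward_filter(X: np.ndarray, hyp: Hyperparams, engine: MomentEngine,
                   likelihood: str = "pseudo", tol: float = 1e-6,
                   max_iter: int = 500) -> tuple[list[GaussianState], list[GaussianState], float]:
    """Run the recursive filter over all bins.

    Returns (filter_states, prediction_states, approximate marginal
    log-likelihood).  X is the (N, R, T) binary tensor.
    """
    N, R, T = X.shape
    pred_states: list[GaussianState] = []
    filt_states: list[GaussianState] = []
    mll = 0.0
    pred = GaussianState(hyp.mu.copy(), hyp.sigma.copy())   # theta_{1|0}, W_{1|0}
    for t in range(T):
        if t > 0:
            pred = predict(filt_states[-1], hyp)
        filt, info = filter_update(pred, X[:, :, t], engine, likelihood, tol, max_iter)
        pred_states.append(pred)
        filt_states.append(filt)
        if info["logdet_filter"] is not None:
            mll += info["data_term"] - info["penalty"] \
                + 0.5 * (info["logdet_filter"] - info["logdet_pred"])
    return filt_states, pred_states, mll


def smooth(filter_states: list[GaussianState], pred_states: list[GaussianState],
           ) -> tuple[list[GaussianState], list[np.ndarray]]:
    """Fixed-interval (RTS) smoother over a completed forward pass.

    Returns the smoother states and the lag-one cross-covariances
    ``cross_cov[t] = W_{t,t+1|T}`` for t = 0..T-2.
    """
    T = len(filter_states)
    d = filter_states[0].mean.shape[0]
    sm: list[GaussianState | None] = [None] * T
    cross: list[np.ndarray | None] = [None] * (T - 1)
    sm[-1] = filter_states[-1]
    for t in range(T - 2, -1, -1):
        Wf = filter_states[t].cov
        pred_next = pred_states[t + 1]
        c = _cho_factor_jittered(pred_next.cov)
        A = cho_solve(c, Wf.T).T                     # A_t = W_{t|t} W_{t+1|t}^{-1}
        mean = filter_states[t].mean + A @ (sm[t + 1].mean - pred_next.mean)
        cov = Wf + A @ (sm[t + 1].cov - pred_next.cov) @ A.T
        cov = 0.5 * (cov + cov.T)
        sm[t] = GaussianState(mean, cov)
        cross[t] = A @ sm[t + 1].cov                 # W_{t,t+1|T}
    return sm, cross


def marginal_likelihood(fit: FitResult) -> float:
    """The Laplace-approximate marginal log-likelihood stored with the fit."""
    return fit.marginal_ll


def _initial_mu(X: np.ndarray) -> np.ndarray:
    """Independent-model fit to time/trial-averaged data, couplings zero."""
    N = X.shape[0]
    rates = X.reshape(N, -1).mean(axis=1)
    n_obs = X.shape[1] * X.shape[2]
    rates = np.clip(rates, 1.0 / (n_obs + 1.0), 1.0 - 1.0 / (n_obs + 1.0))
    mu = np.zeros(theta_dim(N))
    mu[:N] = np.log(rates / (1.0 - rates))
    return mu


def _lambda_update(sm: list[GaussianState], cross: list[np.ndarray]) -> float:
    """Closed-form M-step for the state-noise precision.

    lambda* = (T-1) d / tr sum_{t=2}^T <(theta_t - theta_{t-1})(...)'>, with
    the expectation under the smoother expanded into means, covariances and
    lag-one cross-covariances.
    """
    T = len(sm)
    d = sm[0].mean.shape[0]
    tr = 0.0
    for t in range(1, T):
        dm = sm[t].mean - sm[t - 1].mean
        tr += float(dm @ dm)
        tr += float(np.trace(sm[t].cov)) + float(np.trace(sm[t - 1].cov))
        tr -= 2.0 * float(np.trace(cross[t - 1]))
    if tr <= 0.0:
        return np.inf
    return (T - 1) * d / tr


def _states_to_result(X, filt, preds, sm, cross, mll, hyp, engine_name, likelihood,
                      mll_trace, lambda_trace, em_converged) -> FitResult:
    to_arr = lambda states, attr: np.stack([getattr(s, attr) for s in states])
    return FitResult(
        n_neurons=X.shape[0],
        theta_filter=to_arr(filt, "mean"), W_filter=to_arr(filt, "cov"),
        theta_pred=to_arr(preds, "mean"), W_pred=to_arr(preds, "cov"),
        theta_smooth=to_arr(sm, "mean"), W_smooth=to_arr(sm, "cov"),
        cross_cov=np.stack(cross) if cross else np.empty((0, len(hyp.mu), len(hyp.mu))),
        marginal_ll=mll, hyperparams=hyp, engine=engine_name, likelihood=likelihood,
        mll_trace=np.asarray(mll_trace), lambda_trace=np.asarray(lambda_trace),
        em_converged=em_converged)


def em_fit(X: SpikeTensor | np.ndarray, engine: str | MomentEngine = "bethe",
           likelihood: str = "pseudo", init: Hyperparams | None = None,
           em_tol: float = 1e-4, max_em_iter: int = 100, map_tol: float = 1e-6,
           stationary: bool = False, update_mu: bool = True) -> FitResult:
    """Empirical-Bayes EM fit of the state-space pairwise model.

    Alternates the recursive filter + smoother (E-step) with closed-form
    updates of the state-noise precision lambda and the initial mean mu
    (M-step); the initial-state covariance Sigma is held fixed.  Stops when
    the change of the approximate marginal likelihood falls below
    ``em_tol * |mll|`` or after ``max_em_iter`` iterations.

    ``stationary=True`` fixes lambda^{-1} = 0 (no state noise), turning the
    model into a stationary one; lambda is then not updated.
    """
    Xarr = X.X if isinstance(X, SpikeTensor) else np.asarray(X)
    eng = get_engine(engine)
    if init is None:
        init = Hyperparams.default(_initial_mu(Xarr))
    hyp = Hyperparams(lam=np.inf if stationary else init.lam,
                      mu=init.mu.copy(), sigma=init.sigma.copy())

    mll_trace: list[float] = []
    lambda_trace: list[float] = []
    prev_mll = -np.inf
    n_decreases = 0
    best = None
    for it in range(max_em_iter):
        filt, preds, mll = forward_filter(Xarr, hyp, eng, likelihood, tol=map_tol)
        sm, cross = smooth(filt, preds)
        mll_trace.append(mll)
        lambda_trace.append(hyp.lam)
        best = (filt, preds, sm, cross, mll,
                Hyperparams(hyp.lam, hyp.mu.copy(), hyp.sigma.copy()))

        if mll < prev_mll - 1e-8 * max(1.0, abs(prev_mll)):
            n_decreases += 1
            if n_decreases > 3 and eng.exact_fisher and likelihood == "exact":
                raise RuntimeError(
                    "marginal likelihood decreased for >3 consecutive EM iterations "
                    "with the exact engine; this indicates an implementation problem")
            if n_decreases > 3:
                warnings.warn("approximate marginal likelihood decreased repeatedly "
                              "during EM; stopping at the best iterate", RuntimeWarning)
                break
        else:
            n_decreases = 0
        if it > 0 and abs(mll - prev_mll) < em_tol * abs(mll):
            prev_mll = mll
            return _states_to_result(Xarr, filt, preds, sm, cross, mll, hyp,
                                     eng.name, likelihood, mll_trace, lambda_trace, True)
        prev_mll = mll

        # M-step
        if not stationary:
            hyp.lam = _lambda_update(sm, cross)
        if update_mu:
            hyp.mu = sm[0].mean.copy()

    filt, preds, sm, cross, mll, hyp_best = best
    warnings.warn(f"EM did not converge within {max_em_iter} iterations", RuntimeWarning)
    return _states_to_result(Xarr, filt, preds, sm, cross, mll, hyp_best,
                             eng.name, likelihood, mll_trace, lambda_trace, False)


def aic(mll: float, k: int) -> float:
    """Akaike information criterion, -2 l + 2 k."""
    return -2.0 * mll + 2 * k


def fit_stationary_aic(X: SpikeTensor | np.ndarray, engine: str | MomentEngine = "bethe",
                       likelihood: str = "pseudo", **kwargs
                       ) -> tuple[FitResult, FitResult, float, float]:
    """Fit the dynamic and the stationary (lambda^{-1} = 0) model and compare by AIC.

    Free-hyperparameter counts: the dynamic model optimizes lambda and the d
    entries of mu (k = d + 1); the stationary model only mu (k = d).  Sigma
    is fixed in both and not counted.
    """
    fit_dyn = em_fit(X, engine=engine, likelihood=likelihood, **kwargs)
    fit_stat = em_fit(X, engine=engine, likelihood=likelihood, stationary=True, **kwargs)
    d = fit_dyn.theta_smooth.shape[1]
    aic_dyn = aic(fit_dyn.marginal_ll, d + 1)
    aic_stat = aic(fit_stat.marginal_ll, d)
    return fit_dyn, fit_stat, aic_dyn, aic_stat
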