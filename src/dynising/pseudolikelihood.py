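"""Pseudolikelihood MAP estimation for one time bin of the state-space model.

The pseudolikelihood replaces the joint likelihood of a population pattern by
the product over neurons of each neuron's conditional likelihood given the
others,

    p~(x | theta) = prod_n p(x_n | x_{\\n}, theta),
    p(x_n = 1 | x_{\\n}) = sigmoid(f_n),   f_n = theta_n + sum_{j != n} theta_nj x_j,

which avoids the log partition function entirely.  Adding the Gaussian
one-step prediction density of the state-space model as a penalty gives a
concave objective whose maximizer approximates the filter mean.  Each
coupling theta_ij appears in two conditionals (n = i and n = j), so its
gradient receives both contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .params import NaturalParams, split_theta, theta_dim


def _log1pexp(f: np.ndarray) -> np.ndarray:
    # log(1 + exp(f)), stable for |f| >> 1
    return np.logaddexp(0.0, f)


def _sigmoid(f: np.ndarray) -> np.ndarray:
    out = np.empty_like(f, dtype=float)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    return out


def conditional_rate(theta: NaturalParams, x_others: np.ndarray, n: int) -> float:
    """P(x_n = 1 | x_others) under the pairwise model; x_others omits neuron n."""
    N = theta.n
    if not 0 <= n < N:
        raise ValueError(f"neuron index {n} out of range for N={N}")
    x_others = np.asarray(x_others, dtype=float)
    if x_others.shape != (N - 1,):
        raise ValueError("x_others must have length N-1")
    if not np.all((x_others == 0) | (x_others == 1)):
        raise ValueError("x_others must be binary")
    h, J = split_theta(theta.theta, N)
    x = np.insert(x_others, n, 0.0)
    f = h[n] + J[n] @ x
    return float(_sigmoid(np.array([f]))[0])


@dataclass
class PLObjectiveContext:
    """Data and Gaussian prior defining one bin's penalized pseudo-log-posterior.

    Attributes
    ----------
    X_t : (N, R) binary array of all trials at one bin.
    prior_mean : flat natural-parameter vector theta_{t|t-1}.
    prior_cov : (d, d) symmetric positive-definite prediction covariance.
    """

    X_t: np.ndarray
    prior_mean: np.ndarray
    prior_cov: np.ndarray
    _cho: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X_t = np.asarray(self.X_t, dtype=float)
        self.prior_mean = np.asarray(self.prior_mean, dtype=float)
        self.prior_cov = np.asarray(self.prior_cov, dtype=float)
        n = self.X_t.shape[0]
        if self.prior_mean.shape != (theta_dim(n),):
            raise ValueError("prior mean length inconsistent with data")

    @property
    def n(self) -> int:
        return self.X_t.shape[0]

    @property
    def n_trials(self) -> int:
        return self.X_t.shape[1]

    def prior_solve(self, v: np.ndarray) -> np.ndarray:
        """W_{t|t-1}^{-1} v via a cached Cholesky solve (never an explicit inverse)."""
        if self._cho is None:
            try:
                self._cho = cho_factor(self.prior_cov)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "prior covariance is not positive definite; "
                    "add diagonal jitter before the PL step"
                ) from err
        return cho_solve(self._cho, v)


def _conditional_fields(theta: np.ndarray, X: np.ndarray, n: int) -> np.ndarray:
    """f_n^{t,r} for all neurons/trials: (N, R) matrix h_i + sum_j J_ij X_j^r."""
    h, J = split_theta(theta, n)
    return h[:, None] + J @ X


def pl_objective(theta: np.ndarray, ctx: PLObjectiveContext) -> float:
    """Penalized pseudo-log-posterior (up to an additive constant)."""
    X = ctx.X_t
    F = _conditional_fields(theta, X, ctx.n)
    ll = float(np.sum(X * F - _log1pexp(F)))
    delta = theta - ctx.prior_mean
    return ll - 0.5 * float(delta @ ctx.prior_solve(delta))


def pl_gradient(theta: np.ndarray, ctx: PLObjectiveContext) -> np.ndarray:
    """Analytic gradient of :func:`pl_objective` with respect to theta."""
    X = ctx.X_t
    N = ctx.n
    F = _conditional_fields(theta, X, N)
    D = X - _sigmoid(F)                      # (N, R) residuals X_n - eta~_n
    grad_h = D.sum(axis=1)
    M = D @ X.T                              # M[i, j] = sum_r D_i^r X_j^r
    Gm = M + M.T                             # coupling ij: conditionals n=i and n=j
    iu = np.triu_indices(N, k=1)
    grad = np.concatenate([grad_h, Gm[iu]])
    return grad - ctx.prior_solve(theta - ctx.prior_mean)


def pl_hessian(theta: np.ndarray, ctx: PLObjectiveContext) -> np.ndarray:
    """Analytic Hessian of :func:`pl_objective` (negative definite).

    The data block decomposes into one small dense block per conditional:
    conditional n touches only field n and the couplings (n, j), so the
    full d x d Hessian is assembled from N blocks of size N.
    """
    X = ctx.X_t
    N, R = X.shape
    d = theta.shape[0]
    F = _conditional_fields(theta, X, N)
    Wgt = _sigmoid(F)
    Wgt = Wgt * (1.0 - Wgt)                  # (N, R) logistic variances
    # parameter positions touched by conditional n: field n, couplings (n, j)
    pair_pos = np.zeros((N, N), dtype=np.intp)
    iu = np.triu_indices(N, k=1)
    pair_pos[iu] = np.arange(N, d)
    pair_pos = pair_pos + pair_pos.T
    H = np.zeros((d, d))
    for nn in range(N):
        others = np.delete(np.arange(N), nn)
        U = np.concatenate([np.ones((1, R)), X[others]], axis=0)   # (N, R)
        block = (U * Wgt[nn]) @ U.T
        pos = np.concatenate([[nn], pair_pos[nn, others]])
        H[np.ix_(pos, pos)] -= block
    if ctx._cho is None:
        ctx.prior_solve(np.zeros(d))         # populate the Cholesky cache
    H -= cho_solve(ctx._cho, np.eye(d))
    return H


def _newton_polish(theta: np.ndarray, grad_fn, hess_fn, obj_fn, tol: float,
                   max_iter: int = 50) -> tuple[np.ndarray, float, bool]:
    """Safeguarded Newton ascent on a concave objective until max|grad| < tol."""
    f = obj_fn(theta)
    for _ in range(max_iter):
        g = grad_fn(theta)
        gmax = float(np.max(np.abs(g)))
        if gmax < tol:
            return theta, gmax, True
        H = hess_fn(theta)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        for _ in range(30):                  # backtracking keeps ascent monotone
            cand = theta + alpha * step
            f_cand = obj_fn(cand)
            if f_cand >= f - 1e-12 * max(1.0, abs(f)):
                theta, f = cand, f_cand
                break
            alpha *= 0.5
        else:
            break
    g = grad_fn(theta)
    return theta, float(np.max(np.abs(g))), float(np.max(np.abs(g))) < tol


@dataclass(frozen=True)
class PLMapResult:
    theta: np.ndarray
    converged: bool
    grad_max: float
    n_iter: int


def pl_map(ctx: PLObjectiveContext, tol: float = 1e-6, max_iter: int = 500,
           x0: np.ndarray | None = None) -> PLMapResult:
    """Maximize the penalized pseudo-log-posterior by quasi-Newton ascent.

    Warm-started at the prediction mean (the state is a random walk, so the
    previous filter mean is an excellent initial iterate).  Convergence is
    declared when the max-norm of the gradient falls below ``tol``.
    """
    if ctx.n_trials == 0:
        return PLMapResult(ctx.prior_mean.copy(), True, 0.0, 0)
    x0 = ctx.prior_mean if x0 is None else np.asarray(x0, dtype=float)

    res = minimize(
        lambda th: -pl_objective(th, ctx),
        x0,
        jac=lambda th: -pl_gradient(th, ctx),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14, "maxcor": 20},
    )
    theta = res.x
    grad_max = float(np.max(np.abs(pl_gradient(theta, ctx))))
    if grad_max >= tol:
        theta, grad_max, _ = _newton_polish(
            theta,
            lambda th: pl_gradient(th, ctx),
            lambda th: pl_hessian(th, ctx),
            lambda th: pl_objective(th, ctx),
            tol,
        )
    converged = grad_max < tol
    if not converged:
        warnings.warn(
            f"pl_map did not reach gradient tolerance {tol:g} "
            f"(max |grad| = {grad_max:.3g}); returning best iterate",
            RuntimeWarning,
        )
    return PLMapResult(theta, converged, grad_max, int(res.nit))
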