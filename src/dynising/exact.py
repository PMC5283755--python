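"""Exact small-population engine for the pairwise maximum-entropy model.

For populations small enough to enumerate all ``2^n`` activity patterns this
module provides the log partition function psi, the expectation parameters
eta = <F(x)>, the Fisher information G = <FF'> - eta eta', exact sampling,
and the beta-scaled free energy psi(beta) used for the heat capacity.  These
quantities serve both as the exact inference engine for n <= ~15 and as the
brute-force oracle the approximate engines (Bethe, TAP) are validated
against.

All log quantities are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .params import NaturalParams, theta_dim

#: Largest population enumerated exactly (2^20 ~ 1M states).
N_MAX_DEFAULT = 20


class CapabilityError(RuntimeError):
    """Raised when exact enumeration is requested beyond the configured size."""


@dataclass(frozen=True)
class Moments:
    """Log partition psi, expectation parameters eta, Fisher information G.

    ``G`` is the full d x d matrix for the exact engine; approximate engines
    return a diagonal matrix built from Bernoulli feature variances.
    """

    psi: float
    eta: np.ndarray
    G: np.ndarray


def features(x: np.ndarray) -> np.ndarray:
    """Feature vector F(x) = (x_1..x_n, x_1 x_2, ..., x_{n-1} x_n).

    Pair entries follow the same lexicographic i < j order as the natural
    parameters.
    """
    x = np.asarray(x)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("entries of x must be binary (0/1)")
    x = x.astype(float)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.concatenate([x, x[iu[0]] * x[iu[1]]])


@lru_cache(maxsize=8)
def _tables(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(state table (2^n, n), feature table (2^n, d)); state s has bit i = neuron i."""
    s = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
    iu = np.triu_indices(n, k=1)
    F = np.concatenate([s, s[:, iu[0]] * s[:, iu[1]]], axis=1)
    return s, F


def _check_size(n: int, n_max: int) -> None:
    if n > n_max:
        raise CapabilityError(
            f"exact enumeration over 2^{n} states exceeds n_max={n_max}; "
            "use the Bethe or TAP engine instead"
        )


def state_log_probs(theta: NaturalParams, n_max: int = N_MAX_DEFAULT) -> np.ndarray:
    """Log probability of every activity pattern, indexed by the bit code."""
    _check_size(theta.n, n_max)
    _, F = _tables(theta.n)
    logits = F @ theta.theta
    return logits - logsumexp(logits)


def exact_psi_eta(theta: NaturalParams, n_max: int = N_MAX_DEFAULT) -> tuple[float, np.ndarray]:
    """Log partition function and expectation parameters, skipping G."""
    _check_size(theta.n, n_max)
    _, F = _tables(theta.n)
    logits = F @ theta.theta
    psi = float(logsumexp(logits))
    p = np.exp(logits - psi)
    return psi, p @ F


def exact_moments(theta: NaturalParams, n_max: int = N_MAX_DEFAULT) -> Moments:
    """psi, eta and the full Fisher information by enumeration over 2^n states."""
    _check_size(theta.n, n_max)
    _, F = _tables(theta.n)
    logits = F @ theta.theta
    psi = float(logsumexp(logits))
    p = np.exp(logits - psi)
    eta = p @ F
    second = F.T @ (p[:, None] * F)
    G = second - np.outer(eta, eta)
    return Moments(psi=psi, eta=eta, G=G)


def psi_beta(theta: NaturalParams, beta: float, n_max: int = N_MAX_DEFAULT) -> float:
    """Free energy of the beta-scaled model, psi(beta) = log sum_x exp(beta theta'F)."""
    _check_size(theta.n, n_max)
    _, F = _tables(theta.n)
    return float(logsumexp(beta * (F @ theta.theta)))


def sample_states(theta: NaturalParams, size: int, rng: np.random.Generator,
                  n_max: int = N_MAX_DEFAULT) -> np.ndarray:
    """Draw ``size`` binary patterns (size, n) i.i.d. from p(x|theta)."""
    logp = state_log_probs(theta, n_max)
    idx = rng.choice(logp.shape[0], size=size, p=np.exp(logp))
    s, _ = _tables(theta.n)
    return s[idx].astype(np.uint8)


def gibbs_sample_states(theta: NaturalParams, size: int, rng: np.random.Generator,
                        burn_in_sweeps: int | None = None, thin_sweeps: int | None = None) -> np.ndarray:
    """Seeded systematic-sweep Gibbs sampler for populations too large to enumerate.

    Defaults: burn-in 100 n sweeps, thinning n sweeps between retained samples.
    """
    n = theta.n
    from .params import split_theta

    h, J = split_theta(theta.theta, n)
    burn = 100 * n if burn_in_sweeps is None else burn_in_sweeps
    thin = n if thin_sweeps is None else thin_sweeps
    x = (rng.random(n) < 0.5).astype(float)
    out = np.empty((size, n), dtype=np.uint8)

    def sweep():
        for i in range(n):
            f = h[i] + J[i] @ x
            x[i] = float(rng.random() < 1.0 / (1.0 + np.exp(-f)))

    for _ in range(burn):
        sweep()
    for k in range(size):
        for _ in range(thin):
            sweep()
        out[k] = x.astype(np.uint8)
    return out


def sample_population(theta_traj: np.ndarray, n_neurons: int, n_trials: int, seed: int,
                      n_max: int = N_MAX_DEFAULT) -> np.ndarray:
    """Sample a binary activity tensor X (n, R, T) from a theta trajectory.

    At every bin t and trial r the pattern is an independent draw from the
    instantaneous model p(x|theta_t) — the quasistatic, across-trial
    stationarity assumption.  Exact inverse-CDF sampling when n <= n_max,
    otherwise a seeded Gibbs sampler.

    Parameters
    ----------
    theta_traj : (T, d) array of natural parameters per bin.
    """
    theta_traj = np.atleast_2d(np.asarray(theta_traj, dtype=float))
    T = theta_traj.shape[0]
    if theta_traj.shape[1] != theta_dim(n_neurons):
        raise ValueError("trajectory width inconsistent with n_neurons")
    rng = np.random.default_rng(seed)
    X = np.empty((n_neurons, n_trials, T), dtype=np.uint8)
    for t in range(T):
        th = NaturalParams(theta_traj[t], n_neurons)
        if n_neurons <= n_max:
            pats = sample_states(th, n_trials, rng, n_max)
        else:
            pats = gibbs_sample_states(th, n_trials, rng)
        X[:, :, t] = pats.T
    return X
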