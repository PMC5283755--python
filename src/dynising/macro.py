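"""Time-resolved macroscopic network measures with credible bands.

From a fitted (or true) parameter vector theta_t and a moment engine, the
model yields population-level summaries:

* population spike rate  p_spike(t) = (1/N) sum_i eta_i;
* simultaneous-silence probability  p_silence(t) = exp(-psi_t);
* entropy  S(t) = -theta' eta + psi  (nats);
* heat capacity (sensitivity)  C(t) = d^2 psi / d beta^2 at beta = 1,
  evaluated by the central finite difference with step epsilon = 1e-3;
* entropy fraction  (S_ind - S_pair) / S_ind, the share of the
  independent-model entropy removed by the pairwise interactions.

Credible bands are obtained by resampling the natural parameters from the
Gaussian smoother density and taking empirical quantiles of each measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .engines import MomentEngine, get_engine
from .params import NaturalParams, pair_list

logger = logging.getLogger(__name__)

MEASURES = ("population_rate", "silence", "entropy", "heat_capacity", "entropy_fraction")


@dataclass(frozen=True)
class MacroSeries:
    """Point trajectory of one macroscopic measure with a credible band."""

    name: str
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    quantiles: tuple[float, float] = (0.01, 0.99)


def population_rate(eta1_t: np.ndarray) -> float:
    """Mean spike probability across the population at one bin."""
    return float(np.mean(eta1_t))


def silence_probability(psi_t: float) -> float:
    """Probability that no neuron spikes, exp(-psi)."""
    return float(np.exp(-psi_t))


def entropy(theta_t: np.ndarray, eta_t: np.ndarray, psi_t: float) -> float:
    """Network entropy S = -theta' eta + psi, in nats."""
    return float(-np.dot(theta_t, eta_t) + psi_t)


def heat_capacity(theta: NaturalParams, engine: str | MomentEngine, eps: float = 1e-3) -> float:
    """Variance of the information content via the beta second difference.

    C = [psi(1+eps) - 2 psi(1) + psi(1-eps)] / eps^2, each psi evaluated by
    the selected engine on the scaled model beta*theta.
    """
    eng = get_engine(engine)
    p_plus = eng.psi(theta, 1.0 + eps)
    p_0 = eng.psi(theta, 1.0)
    p_minus = eng.psi(theta, 1.0 - eps)
    return float((p_plus - 2.0 * p_0 + p_minus) / eps ** 2)


def _bernoulli_entropy(eta: np.ndarray) -> float:
    eta = np.clip(eta, 1e-15, 1 - 1e-15)
    return float(np.sum(-eta * np.log(eta) - (1 - eta) * np.log(1 - eta)))


def entropy_fraction(theta_t: np.ndarray, eta_t: np.ndarray, psi_t: float, n: int,
                     floor: float | None = None) -> float:
    """Fraction of independent-model entropy explained by the interactions.

    The independent model keeps the same rates eta_i (fields logit(eta_i),
    couplings 0); its entropy S_ind is the maximum at fixed rates, so the
    fraction is non-negative for exact moments.  With approximate engines
    slightly negative values can occur; if ``floor`` is given they are
    clipped to it (and counted in a log message), never silently.
    """
    eta1 = np.asarray(eta_t)[:n]
    if np.any(eta1 <= 0.0) or np.any(eta1 >= 1.0):
        raise ValueError("entropy_fraction needs rates strictly inside (0, 1)")
    s_ind = _bernoulli_entropy(eta1)
    if s_ind == 0.0:
        raise ValueError("independent-model entropy is zero; fraction undefined")
    s_pair = entropy(theta_t, eta_t, psi_t)
    frac = (s_ind - s_pair) / s_ind
    if floor is not None and frac < floor:
        logger.info("entropy_fraction clipped from %.3g to floor %.3g", frac, floor)
        frac = floor
    return float(frac)


def evaluate_measure(measure: str, theta: np.ndarray, n: int,
                     engine: str | MomentEngine, eps: float = 1e-3) -> float:
    """Evaluate one named macroscopic measure at a parameter vector."""
    eng = get_engine(engine)
    nat = NaturalParams(np.asarray(theta, dtype=float), n)
    if measure == "heat_capacity":
        return heat_capacity(nat, eng, eps=eps)
    psi, eta = eng.psi_eta(nat)
    if measure == "population_rate":
        return population_rate(eta[:n])
    if measure == "silence":
        return silence_probability(psi)
    if measure == "entropy":
        return entropy(nat.theta, eta, psi)
    if measure == "entropy_fraction":
        return entropy_fraction(nat.theta, eta, psi, n)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def macro_trajectory(measure: str, theta_traj: np.ndarray, n: int,
                     engine: str | MomentEngine, eps: float = 1e-3) -> np.ndarray:
    """Evaluate a measure along a (T, d) parameter trajectory."""
    eng = get_engine(engine)
    return np.array([evaluate_measure(measure, th, n, eng, eps) for th in np.atleast_2d(theta_traj)])


def credible_band(theta_smooth: np.ndarray, W_smooth: np.ndarray, n: int, measure: str,
                  engine: str | MomentEngine, n_samples: int = 100,
                  quantiles: tuple[float, float] = (0.01, 0.99), seed: int = 0,
                  use_full_cov: bool = False, eps: float = 1e-3,
                  max_failure_frac: float = 0.2) -> MacroSeries:
    """Credible band of a measure by resampling from the smoother density.

    Per bin, ``n_samples`` parameter vectors are drawn from the Gaussian
    smoother density — using the diagonal of W_{t|T} by default, the full
    covariance with ``use_full_cov=True`` — the measure is evaluated on
    each draw through the engine, and the empirical quantiles are returned.
    Draws on which the engine fails are resampled; more than
    ``max_failure_frac`` failures per bin is an error.
    """
    eng = get_engine(engine)
    theta_smooth = np.atleast_2d(np.asarray(theta_smooth, dtype=float))
    T, d = theta_smooth.shape
    rng = np.random.default_rng(seed)
    lower = np.empty(T)
    upper = np.empty(T)
    point = np.empty(T)
    max_fail = int(np.ceil(max_failure_frac * n_samples))
    for t in range(T):
        mean = theta_smooth[t]
        cov = np.asarray(W_smooth[t], dtype=float)
        if use_full_cov:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
            draw = lambda: mean + L @ rng.standard_normal(d)
        else:
            sd = np.sqrt(np.clip(np.diag(cov) if cov.ndim == 2 else cov, 0.0, None))
            draw = lambda: mean + sd * rng.standard_normal(d)
        vals = []
        n_fail = 0
        while len(vals) < n_samples:
            try:
                vals.append(evaluate_measure(measure, draw(), n, eng, eps))
            except Exception:
                n_fail += 1
                if n_fail > max_fail:
                    raise RuntimeError(
                        f"engine failed on >{max_failure_frac:.0%} of resampled "
                        f"draws at bin {t} for measure {measure!r}")
        point[t] = evaluate_measure(measure, mean, n, eng, eps)
        lower[t], upper[t] = np.quantile(vals, quantiles)
        if n_fail:
            logger.info("credible_band: %d failed draw(s) resampled at bin %d", n_fail, t)
    return MacroSeries(measure, point, lower, upper, quantiles)


def significant_edges(theta_smooth: np.ndarray, W_smooth: np.ndarray, n: int,
                      level: float = 0.98) -> tuple[np.ndarray, np.ndarray]:
    """Couplings whose central credible interval excludes zero, per bin.

    Edge (i, j) is flagged at bin t iff theta_ij,t|T +/- z * sd excludes 0,
    with z the (1+level)/2 normal quantile.  Returns (flags (T, n_pairs)
    boolean, pairs (n_pairs, 2)).
    """
    theta_smooth = np.atleast_2d(np.asarray(theta_smooth, dtype=float))
    T, d = theta_smooth.shape
    z = norm.ppf(0.5 * (1.0 + level))
    if not np.isfinite(z):
        pairs = pair_list(n)
        return np.zeros((T, len(pairs)), dtype=bool), pairs
    W = np.asarray(W_smooth, dtype=float)
    var = np.stack([np.diag(W[t]) if W[t].ndim == 2 else W[t] for t in range(T)])
    sd = np.sqrt(np.clip(var[:, n:], 0.0, None))
    coup = theta_smooth[:, n:]
    flags = np.abs(coup) > z * sd
    flags &= coup != 0.0
    return flags, pair_list(n)
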