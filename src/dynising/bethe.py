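"""Bethe approximation of marginals and free energy for the pairwise model.

The joint distribution of the fully connected binary pairwise model is
approximated by a product of consistent pairwise beliefs,

    q(x) = prod_{i<j} q(x_i, x_j) / prod_i q(x_i)^(N-2),

whose stationary points are found primarily by damped synchronous belief
propagation (BP).  On a fully connected graph BP may fail to converge; the
solver then falls back to a convergent concave-convex double-loop minimizer
of the Bethe free energy in marginal coordinates (outer quasi-Newton update
of the singleton marginals, inner closed-form solve for each pairwise
belief).  The Bethe log partition function is read off the belief assigned
to the all-silent pattern, psi = -log q(0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .params import NaturalParams, pair_list, split_theta


class BetheConvergenceError(RuntimeError):
    """Raised when neither BP nor the double-loop fallback converged."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class Beliefs:
    """Singleton and pairwise beliefs of the Bethe approximation.

    Attributes
    ----------
    q_single : (N, 2) table, q_single[i, x] = q(x_i = x).
    q_pair : (n_pairs, 2, 2) tables over lexicographic pairs i < j,
        q_pair[e, xi, xj] = q(x_i = xi, x_j = xj).
    pairs : (n_pairs, 2) index pairs matching the coupling ordering.
    """

    q_single: np.ndarray
    q_pair: np.ndarray
    pairs: np.ndarray

    @property
    def n(self) -> int:
        return self.q_single.shape[0]

    def eta(self) -> np.ndarray:
        """Expectation parameters (eta_i ..., eta_ij ...) implied by the beliefs."""
        return np.concatenate([self.q_single[:, 1], self.q_pair[:, 1, 1]])

    def consistency_residual(self) -> float:
        """Worst violation of the marginalization constraints."""
        ri = np.abs(self.q_pair.sum(axis=2) - self.q_single[self.pairs[:, 0]])
        rj = np.abs(self.q_pair.sum(axis=1) - self.q_single[self.pairs[:, 1]])
        return float(max(ri.max(initial=0.0), rj.max(initial=0.0)))


def _beliefs_from_log_messages(h: np.ndarray, J: np.ndarray, Lm: np.ndarray,
                               pairs: np.ndarray) -> Beliefs:
    n = h.shape[0]
    S = Lm.sum(axis=0)                                   # (n, 2): sum_k log m_{k->i}
    lq1 = np.stack([np.zeros(n), h], axis=1) + S
    lq1 -= logsumexp(lq1, axis=1, keepdims=True)
    i, j = pairs[:, 0], pairs[:, 1]
    # cavity terms: node potential + incoming messages except from the partner
    ci = np.stack([np.zeros(len(i)), h[i]], axis=1) + S[i] - np.moveaxis(Lm[j, i], 0, 0)
    cj = np.stack([np.zeros(len(j)), h[j]], axis=1) + S[j] - Lm[i, j]
    lq2 = ci[:, :, None] + cj[:, None, :]
    lq2[:, 1, 1] += J[i, j]
    lq2 -= logsumexp(lq2.reshape(len(i), 4), axis=1)[:, None, None]
    return Beliefs(np.exp(lq1), np.exp(lq2), pairs)


def _bp(h: np.ndarray, J: np.ndarray, pairs: np.ndarray, tol: float,
        max_iter: int, damping: float) -> tuple[Beliefs | None, float]:
    """Damped synchronous BP in log space; returns (beliefs or None, residual)."""
    n = h.shape[0]
    Lm = np.zeros((n, n, 2))                             # log m_{i->j}(x_j)
    idx = np.arange(n)
    resid = np.inf
    for _ in range(max_iter):
        S = Lm.sum(axis=0)                               # (n, 2)
        # cavity[i, j, xi] = h_i xi + sum_{k != j} log m_{k->i}(xi)
        cav = np.stack([np.zeros((n, n)), np.tile(h[:, None], (1, n))], axis=2)
        cav = cav + S[:, None, :] - np.swapaxes(Lm, 0, 1)
        # new message i->j: logsumexp over xi of cav[i,j,xi] + J_ij xi xj
        e0 = logsumexp(cav, axis=2)                      # x_j = 0 term
        e1 = logsumexp(np.stack([cav[:, :, 0], cav[:, :, 1] + J], axis=2), axis=2)
        Lnew = np.stack([e0, e1], axis=2)
        Lnew -= logsumexp(Lnew, axis=2, keepdims=True)
        Lnew[idx, idx] = 0.0
        resid = float(np.max(np.abs(np.exp(Lnew) - np.exp(Lm))))
        Lm = damping * Lm + (1.0 - damping) * Lnew
        if resid < tol:
            return _beliefs_from_log_messages(h, J, Lm, pairs), resid
    return None, resid


def _pair_belief_from_marginals(ei: np.ndarray, ej: np.ndarray, Jij: np.ndarray) -> np.ndarray:
    """Closed-form pairwise belief (e, 2, 2) consistent with given marginals.

    For binary variables the Bethe-optimal pairwise belief given marginals
    (eta_i, eta_j) satisfies q11 q00 / (q10 q01) = exp(J_ij); the joint
    probability q11 = xi solves the quadratic
    (1-a) xi^2 + [1 + (a-1)(eta_i+eta_j)] xi - a eta_i eta_j = 0, a = e^J.
    """
    a = np.exp(Jij)
    A = 1.0 - a
    b = 1.0 + (a - 1.0) * (ei + ej)
    disc = np.sqrt(np.maximum(b * b + 4.0 * A * a * ei * ej, 0.0))
    xi = 2.0 * a * ei * ej / (b + disc)                  # stable root, -> a ei ej as J -> 0
    lo = np.maximum(0.0, ei + ej - 1.0)
    hi = np.minimum(ei, ej)
    xi = np.clip(xi, lo + 1e-15, hi - 1e-15)
    q = np.empty(Jij.shape + (2, 2))
    q[..., 1, 1] = xi
    q[..., 1, 0] = ei - xi
    q[..., 0, 1] = ej - xi
    q[..., 0, 0] = 1.0 - ei - ej + xi
    return np.clip(q, 1e-15, None)


def _double_loop(h: np.ndarray, J: np.ndarray, pairs: np.ndarray, tol: float,
                 max_outer: int) -> tuple[Beliefs, float]:
    """Convergent double-loop descent of the Bethe free energy.

    Outer loop: quasi-Newton update of the singleton marginals in logit
    space.  Inner loop: exact closed-form pairwise beliefs given the
    marginals, so the marginalization constraints hold by construction at
    every iterate (concave-convex style splitting of the entropy).
    """
    n = h.shape[0]
    i, j = pairs[:, 0], pairs[:, 1]
    Jij = J[i, j]
    deg = n - 1

    def free_energy_and_grad(u: np.ndarray) -> tuple[float, np.ndarray]:
        eta = 1.0 / (1.0 + np.exp(-u))
        eta = np.clip(eta, 1e-12, 1.0 - 1e-12)
        q = _pair_belief_from_marginals(eta[i], eta[j], Jij)
        energy = -float(h @ eta) - float(Jij @ q[:, 1, 1])
        H_pair = -float(np.sum(q * np.log(q)))
        H_node = -float(np.sum(eta * np.log(eta) + (1 - eta) * np.log(1 - eta)))
        F = energy - H_pair + (deg - 1) * H_node
        # envelope theorem: pairwise beliefs are inner-optimal, so only the
        # explicit eta dependence contributes to the gradient
        lr = np.log(q[:, 1, 0] / q[:, 0, 0])
        g = -h - (deg - 1) * np.log(eta / (1 - eta))
        np.add.at(g, i, lr)
        np.add.at(g, j, np.log(q[:, 0, 1] / q[:, 0, 0]))
        return F, g * eta * (1.0 - eta)

    u0 = h.copy()
    res = minimize(free_energy_and_grad, u0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_outer, "gtol": 1e-12, "ftol": 1e-16})
    eta = 1.0 / (1.0 + np.exp(-res.x))
    q2 = _pair_belief_from_marginals(eta[i], eta[j], Jij)
    q1 = np.stack([1.0 - eta, eta], axis=1)
    beliefs = Beliefs(q1, q2, pairs)
    return beliefs, float(np.max(np.abs(res.jac)))


def bethe_marginals(theta: NaturalParams, tol: float = 1e-10, max_iter: int = 500,
                    damping: float = 0.5) -> tuple[Beliefs, str]:
    """Bethe beliefs for the fully connected pairwise binary model.

    Runs damped synchronous BP first; if the messages have not settled to
    ``tol`` within ``max_iter`` sweeps, falls back to the convergent
    double-loop minimizer.  Returns the beliefs and which method produced
    them ("bp" or "cccp").
    """
    h, J = split_theta(theta.theta, theta.n)
    pairs = pair_list(theta.n)
    if theta.n == 1:
        e = 1.0 / (1.0 + np.exp(-h[0]))
        return Beliefs(np.array([[1 - e, e]]), np.zeros((0, 2, 2)), pairs), "bp"
    beliefs, resid = _bp(h, J, pairs, tol, max_iter, damping)
    if beliefs is not None:
        return beliefs, "bp"
    beliefs, grad_resid = _double_loop(h, J, pairs, tol, max_outer=200 * max(theta.n, 10))
    if grad_resid > 1e-5:
        raise BetheConvergenceError(
            f"BP residual {resid:.3g} and double-loop gradient residual "
            f"{grad_resid:.3g}; retry with stronger damping", grad_resid)
    return beliefs, "cccp"


def bethe_psi(beliefs: Beliefs) -> float:
    """Bethe log partition function, psi = -log q(0) computed in log space."""
    n = beliefs.n
    q0_pair = beliefs.q_pair[:, 0, 0]
    q0_single = beliefs.q_single[:, 0]
    if np.any(q0_pair <= 0.0) or np.any(q0_single <= 0.0):
        raise ValueError("a belief assigns zero mass to the all-silent cell; psi undefined")
    log_q0 = float(np.sum(np.log(q0_pair)) - (n - 2) * np.sum(np.log(q0_single)))
    return -log_q0
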