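"""TAP (second-order Plefka) mean-field forward problem for {0,1} units.

The Plefka expansion of the Gibbs free energy around the independent model,
truncated at second order in the couplings, yields self-consistent
equations for the first-order expectations eta_i,

    theta_i = logit(eta_i) - sum_{j!=i} theta_ij eta_j
              - sum_{j!=i} theta_ij^2 (1/2 - eta_i)(eta_j - eta_j^2),

an approximate inverse Fisher block for the fields (the Hessian of the
Gibbs free energy in the mixture coordinates),

    [G^-1]_ij = delta_ij [1/(eta_i(1-eta_i)) + sum_k theta_ik^2 v_k]
                - theta_ij - 2 theta_ij^2 (1/2 - eta_i)(1/2 - eta_j),
    v_k = eta_k - eta_k^2,

the standard Onsager reaction terms of the second-order expansion mapped
to {0,1} variables.  Inverting G^-1 gives the pairwise expectations
eta_ij = G_ij + eta_i eta_j, and the expansion also yields the TAP free
energy psi.  Conventions: theta_ii = 0, theta_ij = theta_ji; double sums
run over ordered pairs j != i (each unordered pair twice).

The self-consistent equations may have no solution when couplings are
strong; failure is always raised explicitly (callers typically fall back to
the Bethe engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .params import NaturalParams, pair_list, split_theta


class TapConvergenceError(RuntimeError):
    """The TAP self-consistent equations could not be solved."""


@dataclass(frozen=True)
class TapSolution:
    """First/second-order expectations, field Fisher block, and free energy."""

    eta1: np.ndarray
    G_block: np.ndarray
    eta2: np.ndarray
    psi: float


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * u))


def _residual(eta: np.ndarray, h: np.ndarray, J: np.ndarray, J2: np.ndarray) -> np.ndarray:
    """Residual of the self-consistent equations in theta units."""
    eta = np.clip(eta, 1e-12, 1 - 1e-12)
    onsager = (0.5 - eta) * (J2 @ (eta - eta ** 2))
    return h - (np.log(eta / (1 - eta)) - J @ eta - onsager)


def tap_forward(theta: NaturalParams, tol: float = 1e-12, max_iter: int = 2000,
                damping: float = 0.5) -> np.ndarray:
    """Solve the TAP equations for the first-order expectations eta_i.

    Damped fixed-point iteration started at the independent-model solution
    eta_i = sigmoid(theta_i), with a Newton-type (hybr) fallback.  Raises
    :class:`TapConvergenceError` if the max residual cannot be brought
    below ``tol``.
    """
    h, J = split_theta(theta.theta, theta.n)
    J2 = J ** 2
    eta = _sigmoid(h)
    for _ in range(max_iter):
        onsager = (0.5 - eta) * (J2 @ (eta - eta ** 2))
        eta_new = _sigmoid(h + J @ eta + onsager)
        eta = damping * eta + (1.0 - damping) * eta_new
        if np.max(np.abs(_residual(eta, h, J, J2))) < tol:
            return eta
    sol = root(lambda e: _residual(e, h, J, J2), eta, method="hybr", tol=1e-14)
    eta = np.clip(sol.x, 1e-12, 1 - 1e-12)
    res = float(np.max(np.abs(_residual(eta, h, J, J2))))
    if res >= tol:
        raise TapConvergenceError(
            f"TAP self-consistent equations did not converge (residual {res:.3g}); "
            "consider the Bethe engine"
        )
    return eta


def tap_fisher(theta: NaturalParams, eta1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher block for the fields and pairwise expectations from a TAP solution.

    Builds the N x N inverse-Fisher matrix, inverts it, and returns
    ``(G_block, eta2)`` where ``eta2`` follows the coupling ordering.
    """
    h, J = split_theta(theta.theta, theta.n)
    eta1 = np.asarray(eta1, dtype=float)
    v = eta1 - eta1 ** 2
    Ginv = np.diag(1.0 / v + (J ** 2) @ v) - J - 2.0 * (J ** 2) * np.outer(0.5 - eta1, 0.5 - eta1)
    try:
        G = np.linalg.inv(Ginv)
    except np.linalg.LinAlgError as err:
        raise TapConvergenceError("TAP inverse-Fisher matrix is singular") from err
    G = 0.5 * (G + G.T)
    pairs = pair_list(theta.n)
    eta2 = G[pairs[:, 0], pairs[:, 1]] + eta1[pairs[:, 0]] * eta1[pairs[:, 1]]
    return G, eta2


def _entropy_bernoulli(eta: np.ndarray) -> np.ndarray:
    # -[eta log eta + (1-eta) log(1-eta)] with the 0 limit at the boundary
    eta = np.clip(eta, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -np.where(eta > 0, eta * np.log(eta), 0.0) \
            - np.where(eta < 1, (1 - eta) * np.log(1 - eta), 0.0)
    return s


def tap_psi(theta: NaturalParams, eta1: np.ndarray) -> float:
    """TAP free energy (approximate log partition function) at a TAP solution."""
    h, J = split_theta(theta.theta, theta.n)
    eta1 = np.asarray(eta1, dtype=float)
    v = eta1 - eta1 ** 2
    psi = float(h @ eta1)
    psi += float(np.sum(_entropy_bernoulli(eta1)))
    psi += 0.5 * float(eta1 @ J @ eta1)
    psi += 0.25 * float(v @ (J ** 2) @ v)
    return psi


def tap_solve(theta: NaturalParams, tol: float = 1e-12, max_iter: int = 2000) -> TapSolution:
    """Full TAP solution: eta1, field Fisher block, eta2, and psi."""
    eta1 = tap_forward(theta, tol=tol, max_iter=max_iter)
    G, eta2 = tap_fisher(theta, eta1)
    return TapSolution(eta1=eta1, G_block=G, eta2=eta2, psi=tap_psi(theta, eta1))
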