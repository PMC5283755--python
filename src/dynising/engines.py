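"""Pluggable moment engines: exact enumeration, Bethe, and TAP.

The state-space filter needs, at a candidate parameter vector theta, the
expectation parameters eta, the log partition function psi, and a Fisher
information matrix G for the Laplace covariance update.  The exact engine
enumerates all states and returns the full G; the Bethe and TAP engines
return approximate eta/psi and a diagonal G whose entries are the Bernoulli
feature variances eta_k (1 - eta_k).
"""

from __future__ import annotations

import numpy as np

from . import bethe as _bethe
from . import exact as _exact
from . import tap as _tap
from .exact import Moments
from .params import NaturalParams


class MomentEngine:
    """Interface shared by the exact, Bethe, and TAP engines."""

    name: str = "abstract"
    exact_fisher: bool = False

    def moments(self, theta: NaturalParams) -> Moments:
        raise NotImplementedError

    def psi(self, theta: NaturalParams, beta: float = 1.0) -> float:
        """Free energy of the (optionally beta-scaled) model."""
        raise NotImplementedError

    def psi_eta(self, theta: NaturalParams) -> tuple[float, np.ndarray]:
        m = self.moments(theta)
        return m.psi, m.eta


class ExactEngine(MomentEngine):
    """Brute-force enumeration engine; full Fisher information."""

    name = "exact"
    exact_fisher = True

    def __init__(self, n_max: int = _exact.N_MAX_DEFAULT):
        self.n_max = n_max

    def moments(self, theta: NaturalParams) -> Moments:
        return _exact.exact_moments(theta, n_max=self.n_max)

    def psi(self, theta: NaturalParams, beta: float = 1.0) -> float:
        return _exact.psi_beta(theta, beta, n_max=self.n_max)

    def psi_eta(self, theta: NaturalParams) -> tuple[float, np.ndarray]:
        return _exact.exact_psi_eta(theta, n_max=self.n_max)


def _diag_fisher(eta: np.ndarray) -> np.ndarray:
    # Bernoulli variances of all d features; keeps the Laplace covariance PD
    v = np.clip(eta * (1.0 - eta), 1e-12, None)
    return np.diag(v)


class BetheEngine(MomentEngine):
    """Belief-propagation / double-loop Bethe engine; diagonal Fisher."""

    name = "bethe"

    def __init__(self, tol: float = 1e-10, max_iter: int = 500, damping: float = 0.5):
        self.tol = tol
        self.max_iter = max_iter
        self.damping = damping
        self.n_cccp_calls = 0

    def _beliefs(self, theta: NaturalParams) -> _bethe.Beliefs:
        beliefs, method = _bethe.bethe_marginals(
            theta, tol=self.tol, max_iter=self.max_iter, damping=self.damping)
        if method == "cccp":
            self.n_cccp_calls += 1
        return beliefs

    def moments(self, theta: NaturalParams) -> Moments:
        beliefs = self._beliefs(theta)
        eta = beliefs.eta()
        return Moments(psi=_bethe.bethe_psi(beliefs), eta=eta, G=_diag_fisher(eta))

    def psi(self, theta: NaturalParams, beta: float = 1.0) -> float:
        scaled = theta if beta == 1.0 else NaturalParams(beta * theta.theta, theta.n)
        return _bethe.bethe_psi(self._beliefs(scaled))


class TapEngine(MomentEngine):
    """Second-order Plefka (TAP) engine; diagonal Fisher.

    Raises :class:`dynising.tap.TapConvergenceError` when the
    self-consistent equations cannot be solved; callers may fall back to
    the Bethe engine.
    """

    name = "tap"

    def __init__(self, tol: float = 1e-12, max_iter: int = 2000):
        self.tol = tol
        self.max_iter = max_iter

    def moments(self, theta: NaturalParams) -> Moments:
        sol = _tap.tap_solve(theta, tol=self.tol, max_iter=self.max_iter)
        eta = np.concatenate([sol.eta1, sol.eta2])
        return Moments(psi=sol.psi, eta=eta, G=_diag_fisher(eta))

    def psi(self, theta: NaturalParams, beta: float = 1.0) -> float:
        scaled = theta if beta == 1.0 else NaturalParams(beta * theta.theta, theta.n)
        eta1 = _tap.tap_forward(scaled, tol=self.tol, max_iter=self.max_iter)
        return _tap.tap_psi(scaled, eta1)


_ENGINES = {"exact": ExactEngine, "bethe": BetheEngine, "tap": TapEngine}


def get_engine(name: str | MomentEngine, **kwargs) -> MomentEngine:
    """Engine by name ("exact" | "bethe" | "tap"), or pass one through."""
    if isinstance(name, MomentEngine):
        return name
    try:
        return _ENGINES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(_ENGINES)}") from None
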