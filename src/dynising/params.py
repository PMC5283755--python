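"""Natural-parameter vectors of the pairwise maximum-entropy (Ising) model.

A population of ``n`` binary neurons is described by ``d = n + n(n-1)/2``
natural parameters: first-order fields ``theta_i`` followed by pairwise
couplings ``theta_ij`` in lexicographic ``i < j`` order,

    theta = (theta_1, ..., theta_n, theta_{1,2}, theta_{1,3}, ..., theta_{n-1,n}).

All indices here are 0-based.  Helper functions convert between the flat
vector and the (fields, symmetric coupling matrix) representation, and
assemble block-independent populations into one large vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def theta_dim(n: int) -> int:
    """Number of natural parameters for ``n`` neurons."""
    return n + n * (n - 1) // 2


def pair_list(n: int) -> np.ndarray:
    """(n_pairs, 2) array of 0-based pairs (i, j), i < j, lexicographic."""
    return np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.intp).reshape(-1, 2)


def pair_index(i: int, j: int, n: int) -> int:
    """Position of coupling (i, j), i < j, inside the coupling block."""
    if not 0 <= i < j < n:
        raise ValueError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def split_theta(theta: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat theta -> (fields (n,), symmetric coupling matrix (n, n) with zero diagonal)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (theta_dim(n),):
        raise ValueError(f"theta has shape {theta.shape}, expected ({theta_dim(n)},) for n={n}")
    h = theta[:n].copy()
    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    J[iu] = theta[n:]
    J = J + J.T
    return h, J

def join_theta(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """(fields, symmetric coupling matrix) -> flat theta vector."""
    h = np.asarray(h, dtype=float)
    J = np.asarray(J, dtype=float)
    n = h.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.concatenate([h, J[iu]])


@dataclass(frozen=True)
class NaturalParams:
    """Flat natural-parameter vector theta together with the population size."""

    theta: np.ndarray
    n: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 1 or theta.shape[0] != theta_dim(self.n):
            raise ValueError(
                f"theta has shape {np.shape(self.theta)}, expected ({theta_dim(self.n)},) for n={self.n}"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta entries must be finite")
        object.__setattr__(self, "theta", theta)

    @property
    def d(self) -> int:
        return self.theta.shape[0]

    @property
    def fields(self) -> np.ndarray:
        return self.theta[: self.n]

    @property
    def couplings(self) -> np.ndarray:
        return self.theta[self.n:]

    def coupling_matrix(self) -> np.ndarray:
        return split_theta(self.theta, self.n)[1]

    @classmethod
    def from_fields_couplings(cls, h: np.ndarray, J: np.ndarray) -> "NaturalParams":
        return cls(join_theta(h, J), len(h))

    @classmethod
    def zeros(cls, n: int) -> "NaturalParams":
        return cls(np.zeros(theta_dim(n)), n)


def concat_block_thetas(thetas: list[np.ndarray], ns: list[int]) -> np.ndarray:
    """Assemble independent subpopulations into one parameter vector.

    Parameters of different blocks are copied into the concatenated ordering;
    all between-block couplings are exactly zero.  Accepts flat vectors
    (d_k,) or trajectories (T, d_k); trajectories must share T.
    """
    if len(thetas) != len(ns):
        raise ValueError("one theta per block size required")
    arrs = [np.atleast_2d(np.asarray(th, dtype=float)) for th in thetas]
    T = arrs[0].shape[0]
    n_tot = int(np.sum(ns))
    out_h = np.zeros((T, n_tot))
    out_J = np.zeros((T, n_tot, n_tot))
    off = 0
    for arr, nk in zip(arrs, ns):
        if arr.shape != (T, theta_dim(nk)):
            raise ValueError("block shape mismatch")
        iu = np.triu_indices(nk, k=1)
        out_h[:, off:off + nk] = arr[:, :nk]
        out_J[:, off + iu[0], off + iu[1]] = arr[:, nk:]
        off += nk
    iu_tot = np.triu_indices(n_tot, k=1)
    flat = np.concatenate([out_h, out_J[:, iu_tot[0], iu_tot[1]]], axis=1)
    if np.asarray(thetas[0]).ndim == 1:
        return flat[0]
    return flat
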