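"""Spike-data handling: binning, stationarity screening, trial shuffling, I/O.

Raw data are lists of (neuron id, trial id, spike time in seconds).  They
are discretized into a binary tensor X with shape (neurons, trials, bins)
at a user-chosen bin width delta; a bin is 1 if the neuron fired at least
once in it.  Binning intervals are half-open, [t_start + k*delta,
t_start + (k+1)*delta), and all internal indices are 0-based.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: two-sided 95% normal bound used by the stationarity screen
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SpikeTensor:
    """Binary activity tensor X (N x R x T) with its bin width in seconds."""

    X: np.ndarray
    delta: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 3 or min(X.shape) < 1:
            raise ValueError("X must be a non-empty (neurons, trials, bins) array")
        if not np.all((X == 0) | (X == 1)):
            raise ValueError("X entries must be 0/1")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        object.__setattr__(self, "X", X.astype(np.uint8))

    @property
    def n_neurons(self) -> int:
        return self.X.shape[0]

    @property
    def n_trials(self) -> int:
        return self.X.shape[1]

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]


def read_spike_csv(path) -> pd.DataFrame:
    """Read a spike record table with columns ``neuron,trial,time`` (CSV/TSV)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"neuron", "trial", "time"} - set(df.columns)
    if missing:
        raise ValueError(f"spike table lacks columns: {sorted(missing)}")
    return df[["neuron", "trial", "time"]]


def bin_spikes(records, delta: float, t_start: float, t_end: float,
               n_neurons: int, n_trials: int) -> SpikeTensor:
    """Discretize spike records into a binary (N, R, T) tensor.

    ``records`` is a DataFrame with columns neuron/trial/time or an
    iterable of (neuron_id, trial_id, time) tuples.  Spikes outside
    [t_start, t_end) are dropped (and counted in a log message); multiple
    spikes in one bin collapse to 1; out-of-range ids are an error.
    """
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if not delta > 0:
        raise ValueError("delta must be positive")
    if isinstance(records, pd.DataFrame):
        neur = records["neuron"].to_numpy()
        trial = records["trial"].to_numpy()
        time = records["time"].to_numpy(dtype=float)
    else:
        rec = list(records)
        if rec:
            neur, trial, time = (np.asarray(c) for c in zip(*rec))
            time = time.astype(float)
        else:
            neur = trial = np.empty(0, dtype=int)
            time = np.empty(0, dtype=float)
    neur = neur.astype(np.int64)
    trial = trial.astype(np.int64)
    if neur.size and (neur.min() < 0 or trial.min() < 0):
        raise ValueError("neuron/trial ids must be non-negative")
    if neur.size and (neur.max() >= n_neurons or trial.max() >= n_trials):
        raise ValueError("neuron or trial id exceeds the declared sizes")
    if time.size and (not np.all(np.isfinite(time)) or time.min() < 0):
        raise ValueError("spike times must be finite and non-negative")

    T = int(np.ceil((t_end - t_start) / delta))
    in_range = (time >= t_start) & (time < t_end)
    n_dropped = int(np.sum(~in_range))
    if n_dropped:
        logger.info("bin_spikes: dropped %d spike(s) outside [%g, %g)",
                    n_dropped, t_start, t_end)
    bins = np.floor((time[in_range] - t_start) / delta).astype(np.int64)
    bins = np.minimum(bins, T - 1)          # guard against float round-up at the edge
    X = np.zeros((n_neurons, n_trials, T), dtype=np.uint8)
    X[neur[in_range], trial[in_range], bins] = 1
    return SpikeTensor(X=X, delta=float(delta), t_start=float(t_start))


def stationarity_filter(X: SpikeTensor, alpha: float = 0.05) -> tuple[SpikeTensor, list[int]]:
    """Exclude units whose per-trial rates violate across-trial stationarity.

    For each unit the per-trial mean rates are z-scored across trials using
    the unit's own mean and SD; a unit is excluded iff the fraction of
    trials with |z| beyond the two-sided 95% normal bound (1.96) exceeds
    ``alpha``.  Units with zero across-trial variance are retained by
    definition (degenerate case, logged).
    """
    if X.n_trials < 2:
        raise ValueError("stationarity screening needs at least 2 trials")
    rates = X.X.mean(axis=2)                        # (N, R) per-trial mean rates
    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0.0
    if degenerate.any():
        logger.info("stationarity_filter: %d unit(s) with zero across-trial "
                    "variance retained by definition", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (rates - mu) / sd, 0.0)
    frac_out = (np.abs(z) > _Z95).mean(axis=1)
    kept = [int(i) for i in np.flatnonzero(frac_out <= alpha)]
    if len(kept) < X.n_neurons:
        logger.info("stationarity_filter: excluded %d of %d units",
                    X.n_neurons - len(kept), X.n_neurons)
    return SpikeTensor(X.X[kept], X.delta, X.t_start), kept


def trial_shuffle(X: SpikeTensor, seed: int) -> SpikeTensor:
    """Permute trials independently per neuron (the interaction-null surrogate).

    Every neuron's per-bin across-trial spike counts (its PSTH) are exactly
    preserved, while same-trial alignment across neurons — and with it any
    genuine correlation — is destroyed.
    """
    if X.n_trials < 2:
        raise ValueError("trial shuffling needs at least 2 trials")
    rng = np.random.default_rng(seed)
    out = np.empty_like(X.X)
    for nidx in range(X.n_neurons):
        out[nidx] = X.X[nidx, rng.permutation(X.n_trials)]
    return SpikeTensor(out, X.delta, X.t_start)


def save_tensor_h5(X: SpikeTensor, path) -> None:
    """Write the tensor as HDF5 dataset ``X`` with delta/t_start attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("X", data=X.X, dtype="uint8", compression="gzip")
        ds.attrs["delta"] = X.delta
        ds.attrs["t_start"] = X.t_start


def load_tensor_h5(path) -> SpikeTensor:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["X"]
        return SpikeTensor(ds[...], float(ds.attrs["delta"]), float(ds.attrs["t_start"]))


def save_tensor_csv_gz(X: SpikeTensor, path) -> None:
    """Dense gzip-CSV dump (neuron, trial, bin, value) for small tensors."""
    n, r, t = np.nonzero(X.X)
    df = pd.DataFrame({"neuron": n, "trial": r, "bin": t})
    with gzip.open(path, "wt") as fh:
        fh.write(f"# delta={X.delta} t_start={X.t_start} "
                 f"shape={X.n_neurons}x{X.n_trials}x{X.n_bins}\n")
        df.to_csv(fh, index=False)
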