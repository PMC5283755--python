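"""HDF5 serialization of fits, ground truth, and macro series."""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import __version__
from .macro import MacroSeries
from .statespace import FitResult, Hyperparams


def save_fit_h5(fit: FitResult, path, full_cov: bool = False,
                provenance: dict | None = None) -> None:
    """Write a fit: smoothed means, variance diagonals, traces; full covariances optional."""
    with h5py.File(path, "w") as f:
        f.create_dataset("theta_smooth", data=fit.theta_smooth)
        f.create_dataset("W_diag_smooth", data=np.stack([np.diag(w) for w in fit.W_smooth]))
        f.create_dataset("theta_filter", data=fit.theta_filter)
        f.create_dataset("lambda_trace", data=fit.lambda_trace)
        f.create_dataset("mll_trace", data=fit.mll_trace)
        if full_cov:
            f.create_dataset("W_smooth", data=fit.W_smooth)
            f.create_dataset("cross_cov", data=fit.cross_cov)
        f.attrs["n_neurons"] = fit.n_neurons
        f.attrs["engine"] = fit.engine
        f.attrs["likelihood"] = fit.likelihood
        f.attrs["marginal_ll"] = fit.marginal_ll
        f.attrs["lambda"] = fit.hyperparams.lam
        f.attrs["em_converged"] = fit.em_converged
        f.attrs["package_version"] = __version__
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_fit_arrays(path) -> dict:
    """Read back the arrays and attributes written by :func:`save_fit_h5`."""
    out = {}
    with h5py.File(path, "r") as f:
        for k in f.keys():
            out[k] = f[k][...]
        out.update({k: f.attrs[k] for k in f.attrs})
    return out


def save_ground_truth_h5(truth: np.ndarray, n_neurons: int, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("ground_truth")
        g.create_dataset("theta", data=np.asarray(truth))
        g.attrs["n_neurons"] = n_neurons


def load_ground_truth_h5(path) -> tuple[np.ndarray, int]:
    with h5py.File(path, "r") as f:
        g = f["ground_truth"]
        return g["theta"][...], int(g.attrs["n_neurons"])


def save_macro_csv(series: MacroSeries, path) -> None:
    """Tidy per-measure CSV: bin, point, lower, upper."""
    import pandas as pd

    pd.DataFrame({
        "bin": np.arange(len(series.point)),
        "point": series.point,
        "lower": series.lower,
        "upper": series.upper,
    }).to_csv(path, index=False)


def save_macro_h5(series_list: list[MacroSeries], path) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group("macro")
        for s in series_list:
            if s.name in grp:
                del grp[s.name]
            g = grp.create_group(s.name)
            g.create_dataset("point", data=s.point)
            g.create_dataset("lower", data=s.lower)
            g.create_dataset("upper", data=s.upper)
            g.attrs["quantiles"] = s.quantiles
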