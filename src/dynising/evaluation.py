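"""Error metrics comparing fitted trajectories against ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ErrorReport:
    """RMSE of the natural parameters and relative errors of macro measures."""

    rmse_theta: float
    macro_errors: dict = field(default_factory=dict)


def rmse_theta(est: np.ndarray, truth: np.ndarray) -> float:
    """Time-averaged RMSE of the parameter trajectory.

    sqrt( (1/T) sum_t || theta_est_t - theta_true_t ||^2 ), with ||.|| the
    L2 norm over the d parameters.
    """
    est = np.atleast_2d(np.asarray(est, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean(np.sum((est - truth) ** 2, axis=1))))


def macro_error(est_series: np.ndarray, true_series: np.ndarray) -> float:
    """Relative error of a macroscopic measure trajectory.

    RMSE of the series divided by the time-mean of the true series.
    """
    est_series = np.asarray(est_series, dtype=float)
    true_series = np.asarray(true_series, dtype=float)
    if est_series.shape != true_series.shape:
        raise ValueError("series length mismatch")
    denom = float(np.mean(true_series))
    if denom == 0.0:
        raise ValueError("true series has zero time-mean; relative error undefined")
    rmse = float(np.sqrt(np.mean((est_series - true_series) ** 2)))
    return rmse / denom
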