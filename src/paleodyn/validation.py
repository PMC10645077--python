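"""Trajectory-simulation validation and the coefficient of prediction.

A fitted growth-rate model is judged not only by its one-step residuals but by
how well it reproduces the whole observed trajectory when iterated forward
from nothing but the first observed value and the covariate series: observed
population values never re-enter after the first step. The accuracy of the
simulated total trajectory is scored with the coefficient of prediction

    sigma^2 = 1 - sum_i (O*_i - O_i)^2 / sum_i (Obar - O_i)^2

which is 1 for a perfect prediction, 0 for a predictor no better than the
observed mean, and negative when worse than the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, ValidationError
from .models import ParameterSet, predict_growth_rate
from .proxies import GenerationTable

__all__ = ["SimulatedTrajectory", "simulate_trajectory", "coefficient_of_prediction"]


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Model-iterated log-population path on the generation grid."""

    years: np.ndarray
    X: np.ndarray  # simulated log population

    @property
    def x(self) -> np.ndarray:
        return np.exp(self.X)

    def __len__(self) -> int:
        return self.years.size


def simulate_trajectory(params: ParameterSet, table: GenerationTable) -> SimulatedTrajectory:
    """Iterate the growth model from the table's first observed value.

    ``X_0`` is the observed first log population; thereafter
    ``X_{t+1} = X_t + R(params, X_t, covariates at t)`` with covariates taken
    from the (observed, smoothed) series in the table. Observed population
    values never feed back in after t = 0.
    """
    years = table.years
    z = table.column("z_lithic")
    zw = table.column("z_warfare")
    zs = table.column("z_pollution")
    X = np.empty(years.size)
    X[0] = table.column("X")[0]
    for t in range(years.size - 1):
        X[t + 1] = X[t] + predict_growth_rate(params, X[t], z[t], zw[t], zs[t])
        # |X| > 40 can only end in float overflow: treat as collapse/runaway
        if not np.isfinite(X[t + 1]) or abs(X[t + 1]) > 40.0:
            raise DivergenceError(f"trajectory became non-finite at step {t + 1}")
    return SimulatedTrajectory(years=years, X=X)


def coefficient_of_prediction(observed, predicted) -> float:
    """1 - SSE(prediction)/SST(mean) over paired observed/predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValidationError("observed/predicted must be equal-length, size >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("coefficient of prediction undefined for constant observations")
    sse = float(np.sum((pred - obs) ** 2))
    return 1.0 - sse / sst
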