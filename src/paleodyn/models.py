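"""Competition-cooperation population-dynamic models and AICc inference.

The model family describes the per-generation logarithmic growth rate
``R_t = ln(x_{t+1}/x_t)`` of a population proxy as the balance of a Ricker
competition term and an Allee-like cooperation term, each optionally modulated
by exogenous covariates:

    R_t = R_m - (c + a0*z_t + a1*z'_t) * exp(X_t)
              - (w + b0*z''_t + b1*z'_t) * exp(-X_t)

with ``X_t = ln x_t``, ``z`` hydroclimate (lithic %), ``z'`` warfare and
``z''`` social upscaling (palaeopollution). ``R_m`` is the logarithmic mean
maximum reproductive rate, ``c`` the intensity of intra-population competition
and ``w`` the intensity of cooperation (the population size needed to overcome
exogenous hazards). The four candidate structures:

    A: endogenous only (c, w)
    B: A + hydroclimate and warfare on c        (a0, a1)
    C: B + social upscaling on w                (b0)
    D: C + warfare on w                         (b1)

Because the right-hand side is linear in the parameters given the data, the
least-squares optimum is found exactly by ordinary least squares on the
regressors {1, e^X, z e^X, z' e^X, e^-X, z'' e^-X, z' e^-X}; an iterative
nonlinear-least-squares mode is provided for parity with common practice and
converges to the same optimum. Candidate models are ranked by the
small-sample-corrected Akaike criterion (AICc) with the full Gaussian
log-likelihood, and compared through Akaike weights and per-predictor relative
importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CollinearityError, ComparisonError, ValidationError
from .proxies import GenerationTable

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "MODEL_SPECS",
    "predict_growth_rate",
    "PopulationDynamicsModel",
    "PopulationDynamicsResults",
    "FitResult",
    "fit_model",
    "aicc",
    "model_selection",
    "fit_all_models",
    "ModelComparison",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the competition (c) and cooperation (w) terms."""

    name: str
    covariates_on_c: tuple[str, ...] = ()
    covariates_on_w: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.covariates_on_c) <= {"lithic", "warfare"}:
            raise ValidationError(f"{self.name}: invalid covariates_on_c")
        if not set(self.covariates_on_w) <= {"pollution", "warfare"}:
            raise ValidationError(f"{self.name}: invalid covariates_on_w")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["R_m", "c"]
        if "lithic" in self.covariates_on_c:
            names.append("alpha0")
        if "warfare" in self.covariates_on_c:
            names.append("alpha1")
        names.append("w")
        if "pollution" in self.covariates_on_w:
            names.append("beta0")
        if "warfare" in self.covariates_on_w:
            names.append("beta1")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def predictors(self) -> frozenset[str]:
        return frozenset(self.covariates_on_c) | frozenset(self.covariates_on_w)


#: The four candidate structures, nested A within B within C within D.
MODEL_SPECS: dict[str, ModelSpec] = {
    "A": ModelSpec("A"),
    "B": ModelSpec("B", covariates_on_c=("lithic", "warfare")),
    "C": ModelSpec("C", covariates_on_c=("lithic", "warfare"), covariates_on_w=("pollution",)),
    "D": ModelSpec(
        "D",
        covariates_on_c=("lithic", "warfare"),
        covariates_on_w=("pollution", "warfare"),
    ),
}


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector; terms absent from a model stay at 0."""

    R_m: float = 0.0
    c: float = 0.0
    w: float = 0.0
    alpha0: float = 0.0
    alpha1: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "R_m": self.R_m,
            "c": self.c,
            "w": self.w,
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "beta0": self.beta0,
            "beta1": self.beta1,
        }


def predict_growth_rate(params: ParameterSet, X, z=0.0, z_war=0.0, z_soc=0.0):
    """Growth rate R for log population X and covariates (vectorised).

    ``z`` is the hydroclimate proxy, ``z_war`` warfare, ``z_soc`` social
    upscaling. With all coupling terms zero this reduces to the pure
    endogenous competition-cooperation model.
    """
    X = np.asarray(X, dtype=float)
    comp = (params.c + params.alpha0 * np.asarray(z) + params.alpha1 * np.asarray(z_war))
    coop = (params.w + params.beta0 * np.asarray(z_soc) + params.beta1 * np.asarray(z_war))
    return params.R_m - comp * np.exp(X) - coop * np.exp(-X)


def _design(spec: ModelSpec, table: GenerationTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector, regressor matrix and column labels for a model."""
    df = table.frame.iloc[:-1]  # last row has no forward growth rate
    y = df["R"].to_numpy(float)
    eX = np.exp(df["X"].to_numpy(float))
    enX = np.exp(-df["X"].to_numpy(float))
    z = df["z_lithic"].to_numpy(float)
    zw = df["z_warfare"].to_numpy(float)
    zs = df["z_pollution"].to_numpy(float)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for name in spec.param_names:
        if name == "R_m":
            cols.append(np.ones_like(y))
        elif name == "c":
            cols.append(-eX)
        elif name == "alpha0":
            cols.append(-z * eX)
        elif name == "alpha1":
            cols.append(-zw * eX)
        elif name == "w":
            cols.append(-enX)
        elif name == "beta0":
            cols.append(-zs * enX)
        elif name == "beta1":
            cols.append(-zw * enX)
        labels.append(name)
    return y, np.column_stack(cols), labels


def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample-corrected Akaike criterion from a Gaussian RSS fit.

    Uses the full Gaussian log-likelihood (constants included) with the
    residual variance counted as a parameter, K = n_params + 1:

        AICc = n*[ln(2*pi*rss/n) + 1] + 2K + 2K(K+1)/(n - K - 1)
    """
    if rss < 0:
        raise ValidationError("negative RSS")
    K = n_params + 1
    if n <= K + 1:
        raise ValidationError(
            f"AICc correction undefined: n={n} <= K+1={K + 1}"
        )
    return float(n * (np.log(2.0 * np.pi * rss / n) + 1.0) + 2 * K + 2 * K * (K + 1) / (n - K - 1))


class PopulationDynamicsModel:
    """A competition-cooperation growth-rate model bound to a generation table.

    Parameters
    ----------
    table : GenerationTable
        25-yr log-population and covariate table; the first ``len(table)-1``
        rows supply growth-rate observations.
    spec : ModelSpec or str
        Candidate structure (one of "A".."D" or a custom ModelSpec).
    """

    def __init__(self, table: GenerationTable, spec: ModelSpec | str = "D"):
        if isinstance(spec, str):
            try:
                spec = MODEL_SPECS[spec.upper()]
            except KeyError:
                raise ValidationError(f"unknown model spec '{spec}'") from None
        self.table = table
        self.spec = spec
        self.endog, self.exog, self.exog_names = _design(spec, table)
        self.nobs = self.endog.size
        if self.nobs < spec.n_params + 2:
            raise ValidationError(
                f"model {spec.name} needs >= {spec.n_params + 2} growth rates, got {self.nobs}"
            )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, spec: ModelSpec | str = "D", step: int = 25):
        return cls(GenerationTable(frame=frame, step=step), spec)

    def _check_rank(self) -> None:
        Xm = self.exog
        rank = np.linalg.matrix_rank(Xm)
        if rank < Xm.shape[1]:
            # name columns that add no rank over their predecessors
            bad = []
            r_prev = 0
            for j in range(Xm.shape[1]):
                r = np.linalg.matrix_rank(Xm[:, : j + 1])
                if r == r_prev:
                    bad.append(self.exog_names[j])
                r_prev = r
            raise CollinearityError(
                f"model {self.spec.name}: rank-deficient regressors ({', '.join(bad)})"
            )

    def fit(self, method: str = "ols") -> "PopulationDynamicsResults":
        """Least-squares fit of the growth-rate model.

        ``method="ols"`` solves the exactly-equivalent linear problem;
        ``method="nls"`` runs iterative nonlinear least squares from a zero
        start (same optimum, provided for parity with nls-style workflows).
        """
        self._check_rank()
        y, Xm = self.endog, self.exog
        if method == "ols":
            beta, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
        elif method == "nls":
            sol = least_squares(
                lambda b: Xm @ b - y, x0=np.zeros(Xm.shape[1]), method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            beta = sol.x
        else:
            raise ValidationError(f"unknown fit method '{method}'")
        resid = y - Xm @ beta
        rss = float(resid @ resid)
        n = y.size
        p = Xm.shape[1]
        sigma2 = rss / max(n - p, 1)
        xtx_inv = np.linalg.pinv(Xm.T @ Xm)
        bse = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        params = ParameterSet(**{k: float(v) for k, v in zip(self.exog_names, beta)})
        return PopulationDynamicsResults(
            model=self,
            params=params,
            params_array=beta,
            bse=bse,
            resid=resid,
            rss=rss,
        )


@dataclass
class PopulationDynamicsResults:
    """Estimates, fit diagnostics and validation hooks for one fitted model."""

    model: PopulationDynamicsModel
    params: ParameterSet
    params_array: np.ndarray
    bse: np.ndarray
    resid: np.ndarray
    rss: float
    delta_aicc: float | None = None
    akaike_weight: float | None = None
    sigma2_prediction: float | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n, self.n_params)

    def predict(self) -> np.ndarray:
        """One-step-ahead growth rates on the fitting data."""
        return self.model.exog @ self.params_array

    def simulate(self, scale: str = "log"):
        """Total-trajectory simulation from the first observed value."""
        from .validation import simulate_trajectory

        return simulate_trajectory(self.params, self.model.table)

    def coefficient_of_prediction(self, scale: str = "log") -> float:
        """Coefficient of prediction of the simulated total trajectory.

        Computed on the log-population trajectory by default (the scale the
        model is fitted on); ``scale="raw"`` scores e^X instead.
        """
        from .validation import coefficient_of_prediction

        traj = self.simulate()
        if scale == "log":
            obs, pred = self.model.table.column("X"), traj.X
        elif scale == "raw":
            obs, pred = self.model.table.column("x"), traj.x
        else:
            raise ValidationError(f"unknown scale '{scale}'")
        sig2 = coefficient_of_prediction(obs, pred)
        self.sigma2_prediction = sig2
        return sig2

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"Competition-cooperation growth model {self.spec.name}",
            f"  observations (growth rates): {self.n}",
            f"  free parameters:             {self.n_params}",
            f"  RSS:  {self.rss:.6g}",
            f"  AICc: {self.aicc:.4f}",
        ]
        if self.delta_aicc is not None:
            lines.append(f"  dAICc: {self.delta_aicc:.4f}   w_i: {self.akaike_weight:.4f}")
        if self.sigma2_prediction is not None:
            lines.append(f"  sigma2 (trajectory prediction): {self.sigma2_prediction:.4f}")
        lines.append(f"  {'param':>8} {'estimate':>14} {'std err':>12}")
        for name, est, se in zip(self.model.exog_names, self.params_array, self.bse):
            lines.append(f"  {name:>8} {est:>14.6g} {se:>12.3g}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        """One report row mirroring the standard fit-table layout."""
        d = self.params.as_dict()
        d = {"model": self.spec.name, **d}
        d["rss"] = self.rss
        d["AICc"] = self.aicc
        d["dAICc"] = self.delta_aicc
        d["w_i"] = self.akaike_weight
        d["sigma2"] = self.sigma2_prediction
        return d


#: Alias: a fitted model carries everything a fit-table row needs.
FitResult = PopulationDynamicsResults


def fit_model(spec: ModelSpec | str, table: GenerationTable, method: str = "ols") -> FitResult:
    """Fit one candidate structure to a generation table."""
    return PopulationDynamicsModel(table, spec).fit(method=method)


@dataclass
class ModelComparison:
    """AICc ranking, Akaike weights and predictor importance for one table."""

    fits: list[FitResult]
    delta_aicc: np.ndarray
    akaike_weights: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def relative_importance(self) -> dict[str, float]:
        """Per-predictor sum of Akaike weights over models containing it."""
        out: dict[str, float] = {}
        for pred in ("lithic", "warfare", "pollution"):
            out[pred] = float(
                sum(
                    w
                    for f, w in zip(self.fits, self.akaike_weights)
                    if pred in f.spec.predictors
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.to_row() for f in self.fits])

    def summary(self) -> str:
        df = self.to_frame()
        imp = self.relative_importance()
        return (
            df.to_string(index=False, float_format=lambda v: f"{v:.6g}")
            + "\n\nrelative importance: "
            + ", ".join(f"{k}={v:.3f}" for k, v in imp.items())
        )


def model_selection(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank fits by AICc and attach Akaike weights.

    All fits must come from the same table (same number of growth rates).
    Weights are w_i = exp(-d_i/2)/sum_j exp(-d_j/2) with d_i = AICc_i - min.
    Ties in ranking break by fewer parameters, then model name.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ComparisonError("need >= 2 fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ComparisonError(f"fits mix tables with different n: {sorted(ns)}")
    aiccs = np.array([f.aicc for f in fits])
    order = sorted(
        range(len(fits)), key=lambda i: (aiccs[i], fits[i].n_params, fits[i].spec.name)
    )
    fits = [fits[i] for i in order]
    aiccs = aiccs[order]
    delta = aiccs - aiccs.min()
    raw = np.exp(-0.5 * delta)
    weights = raw / raw.sum()
    for f, d, w in zip(fits, delta, weights):
        f.delta_aicc = float(d)
        f.akaike_weight = float(w)
    return ModelComparison(fits=fits, delta_aicc=delta, akaike_weights=weights)


def fit_all_models(
    table: GenerationTable,
    specs: Mapping[str, ModelSpec] = MODEL_SPECS,
    method: str = "ols",
    score_trajectories: bool = False,
    sigma2_scale: str = "log",
) -> ModelComparison:
    """Fit every candidate structure and run model selection on one table."""
    fits = [fit_model(spec, table, method=method) for spec in specs.values()]
    comp = model_selection(fits)
    if score_trajectories:
        for f in comp.fits:
            f.coefficient_of_prediction(scale=sigma2_scale)
    return comp
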