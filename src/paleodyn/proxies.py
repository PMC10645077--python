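"""Covariate series preparation and the 25-year generation table.

Three exogenous covariates feed the population models: a hydroclimate proxy
(terrestrial lithic concentration in a marine core, annually resolved), a
warfare index (skeletal-trauma frequencies scored per chrono-cultural period,
linearly interpolated to annual scale) and a social-upscaling index
(lead/mercury enrichment factors from ice cores, min-max merged). All series
are smoothed with cubic splines (``spar`` 0.65 lithic, 0.45 pollution,
0.70 warfare) and, together with the SPD population proxy, resampled at
25-year steps — one human generation — into a table of log population
``X_t``, growth rates ``R_t = X_{t+1} - X_t`` and aligned covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .smoothing import smooth_series
from .spd import SPDSeries

__all__ = [
    "ProxySeries",
    "PeriodScoreTable",
    "GenerationTable",
    "interpolate_period_scores",
    "normalize_and_merge",
    "spline_smooth",
    "build_generation_table",
    "DEFAULT_SPAR",
]

#: Spline smoothness per covariate kind.
DEFAULT_SPAR = {"lithic": 0.65, "pollution": 0.45, "conflict": 0.70}

PROXY_KINDS = ("lithic", "conflict", "pollution", "spd")


@dataclass(frozen=True)
class ProxySeries:
    """A proxy time series on calendar years AD."""

    grid: np.ndarray
    value: np.ndarray
    kind: str = "lithic"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        val = np.asarray(self.value, dtype=float)
        if grid.shape != val.shape:
            raise ValidationError("grid/value length mismatch")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValidationError("non-finite proxy value")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "value", val)

    def interp(self, years_ad) -> np.ndarray:
        return np.interp(np.asarray(years_ad, dtype=float), self.grid, self.value)

    def minmax(self) -> "ProxySeries":
        """Map values to [0, 1] by (v - min)/(max - min)."""
        lo, hi = self.value.min(), self.value.max()
        if hi == lo:
            raise ValidationError("min-max normalisation undefined for a constant series")
        return ProxySeries(self.grid, (self.value - lo) / (hi - lo), self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year_ad": self.grid, "value": self.value})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "lithic") -> "ProxySeries":
        df = pd.read_csv(path)
        return cls(df["year_ad"].to_numpy(float), df["value"].to_numpy(float), kind)


@dataclass(frozen=True)
class PeriodScoreTable:
    """Scores attached to non-overlapping chrono-cultural periods."""

    period_start: np.ndarray  # years AD
    period_end: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.period_start, dtype=float)
        e = np.asarray(self.period_end, dtype=float)
        v = np.asarray(self.score, dtype=float)
        if not (s.shape == e.shape == v.shape) or s.size == 0:
            raise ValidationError("period table needs matching, non-empty columns")
        if np.any(e <= s):
            raise ValidationError("period_end must exceed period_start")
        order = np.argsort(s)
        s, e, v = s[order], e[order], v[order]
        if np.any(s[1:] < e[:-1]):
            raise ValidationError("periods overlap")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite period score")
        object.__setattr__(self, "period_start", s)
        object.__setattr__(self, "period_end", e)
        object.__setattr__(self, "score", v)

    @classmethod
    def from_csv(cls, path) -> "PeriodScoreTable":
        df = pd.read_csv(path)
        return cls(
            df["period_start"].to_numpy(float),
            df["period_end"].to_numpy(float),
            df["score"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "period_start": self.period_start,
                "period_end": self.period_end,
                "score": self.score,
            }
        ).to_csv(path, index=False)


def interpolate_period_scores(
    table: PeriodScoreTable, kind: str = "conflict"
) -> ProxySeries:
    """Annualise period-level scores by linear interpolation between midpoints.

    Each period's score sits at its midpoint; annual values between midpoints
    come from linear interpolation and are held constant beyond the outermost
    midpoints, over the full span of the periods.
    """
    mid = 0.5 * (table.period_start + table.period_end)
    years = np.arange(np.ceil(table.period_start[0]), np.floor(table.period_end[-1]) + 1)
    vals = np.interp(years, mid, table.score)
    return ProxySeries(years, vals, kind)


def normalize_and_merge(series_a: ProxySeries, series_b: ProxySeries) -> ProxySeries:
    """Min-max normalise two series and average them on their union grid.

    The series are aligned by linear interpolation to the union of their grid
    points within the overlap of their spans; each is then mapped to [0, 1]
    and the output is the pointwise mean.
    """
    lo = max(series_a.grid[0], series_b.grid[0])
    hi = min(series_a.grid[-1], series_b.grid[-1])
    if hi <= lo:
        raise ValidationError("series do not overlap")
    grid = np.union1d(series_a.grid, series_b.grid)
    grid = grid[(grid >= lo) & (grid <= hi)]

    def _mm(s: ProxySeries) -> np.ndarray:
        v = s.interp(grid)
        if v.max() == v.min():
            raise ValidationError("min-max normalisation undefined for a constant series")
        return (v - v.min()) / (v.max() - v.min())

    return ProxySeries(grid, 0.5 * (_mm(series_a) + _mm(series_b)), series_a.kind)


def spline_smooth(
    series: ProxySeries, spar: float | None = None, lam: float | None = None
) -> ProxySeries:
    """Cubic smoothing spline of a proxy series, evaluated on its own grid."""
    return ProxySeries(
        series.grid, smooth_series(series.grid, series.value, spar=spar, lam=lam),
        series.kind,
    )


@dataclass(frozen=True)
class GenerationTable:
    """Generation-scale (25-yr) table of population and covariates.

    Columns: step index ``t``, ``year_ad``, population proxy ``x``, its log
    ``X``, growth rate ``R`` (= X_{t+1} - X_t, NaN on the last row) and the
    covariates ``z_lithic``, ``z_warfare``, ``z_pollution`` sampled at the
    same grid years.
    """

    frame: pd.DataFrame
    step: int = 25

    COLUMNS = ("t", "year_ad", "x", "X", "R", "z_lithic", "z_warfare", "z_pollution")

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"generation table missing columns {sorted(missing)}")
        years = df["year_ad"].to_numpy(float)
        if len(df) < 2 or not np.allclose(np.diff(years), self.step):
            raise ValidationError(f"rows must be spaced exactly {self.step} yr")
        if np.any(df["x"].to_numpy(float) <= 0):
            bad = int(df.loc[df["x"] <= 0, "year_ad"].iloc[0])
            raise ValidationError(f"non-positive population proxy at AD {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_rates(self) -> int:
        return len(self.frame) - 1

    @property
    def years(self) -> np.ndarray:
        return self.frame["year_ad"].to_numpy(float)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        years: np.ndarray,
        x: np.ndarray,
        z_lithic: np.ndarray,
        z_warfare: np.ndarray,
        z_pollution: np.ndarray,
        step: int = 25,
    ) -> "GenerationTable":
        years = np.asarray(years, dtype=float)
        x = np.asarray(x, dtype=float)
        X = np.log(x)
        R = np.append(np.diff(X), np.nan)
        df = pd.DataFrame(
            {
                "t": np.arange(years.size),
                "year_ad": years,
                "x": x,
                "X": X,
                "R": R,
                "z_lithic": np.asarray(z_lithic, dtype=float),
                "z_warfare": np.asarray(z_warfare, dtype=float),
                "z_pollution": np.asarray(z_pollution, dtype=float),
            }
        )
        return cls(frame=df, step=step)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, step: int = 25) -> "GenerationTable":
        return cls(frame=pd.read_csv(path), step=step)


def build_generation_table(
    spd: SPDSeries,
    lithic: ProxySeries,
    warfare: ProxySeries,
    pollution: ProxySeries,
    step: int = 25,
    window: tuple[int, int] | None = None,
) -> GenerationTable:
    """Resample the SPD and covariates at a 25-year generation grid.

    ``x_t`` is the SPD value at each grid year, ``X_t = ln x_t`` and
    ``R_t = X_{t+1} - X_t``; covariates are point-sampled at the same years
    (value "in t", matched to the growth interval that starts at t).
    """
    if window is None:
        window = (int(spd.grid[0]), int(spd.grid[-1]))
    w0, w1 = window
    years = np.arange(w0, w1 + 1, step, dtype=float)
    for s, label in ((lithic, "lithic"), (warfare, "warfare"), (pollution, "pollution")):
        if s.grid[0] > years[0] or s.grid[-1] < years[-1]:
            raise ValidationError(f"{label} series does not cover the window")
    if spd.grid[0] > years[0] or spd.grid[-1] < years[-1]:
        raise ValidationError("SPD does not cover the window")
    x = spd.sample(years)
    if np.any(x <= 0):
        bad = int(years[np.argmax(x <= 0)])
        raise ValidationError(f"non-positive SPD value at AD {bad}")
    return GenerationTable.from_arrays(
        years,
        x,
        lithic.interp(years),
        warfare.interp(years),
        pollution.interp(years),
        step=step,
    )
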