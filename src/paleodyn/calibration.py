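"""Radiocarbon calibration: dates, calibration curves, per-date densities.

Calendar convention: calculations run in calendar years BP (cal BP = 1950 - AD)
because calibration curves are published on that scale; every public grid is
expressed in years AD. Calibration follows the standard intercept-free
probabilistic method: for a date with conventional age ``a`` and lab error
``sigma``, the (unnormalised) probability mass at calendar year ``theta`` is
the Gaussian ordinate N(a; mu(theta), sqrt(sigma^2 + sigma_curve(theta)^2))
with (mu, sigma_curve) linearly interpolated from the curve knots on an annual
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ParseError, ValidationError

__all__ = [
    "RadiocarbonDate",
    "CalibrationCurve",
    "CalibratedDensity",
    "load_calibration_curve",
    "load_dates",
    "calibrate_date",
    "ad_to_calbp",
    "calbp_to_ad",
]

#: Per-tail cumulative mass trimmed from a calibrated density before
#: normalisation, bounding its support.
TAIL_MASS = 1e-5


def ad_to_calbp(year_ad):
    """Convert calendar years AD to calendar years BP (before 1950)."""
    return 1950 - np.asarray(year_ad)


def calbp_to_ad(cal_bp):
    """Convert calendar years BP to calendar years AD."""
    return 1950 - np.asarray(cal_bp)


@dataclass(frozen=True)
class RadiocarbonDate:
    """One dated sample: lab identifier, conventional age, error, site."""

    lab_id: str
    age_c14: float
    sigma: float
    site_id: str
    material: str = ""

    def __post_init__(self) -> None:
        if not self.age_c14 > 0:
            raise ValidationError(f"{self.lab_id}: age_c14 must be > 0")
        if not self.sigma > 0:
            raise ValidationError(f"{self.lab_id}: sigma must be > 0")
        if not self.site_id:
            raise ValidationError(f"{self.lab_id}: site_id must be non-empty")


@dataclass(frozen=True)
class CalibrationCurve:
    """An atmospheric calibration curve as ordered (cal BP, mu, sigma) knots.

    Between knots the curve is linearly interpolated; ``cal_bp`` is stored
    ascending regardless of file order.
    """

    cal_bp: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        cal_bp = np.asarray(self.cal_bp, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sig = np.asarray(self.sigma_curve, dtype=float)
        d = np.diff(cal_bp)
        if np.all(d < 0):  # descending file order; flip to ascending
            cal_bp, mu, sig = cal_bp[::-1], mu[::-1], sig[::-1]
        elif not np.all(d > 0):
            raise ValidationError(f"{self.name}: cal_bp knots are not strictly monotone")
        if np.any(sig < 0):
            raise ValidationError(f"{self.name}: negative curve error")
        object.__setattr__(self, "cal_bp", cal_bp)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma_curve", sig)

    @property
    def calbp_min(self) -> float:
        return float(self.cal_bp[0])

    @property
    def calbp_max(self) -> float:
        return float(self.cal_bp[-1])

    def interp(self, cal_bp) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (mu, sigma_curve) at calendar years BP."""
        cal_bp = np.asarray(cal_bp, dtype=float)
        if np.any(cal_bp < self.calbp_min) or np.any(cal_bp > self.calbp_max):
            raise CoverageError(
                f"queried cal BP outside curve coverage "
                f"[{self.calbp_min:g}, {self.calbp_max:g}]"
            )
        mu = np.interp(cal_bp, self.cal_bp, self.mu)
        sig = np.interp(cal_bp, self.cal_bp, self.sigma_curve)
        return mu, sig

    def annual_grid(self) -> np.ndarray:
        """Annual cal BP grid spanning the curve coverage."""
        return np.arange(np.ceil(self.calbp_min), np.floor(self.calbp_max) + 1.0)


@dataclass(frozen=True)
class CalibratedDensity:
    """Per-year calibrated probability mass of one date on an annual AD grid."""

    grid: np.ndarray  # calendar years AD, ascending, annual
    density: np.ndarray  # probability mass per year
    normalized: bool

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.shape != dens.shape:
            raise ValidationError("grid and density length mismatch")
        if np.any(dens < 0):
            raise ValidationError("negative density")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)

    @property
    def total_mass(self) -> float:
        return float(self.density.sum())

    def on_grid(self, grid_ad: np.ndarray) -> np.ndarray:
        """Density aligned to an arbitrary annual AD grid (zero outside support)."""
        grid_ad = np.asarray(grid_ad, dtype=float)
        out = np.zeros_like(grid_ad)
        if self.grid.size == 0:
            return out
        idx = np.searchsorted(self.grid, grid_ad)
        inside = (idx < self.grid.size) & np.isclose(
            self.grid[np.minimum(idx, self.grid.size - 1)], grid_ad
        )
        out[inside] = self.density[idx[inside]]
        return out


def load_calibration_curve(path: str | Path, name: str | None = None) -> CalibrationCurve:
    """Read a calibration curve in the standard ``.14c`` three-column layout.

    Lines starting with ``#`` are comments; data lines carry at least three
    comma- or whitespace-separated numeric columns: cal BP, conventional
    radiocarbon age BP, 1-sigma curve error.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric value ({exc})") from None
    if not rows:
        raise ParseError(f"{path.name}: no data lines")
    arr = np.asarray(rows, dtype=float)
    return CalibrationCurve(
        cal_bp=arr[:, 0], mu=arr[:, 1], sigma_curve=arr[:, 2],
        name=name or path.stem,
    )


def load_dates(path: str | Path) -> list[RadiocarbonDate]:
    """Read a radiocarbon date table (CSV, P3K14C-compatible columns).

    Required header columns: ``LabID, Age, Error, SiteID``; ``Material`` and
    any further columns are optional.
    """
    df = pd.read_csv(path)
    required = {"LabID", "Age", "Error", "SiteID"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {sorted(missing)}")
    dates = []
    for _, row in df.iterrows():
        dates.append(
            RadiocarbonDate(
                lab_id=str(row["LabID"]),
                age_c14=float(row["Age"]),
                sigma=float(row["Error"]),
                site_id=str(row["SiteID"]),
                material=str(row.get("Material", "") or ""),
            )
        )
    return dates


def save_dates(dates: Iterable[RadiocarbonDate], path: str | Path) -> None:
    """Write dates back out in the P3K14C-compatible CSV layout."""
    pd.DataFrame(
        [
            {
                "LabID": d.lab_id,
                "Age": d.age_c14,
                "Error": d.sigma,
                "SiteID": d.site_id,
                "Material": d.material,
            }
            for d in dates
        ]
    ).to_csv(path, index=False)


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    normalize: bool = True,
    tail_mass: float = TAIL_MASS,
) -> CalibratedDensity:
    """Calibrate one date against a curve on an annual calendar grid.

    The density at each calendar year is the Gaussian ordinate of the date's
    conventional age under the interpolated curve mean and the combined error
    sqrt(sigma^2 + sigma_curve^2). Support is truncated where the cumulative
    mass per tail falls below ``tail_mass``; if ``normalize`` the remaining
    mass is rescaled to 1, otherwise the raw ordinates are kept.
    """
    grid_bp = curve.annual_grid()
    mu = np.interp(grid_bp, curve.cal_bp, curve.mu)
    sig_curve = np.interp(grid_bp, curve.cal_bp, curve.sigma_curve)
    tot_sd = np.sqrt(date.sigma**2 + sig_curve**2)
    resid = date.age_c14 - mu
    # restrict evaluation to the plausible region to keep support compact
    plausible = np.abs(resid) <= 8.0 * tot_sd
    if not plausible.any():
        raise CoverageError(
            f"{date.lab_id}: age {date.age_c14:g} +/- {date.sigma:g} BP lies outside "
            f"coverage of curve '{curve.name}'"
        )
    dens = np.zeros_like(grid_bp)
    dens[plausible] = np.exp(-0.5 * (resid[plausible] / tot_sd[plausible]) ** 2) / (
        np.sqrt(2.0 * np.pi) * tot_sd[plausible]
    )
    total = dens.sum()
    if total <= 0:
        raise CoverageError(f"{date.lab_id}: zero calibrated mass on curve '{curve.name}'")
    # trim tails at cumulative mass `tail_mass` per side, before normalisation
    cum = np.cumsum(dens)
    lo = np.searchsorted(cum, tail_mass * total, side="left")
    hi = np.searchsorted(cum, (1.0 - tail_mass) * total, side="right")
    hi = min(hi + 1, dens.size)
    grid_bp, dens = grid_bp[lo:hi], dens[lo:hi]
    if normalize:
        dens = dens / dens.sum()
    # flip to ascending years AD
    grid_ad = calbp_to_ad(grid_bp)[::-1].copy()
    dens = dens[::-1].copy()
    return CalibratedDensity(grid=grid_ad, density=dens, normalized=normalize)
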