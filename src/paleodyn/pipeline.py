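"""End-to-end orchestration: dates + proxies -> SPDs -> fits -> report.

One call (or ``paleodyn run`` from the shell) takes a radiocarbon date table,
a calibration curve and the covariate inputs, builds both SPD normalisation
variants, fits the four candidate models to each, runs per-variant AICc model
selection, scores total-trajectory predictions, and writes a fit table in the
standard layout (model, parameters, AICc, dAICc, w_i, sigma2) with models
suffixed 1 (unnormalised SPD) and 2 (normalised SPD).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .calibration import load_calibration_curve, load_dates
from .errors import PaleodynError
from .proxies import (
    DEFAULT_SPAR,
    GenerationTable,
    PeriodScoreTable,
    ProxySeries,
    build_generation_table,
    interpolate_period_scores,
    normalize_and_merge,
    spline_smooth,
)
from .models import ModelComparison, fit_all_models
from .spd import SPDSeries, bin_dates, build_spd

__all__ = ["PipelineConfig", "run_pipeline", "load_covariate"]

log = logging.getLogger("paleodyn")


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters for a full pipeline run."""

    window: tuple[int, int] = (100, 1450)
    bin_cut: float = 50.0
    rolling_window: int = 100
    step: int = 25
    spar: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPAR))
    variants: tuple[str, ...] = ("unnormalized", "normalized")
    sigma2_scale: str = "log"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["variants"] = list(self.variants)
        d["spar"] = dict(self.spar)
        return d


def load_covariate(
    paths: Sequence[str | Path] | str | Path, kind: str
) -> ProxySeries:
    """Load one covariate from one or two CSVs, merging a pair min-max.

    Each file is either an annual series (header ``year_ad,value``) or a
    period-score table (header ``period_start,period_end,score``), the latter
    annualised by midpoint linear interpolation first. Two files are min-max
    normalised and averaged on their union grid.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    series = []
    for p in paths:
        cols = set(pd.read_csv(p, nrows=0).columns)
        if {"period_start", "period_end", "score"} <= cols:
            series.append(interpolate_period_scores(PeriodScoreTable.from_csv(p), kind))
        elif {"year_ad", "value"} <= cols:
            series.append(ProxySeries.from_csv(p, kind))
        else:
            raise PaleodynError(f"{p}: unrecognised covariate layout (columns {sorted(cols)})")
    if len(series) == 1:
        return series[0]
    if len(series) == 2:
        return normalize_and_merge(series[0], series[1])
    raise PaleodynError(f"{kind}: expected 1 or 2 files, got {len(series)}")


def run_pipeline(
    config: PipelineConfig,
    dates_path: str | Path,
    curve_path: str | Path,
    lithic_paths: Sequence[str | Path] | str | Path,
    warfare_paths: Sequence[str | Path] | str | Path,
    pollution_paths: Sequence[str | Path] | str | Path,
    spd_paths: Mapping[str, str | Path] | None = None,
    out: str | Path | None = None,
) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    ``spd_paths`` may supply precomputed SPD CSVs per variant, bypassing
    calibration. The returned dict carries the SPD series, generation tables
    and :class:`ModelComparison` per variant plus the combined fit table.
    """

    def stage(name: str):
        log.info("stage %s", name)

    try:
        stage("load")
        spds: dict[str, SPDSeries] = {}
        if spd_paths:
            for variant, p in spd_paths.items():
                spds[variant] = SPDSeries.from_csv(p, normalized=(variant == "normalized"))
        else:
            curve = load_calibration_curve(curve_path)
            dates = load_dates(dates_path)
            log.info("loaded %d dates", len(dates))
            stage("bin")
            bins = bin_dates(dates, cut_height=config.bin_cut)
            log.info("%d bins (cut %.0f yr)", len(bins), config.bin_cut)
            stage("spd")
            for variant in config.variants:
                spds[variant] = build_spd(
                    bins,
                    curve,
                    window=config.window,
                    rolling_window=config.rolling_window,
                    normalize=(variant == "normalized"),
                )
        stage("proxies")
        covs = {}
        for kind, paths in (
            ("lithic", lithic_paths),
            ("conflict", warfare_paths),
            ("pollution", pollution_paths),
        ):
            raw = load_covariate(paths, kind)
            covs[kind] = spline_smooth(raw, spar=config.spar[kind])
            log.info("%s: %d points, spar %.2f", kind, len(raw.grid), config.spar[kind])
        stage("generation tables")
        tables: dict[str, GenerationTable] = {}
        for variant, spd in spds.items():
            tables[variant] = build_generation_table(
                spd,
                covs["lithic"],
                covs["conflict"],
                covs["pollution"],
                step=config.step,
                window=config.window,
            )
        stage("fit + selection + validation")
        comparisons: dict[str, ModelComparison] = {}
        rows = []
        for i, variant in enumerate(config.variants, start=1):
            comp = fit_all_models(
                tables[variant],
                score_trajectories=True,
                sigma2_scale=config.sigma2_scale,
            )
            comparisons[variant] = comp
            for f in comp.fits:
                row = f.to_row()
                row["model"] = f"{row['model']}{i}"
                row["variant"] = variant
                rows.append(row)
    except PaleodynError as exc:
        raise PaleodynError(f"pipeline failed: {exc}") from exc

    fit_table = pd.DataFrame(rows)
    report = {
        "config": config.to_dict(),
        "spds": spds,
        "tables": tables,
        "comparisons": comparisons,
        "fit_table": fit_table,
    }
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for variant, spd in spds.items():
            spd.to_csv(out / f"spd_{variant}.csv")
        for variant, table in tables.items():
            table.to_csv(out / f"generation_table_{variant}.csv")
        fit_table.to_csv(out / "fit_table.csv", index=False)
        summary = {
            "config": config.to_dict(),
            "n_bins": {v: spds[v].n_bins for v in spds},
            "best_model": {
                v: comparisons[v].best.spec.name for v in comparisons
            },
            "akaike_weights": {
                v: {
                    f.spec.name: f.akaike_weight for f in comparisons[v].fits
                }
                for v in comparisons
            },
            "sigma2": {
                v: {f.spec.name: f.sigma2_prediction for f in comparisons[v].fits}
                for v in comparisons
            },
            "relative_importance": {
                v: comparisons[v].relative_importance() for v in comparisons
            },
        }
        with (out / "report.json").open("w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("report written to %s", out)
    return report
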