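"""Pipeline orchestration and summary tables.

Runs the full chain — read/validate stock tables, per-year life-table
calibration, cohort metrics, density-dependence fits on both growth-rate
bases, recovery projections — and produces the cross-stock summaries:
decade aggregates of the growth rates (median, mean, SD of both bases,
median log rates, stocks contributing, median relative abundance) and
grouped variability (the average per-stock standard deviation of the
fishing-excluded rate within species x region groups).

Decades are calendar decades labelled by their starting year.  Summary
statistics use the sample standard deviation; medians interpolate the
midpoint for even counts.  Log-rate summaries are medians of r = ln
lambda (not the log of the median lambda).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import cohorts_frame, extract_complete_cohorts
from .density import abundance_proportion, anchors_frame, dd_observations, fit_dd_gam
from .euler_lotka import CalibrationConfig, lambda_series
from .recovery import RecoveryConfig, annual_rates, project_doubling
from .stock import StockTable, read_stock_table

__all__ = [
    "PipelineConfig",
    "decade_summary",
    "group_variability",
    "run_pipeline",
    "read_stock_table",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """End-to-end run settings."""

    inputs: list
    outdir: str
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    recovery: RecoveryConfig = field(default_factory=RecoveryConfig)
    dd_k_global: int = 10
    dd_k_stock: int = 5
    fit_density: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        missing = [str(p) for p in self.inputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if not self.inputs:
            raise ValueError("no input paths given")
        return self


def decade_summary(series_frame: pd.DataFrame) -> pd.DataFrame:
    """Decade aggregates of both growth-rate bases across all stock-years.

    ``series_frame`` needs columns stock_id, year, lambda_real,
    lambda_dem and prop (relative abundance that year).
    """
    if series_frame.empty:
        log.info("decade summary requested on empty input")
        return pd.DataFrame()
    df = series_frame.copy()
    df["decade"] = (df["year"] // 10) * 10
    rows = []
    for decade, g in df.groupby("decade"):
        rows.append(
            {
                "decade": int(decade),
                "lambda_dem_median": g["lambda_dem"].median(),
                "r_dem_median": np.log(g["lambda_dem"]).median(),
                "lambda_dem_mean": g["lambda_dem"].mean(),
                "lambda_dem_sd": g["lambda_dem"].std(ddof=1),
                "lambda_real_median": g["lambda_real"].median(),
                "r_real_median": np.log(g["lambda_real"]).median(),
                "lambda_real_mean": g["lambda_real"].mean(),
                "lambda_real_sd": g["lambda_real"].std(ddof=1),
                "n_stocks": g["stock_id"].nunique(),
                "prop_of_max_median": g["prop"].median(),
            }
        )
    return pd.DataFrame(rows).sort_values("decade").reset_index(drop=True)


def group_variability(series_frame: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Within-group average of per-stock SD of the fishing-excluded rate.

    ``groups`` maps stock_id to species and region.  Per group: the mean
    over stocks of each stock's SD of lambda_dem, and the SD of those
    per-stock SDs across stocks (NaN for singleton groups).  Groups with
    no usable stock are dropped with a warning.
    """
    per_stock = (
        series_frame.groupby("stock_id")["lambda_dem"].std(ddof=1).rename("sd_lambda_dem")
    )
    merged = groups.merge(per_stock, on="stock_id", how="left")
    rows = []
    for (species, region), g in merged.groupby(["species", "region"]):
        sds = g["sd_lambda_dem"].dropna()
        if sds.empty:
            log.warning("group (%s, %s) has no stocks with a growth-rate series", species, region)
            continue
        rows.append(
            {
                "species": species,
                "region": region,
                "n_stocks": len(sds),
                "mean_sd_lambda_dem": sds.mean(),
                "sd_across_stocks": sds.std(ddof=1) if len(sds) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis chain and write CSV/JSON artifacts.

    Returns a result bundle with all in-memory products plus the manifest
    that was written to disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stocks: list[StockTable] = []
    for path in cfg.inputs:
        stocks.extend(read_stock_table(path))
    log.info("pipeline: %d stocks read", len(stocks))

    series_list = []
    lam_frames = []
    for stock in stocks:
        series = lambda_series(stock, cfg.calibration)
        series_list.append(series)
        frame = series.to_frame()
        props = abundance_proportion(stock)
        frame["prop"] = props[[stock.year_index(y) for y in series.years]]
        lam_frames.append(frame)
    lam_frame = pd.concat(lam_frames, ignore_index=True)
    lam_frame.to_csv(outdir / "lambda_series.csv", index=False)

    cohort_records = []
    for stock, series in zip(stocks, series_list):
        cohort_records.extend(extract_complete_cohorts(stock, series.life_tables))
    cohort_frame = cohorts_frame(cohort_records)
    cohort_frame.to_csv(outdir / "cohorts.csv", index=False)

    dd_fits = {}
    if cfg.fit_density and len(stocks) >= 2:
        for basis in ("real", "dem"):
            obs = dd_observations(stocks, series_list, basis=basis)
            fit = fit_dd_gam(obs, basis=basis, k_global=cfg.dd_k_global, k_stock=cfg.dd_k_stock)
            dd_fits[basis] = fit
            anchors_frame(fit).to_csv(outdir / f"density_anchors_{basis}.csv", index=False)

    recovery_rows = []
    curve_frames = []
    for series in series_list:
        rcfg = RecoveryConfig(**{**asdict(cfg.recovery), "seed": stock_seed(cfg.seed, series.stock_id)})
        res = project_doubling(annual_rates(series), rcfg)
        curve_frames.append(res.to_frame())
        recovery_rows.append(
            {
                "stock_id": series.stock_id,
                "classification": res.classification,
                "prop_doubled_y10": res.prop_doubled[9],
                "prop_doubled_y20": res.prop_doubled[19],
                "median_first_doubling": float(np.nanmedian(res.first_doubling_years))
                if np.any(np.isfinite(res.first_doubling_years))
                else np.nan,
            }
        )
    recovery_frame = pd.DataFrame(recovery_rows)
    recovery_frame.to_csv(outdir / "recovery_classes.csv", index=False)
    pd.concat(curve_frames, ignore_index=True).to_csv(outdir / "recovery_curves.csv", index=False)

    decades = decade_summary(lam_frame)
    decades.to_csv(outdir / "decade_summary.csv", index=False)
    groups = pd.DataFrame(
        {
            "stock_id": [s.stock_id for s in stocks],
            "species": [s.species for s in stocks],
            "region": [s.region for s in stocks],
        }
    )
    variability = group_variability(lam_frame, groups)
    variability.to_csv(outdir / "group_variability.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_stocks": len(stocks),
        "stocks": [s.stock_id for s in stocks],
        "calibration": asdict(cfg.calibration),
        "recovery": asdict(cfg.recovery),
        "n_years_total": int(lam_frame.shape[0]),
        "n_converged": int(lam_frame["converged"].sum()),
        "n_complete_cohorts": int(len(cohort_records)),
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "stocks": stocks,
        "series": series_list,
        "lambda_frame": lam_frame,
        "cohorts": cohort_frame,
        "dd_fits": dd_fits,
        "recovery": recovery_frame,
        "decades": decades,
        "variability": variability,
        "manifest": manifest,
    }


def stock_seed(master_seed: int, stock_id: str) -> int:
    """Independent, reproducible per-stock stream below 2**31."""
    h = np.uint64(1469598103934665603)
    for ch in f"{master_seed}:{stock_id}".encode():
        h = np.uint64((int(h) ^ ch) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))
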