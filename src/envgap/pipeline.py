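"""End-to-end orchestration: effort -> datasets -> gap metrics -> reports.

A single :class:`RunConfig` (usually loaded from YAML) drives the pipeline:
inputs are either read from files (grid rasters, GeoJSON tracklines, covariate
rasters) or simulated from an embedded synthetic-basin scenario.  Outputs are
plain-text artifacts: tidy CSVs per stage, ESRI ASCII map layers, summary
tables at the paper-table granularity, and a JSON run manifest sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import (ALL_COVARIATES, DYNAMIC_COVARIATES, STATIC_COVARIATES,
                         EnvDataset, build_available_dataset, build_climatology,
                         build_prediction_dataset, spearman_screen, write_field)
from .effort import intersect_effort, summarize_effort
from .gap import (GapResult, MonthlySummary, analyze_combination,
                  monthly_summary)
from .grid import StudyGrid, read_grid, write_ascii_grid, write_grid
from .synthetic import (BasinConfig, FieldParams, SurveyDesign, generate_basin,
                        generate_dynamic_covariates, generate_static_covariates,
                        generate_survey_program)
from .tracklines import (STUDY_PERIOD, read_tracklines_geojson,
                         write_tracklines_geojson)

log = logging.getLogger("envgap")

#: The default covariate combinations, in the layout of the headline table:
#: seven single covariates, then all-static, all-dynamic, and everything.
DEFAULT_COMBINATIONS: dict[str, tuple[str, ...]] = {
    **{c: (c,) for c in ALL_COVARIATES},
    "all_static": STATIC_COVARIATES,
    "all_dynamic": DYNAMIC_COVARIATES,
    "all_covariates": ALL_COVARIATES,
}


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    out_dir: str
    seed: int = 0
    scenario: dict | None = None          # synthetic-basin scenario (simulate)
    grid_dir: str | None = None           # or: pre-existing inputs
    tracklines_file: str | None = None
    static_dir: str | None = None         # rasters named {cov}.asc
    dynamic_dir: str | None = None        # rasters named {cov}_{YYYY}_{MM}.asc
    study_period: tuple[tuple[int, int], tuple[int, int]] = STUDY_PERIOD
    climatology_period: tuple[int, int] | None = None
    combinations: dict[str, tuple[str, ...]] = dc_field(
        default_factory=lambda: dict(DEFAULT_COMBINATIONS))
    months: tuple[int, ...] = tuple(range(1, 13))
    dedupe_available: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario is None and (self.grid_dir is None
                                      or self.tracklines_file is None):
            raise ConfigError("either a 'scenario' or both 'grid_dir' and "
                              "'tracklines_file' must be given")
        self.combinations = {name: tuple(covs)
                             for name, covs in self.combinations.items()}
        for name, covs in self.combinations.items():
            bad = [c for c in covs if c not in ALL_COVARIATES]
            if bad:
                raise ConfigError(f"combination {name!r} references unknown "
                                  f"covariate(s) {bad}")
        if any(m not in range(1, 13) for m in self.months):
            raise ConfigError("months must be within 1..12")


def _scenario_objects(scenario: dict, seed: int):
    """Instantiate generator configs from the scenario mapping."""
    basin = BasinConfig(**scenario.get("basin", {}))
    basin.seed = seed if "seed" not in scenario.get("basin", {}) else basin.seed
    fields = FieldParams(**scenario.get("fields", {}))
    design = SurveyDesign(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in scenario.get("survey", {}).items()})
    return basin, fields, design


@dataclass
class RunManifest:
    """Provenance record written at the end of a run."""

    config: dict
    version: str
    input_checksums: dict[str, str]
    counts: dict[str, int]
    timestamp: str

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=1, default=str))
        tmp.rename(path)  # atomic on POSIX


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_covariate_rasters(grid: StudyGrid, static_dir: str | Path,
                           dynamic_dir: str | Path):
    """Read covariate rasters by filename convention and align them to the
    grid with nearest-neighbour resampling.

    Static: ``{covariate}.asc``; dynamic: ``{covariate}_{YYYY}_{MM}.asc``.
    """
    from .covariates import SourceRaster, resample_nearest

    static = {}
    for path in sorted(Path(static_dir).glob("*.asc")):
        cov = path.stem
        static[cov] = resample_nearest(SourceRaster.from_ascii(path), grid,
                                       covariate_id=cov, kind="static")
    dynamic = {}
    for path in sorted(Path(dynamic_dir).glob("*.asc")):
        cov, year, month = path.stem.rsplit("_", 2)
        dynamic[(cov, int(year), int(month))] = resample_nearest(
            SourceRaster.from_ascii(path), grid, covariate_id=cov,
            kind="dynamic", year=int(year), month=int(month))
    if not static and not dynamic:
        raise ConfigError("no covariate rasters found")
    return static, dynamic


def project_to_map(grid: StudyGrid, values_by_cell: dict[int, float] | pd.Series,
                   path: str | Path) -> None:
    """Write per-cell values keyed by cell_id as an ESRI ASCII raster.

    Land and unkeyed sea cells carry the nodata value.
    """
    if isinstance(values_by_cell, pd.Series):
        values_by_cell = values_by_cell.to_dict()
    ids = np.fromiter(values_by_cell.keys(), dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= grid.n_cells):
        raise ValueError("cell_id outside grid")
    arr = np.full((grid.n_rows, grid.n_cols), np.nan)
    rows, cols = grid.rowcol(ids)
    arr[rows, cols] = np.fromiter(values_by_cell.values(), dtype=float)
    write_ascii_grid(path, arr, grid.origin, grid.cell_size)


def _extent_table_row(name: str, covs: tuple[str, ...],
                      result) -> dict:
    if isinstance(result, MonthlySummary):
        return {"combination": name, "covariates": "+".join(covs),
                "mean_extent_pct": result.mean,
                "min_extent_pct": result.min, "min_month": result.min_month,
                "max_extent_pct": result.max, "max_month": result.max_month}
    return {"combination": name, "covariates": "+".join(covs),
            "mean_extent_pct": result, "min_extent_pct": np.nan,
            "min_month": np.nan, "max_extent_pct": np.nan, "max_month": np.nan}


def write_summary_tables(extent_rows: list[dict], effort_summary,
                         out_dir: Path) -> None:
    """Emit the headline tables: extrapolation extents, per-subregion effort,
    and per-year / per-month effort series (percentages to one decimal)."""
    tables = out_dir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    ext = pd.DataFrame(extent_rows)
    for c in ("mean_extent_pct", "min_extent_pct", "max_extent_pct"):
        ext[c] = ext[c].round(1)
    ext.to_csv(tables / "extrapolation_extents.csv", index=False)
    s = effort_summary
    s.per_subregion.round(1).to_csv(tables / "effort_per_subregion.csv", index=False)
    s.per_year.round(1).to_csv(tables / "effort_per_year.csv", index=False)
    s.per_month.round(1).to_csv(tables / "effort_per_month.csv", index=False)
    s.per_platform.round(1).to_csv(tables / "effort_per_platform.csv", index=False)
    if s.zero_total:
        log.warning("zero total effort: summary tables contain only zeros")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute effort -> covariates -> gap analysis -> reports.

    Deterministic for a fixed config and seed.  Any stage error aborts with
    the stage named in the raised exception.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    counts: dict[str, int] = {}

    # -- stage: inputs -------------------------------------------------------
    try:
        if config.scenario is not None:
            basin_cfg, field_params, design = _scenario_objects(
                config.scenario, config.seed)
            grid = generate_basin(basin_cfg)
            static = generate_static_covariates(grid, basin_cfg.seed, field_params)
            dynamic = generate_dynamic_covariates(grid, basin_cfg, field_params)
            tracklines = generate_survey_program(grid, design, basin_cfg)
            sim_dir = out / "inputs"
            write_grid(grid, sim_dir)
            write_tracklines_geojson(tracklines, sim_dir / "tracklines.geojson")
            study_period = ((min(basin_cfg.years), 1), (max(basin_cfg.years), 12))
        else:
            if config.static_dir is None or config.dynamic_dir is None:
                raise ConfigError("file-based runs need 'static_dir' and "
                                  "'dynamic_dir'")
            grid = read_grid(config.grid_dir)
            tracklines = read_tracklines_geojson(config.tracklines_file)
            checksums[config.tracklines_file] = _checksum(Path(config.tracklines_file))
            static, dynamic = load_covariate_rasters(
                grid, config.static_dir, config.dynamic_dir)
            study_period = config.study_period
    except ConfigError:
        raise
    except Exception as e:  # pragma: no cover
        raise RuntimeError(f"stage 'inputs' failed: {e}") from e
    counts["tracklines"] = len(tracklines)
    counts["sea_cells"] = grid.n_sea
    log.info("inputs ready: %d tracklines over %d sea cells",
             len(tracklines), grid.n_sea)

    # -- stage: effort -------------------------------------------------------
    effort = intersect_effort(tracklines, grid, period=study_period)
    counts["effort_strata"] = len(effort.frame)
    counts["discarded_segments"] = len(effort.discard_log)
    effort.to_csv(out / "effort.csv")
    summary = summarize_effort(effort)
    project_to_map(grid, effort.per_cell(), out / "effort_km.asc")
    log.info("effort gridded: %.1f km over %d cells", effort.total_km,
             len(effort.per_cell()))

    # -- stage: datasets -----------------------------------------------------
    climatology = build_climatology(dynamic, config.climatology_period)
    available = build_available_dataset(effort, static, dynamic,
                                        ALL_COVARIATES,
                                        dedupe=config.dedupe_available)
    counts["available_records"] = available.n
    counts["available_excluded"] = available.qc["records_excluded_missing"]
    available.to_csv(out / "available.csv")
    rho, rho_warnings = spearman_screen(available)
    rho.to_csv(out / "spearman_available.csv")
    for w in rho_warnings:
        log.warning("spearman screen: %s", w)

    predictions: dict[int, EnvDataset] = {}
    for month in config.months:
        predictions[month] = build_prediction_dataset(
            grid, static, climatology, month, ALL_COVARIATES)
        predictions[month].to_csv(out / f"prediction_{month:02d}.csv")
    counts["prediction_records_per_month"] = predictions[config.months[0]].n

    # -- stage: gap analysis -------------------------------------------------
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    extent_rows: list[dict] = []
    n_extrap = 0
    for name, covs in config.combinations.items():
        static_only = all(c in STATIC_COVARIATES for c in covs)
        if static_only:
            pred = predictions[config.months[0]]
            res = analyze_combination(available, pred, covs)
            _write_gap_outputs(res, grid, out, maps_dir, name, month=None)
            extent_rows.append(_extent_table_row(name, covs, res.extent_pct))
            n_extrap += int((res.table["hull_class"] == "extrapolation").sum())
        else:
            extents: dict[int, float] = {}
            for month, pred in predictions.items():
                res = analyze_combination(available, pred, covs, month=month)
                _write_gap_outputs(res, grid, out, maps_dir, name, month=month)
                extents[month] = res.extent_pct
                n_extrap += int((res.table["hull_class"] == "extrapolation").sum())
            extent_rows.append(_extent_table_row(name, covs,
                                                 monthly_summary(extents)))
        log.info("combination %s analysed", name)
    counts["extrapolative_records"] = n_extrap

    # -- stage: reports ------------------------------------------------------
    write_summary_tables(extent_rows, summary, out)
    manifest = RunManifest(
        config={k: getattr(config, k) for k in config.__dataclass_fields__},
        version=__version__, input_checksums=checksums, counts=counts,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.write(out / "manifest.json")
    return manifest


def _write_gap_outputs(res: GapResult, grid: StudyGrid, out: Path,
                       maps_dir: Path, name: str, month: int | None) -> None:
    suffix = f"{name}" if month is None else f"{name}_{month:02d}"
    res.table.to_csv(out / f"gap_{suffix}.csv", index=False)
    codes = (res.table["hull_class"] == "extrapolation").astype(float)
    project_to_map(grid, pd.Series(codes.to_numpy(),
                                   index=res.table["cell_id"].to_numpy()),
                   maps_dir / f"extrapolation_{suffix}.asc")
    project_to_map(grid, pd.Series(res.table["proportion_nearby"].to_numpy(),
                                   index=res.table["cell_id"].to_numpy()),
                   maps_dir / f"proportion_nearby_{suffix}.asc")
    if len(res.covariate_names) == 1:
        c = res.covariate_names[0]
        below = (res.table[f"class_{c}"] == "below").astype(float)
        above = (res.table[f"class_{c}"] == "above").astype(float)
        idx = res.table["cell_id"].to_numpy()
        project_to_map(grid, pd.Series(below.to_numpy(), index=idx),
                       maps_dir / f"below_{suffix}.asc")
        project_to_map(grid, pd.Series(above.to_numpy(), index=idx),
                       maps_dir / f"above_{suffix}.asc")


# -- bundled demo scenario ---------------------------------------------------

def demo_config(out_dir: str, seed: int = 0, n_cols: int = 60, n_rows: int = 30,
                years: tuple[int, ...] = (2010, 2011, 2012),
                months: tuple[int, ...] = tuple(range(1, 13))) -> RunConfig:
    """The bundled demonstration scenario: a 60 x 30 all-sea basin with
    summer-biased surveys concentrated in the western subregions, the
    configuration under which the qualitative gap structure (static <
    dynamic < all-covariate extrapolation; winter > summer dynamic extents)
    is expected to emerge."""
    scenario = {
        "basin": {"n_cols": n_cols, "n_rows": n_rows, "land_fraction": 0.0,
                  "n_subregions": 8, "years": list(years), "seed": seed},
        "fields": {"noise_sd": 0.05, "sst_year_anomaly_sd": 0.3},
        "survey": {"n_surveys": 150, "platform_mix": 0.5,
                   "geographic_concentration": 30.0,
                   "favoured_subregion": (0, 1, 2, 3),  # the western half
                   "seasonal_concentration": 8.0,
                   "mean_trackline_length": 80.0},
    }
    return RunConfig(out_dir=out_dir, seed=seed, scenario=scenario,
                     months=months)
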