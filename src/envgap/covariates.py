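"""Covariate alignment, monthly climatologies, and environmental datasets.

Two datasets drive the gap analysis:

* the **available** dataset — covariate values of surveyed grid cells at the
  month and year of each survey (contemporaneous dynamic resolution), the
  support on which a species distribution model would be calibrated;
* the **prediction** dataset — monthly climatological covariate values of all
  sea cells of the study area, where such a model would be asked to predict.

Static covariates (depth, slope, distance to seamounts/canyons) are shared by
both roles; dynamic covariates (sst, pp, eke) differ by design: surveyed
conditions are compared against long-term monthly averages, not against the
conditions of one particular year.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import StudyGrid, read_ascii_grid, write_ascii_grid

STATIC_COVARIATES = ("depth", "slope", "distance_to_seamounts", "distance_to_canyons")
DYNAMIC_COVARIATES = ("sst", "pp", "eke")
ALL_COVARIATES = STATIC_COVARIATES + DYNAMIC_COVARIATES

#: Units of the built-in covariates, for documentation and sidecar metadata.
UNITS = {
    "depth": "m", "slope": "m/km", "distance_to_seamounts": "km",
    "distance_to_canyons": "km", "sst": "degC", "pp": "mgC/m2/day",
    "eke": "cm2/s2",
}


@dataclass
class CovariateField:
    """One covariate's values on the study grid (NaN = missing / land).

    Static fields carry no year or month; dynamic contemporaneous fields carry
    both; monthly climatological fields carry a month only.
    """

    covariate_id: str
    kind: str  # "static" | "dynamic"
    values: np.ndarray
    year: int | None = None
    month: int | None = None
    contributors: np.ndarray | None = None  # climatology: non-missing years per cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("static", "dynamic"):
            raise ValueError("kind must be 'static' or 'dynamic'")
        if self.kind == "static" and (self.year is not None or self.month is not None):
            raise ValueError("static fields carry no year/month")

    @property
    def is_climatology(self) -> bool:
        return self.kind == "dynamic" and self.year is None and self.month is not None


@dataclass
class SourceRaster:
    """A source raster to be aligned to the study grid (values row 0 = bottom)."""

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float

    @classmethod
    def from_ascii(cls, path: str | Path) -> "SourceRaster":
        values, origin, cs = read_ascii_grid(path)
        return cls(values=values, origin=origin, cell_size=cs)


@dataclass
class EnvDataset:
    """Points x covariates matrix in environmental space.

    ``frame`` holds one row per record with columns ``cell_id``, ``month``,
    ``year`` (NaN where not applicable) and one column per covariate, in the
    order of ``covariate_names``.
    """

    role: str  # "available" | "prediction"
    covariate_names: tuple[str, ...]
    frame: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("available", "prediction"):
            raise ValueError("role must be 'available' or 'prediction'")
        if not self.covariate_names:
            raise ValueError("at least one covariate required")
        missing = [c for c in self.covariate_names if c not in self.frame.columns]
        if missing:
            raise ValueError(f"frame lacks covariate columns: {missing}")

    @property
    def records(self) -> np.ndarray:
        """(n, K) matrix of covariate values."""
        return self.frame[list(self.covariate_names)].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def k(self) -> int:
        return len(self.covariate_names)

    def select(self, covariate_names: Iterable[str]) -> "EnvDataset":
        """Restrict to a sub-combination of covariates (records unchanged)."""
        names = tuple(covariate_names)
        unknown = [c for c in names if c not in self.covariate_names]
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        return EnvDataset(role=self.role, covariate_names=names,
                          frame=self.frame, qc=self.qc)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, role: str,
                 covariate_names: Iterable[str] | None = None) -> "EnvDataset":
        frame = pd.read_csv(path)
        if covariate_names is None:
            covariate_names = [c for c in frame.columns
                               if c not in ("cell_id", "year", "month")]
        return cls(role=role, covariate_names=tuple(covariate_names), frame=frame)


# -- raster alignment --------------------------------------------------------

def resample_nearest(source: SourceRaster, grid: StudyGrid,
                     covariate_id: str = "covariate", kind: str = "static",
                     year: int | None = None, month: int | None = None) -> CovariateField:
    """Nearest-neighbour resampling of a source raster onto the study grid.

    Each grid-cell centre takes the value of the nearest source-raster cell
    centre (ties broken toward the lower index); missing source values
    propagate as missing.  Values over land cells are masked out.
    """
    sx0, sy0 = source.origin
    snr, snc = source.values.shape
    # extent-overlap check
    gx1 = grid.origin[0] + grid.n_cols * grid.cell_size
    gy1 = grid.origin[1] + grid.n_rows * grid.cell_size
    sx1 = sx0 + snc * source.cell_size
    sy1 = sy0 + snr * source.cell_size
    if gx1 <= sx0 or sx1 <= grid.origin[0] or gy1 <= sy0 or sy1 <= grid.origin[1]:
        raise ValueError("source raster extent does not overlap the grid")

    cx, cy = grid.cell_centres()
    fc = (cx - sx0) / source.cell_size - 0.5
    fr = (cy - sy0) / source.cell_size - 0.5
    col = np.clip(np.ceil(fc - 0.5).astype(int), 0, snc - 1)
    row = np.clip(np.ceil(fr - 0.5).astype(int), 0, snr - 1)
    values = source.values[row, col]
    values = np.where(grid.sea_mask, values, np.nan)
    if np.all(np.isnan(values[grid.sea_mask])):
        _warnings.warn("resampled field is entirely missing over sea cells")
    return CovariateField(covariate_id=covariate_id, kind=kind, values=values,
                          year=year, month=month)


# -- climatologies -----------------------------------------------------------

def build_climatology(fields: Mapping[tuple[str, int, int], CovariateField],
                      period: tuple[int, int] | None = None,
                      ) -> dict[tuple[str, int], CovariateField]:
    """Per-cell monthly means over years, skipping missing values.

    ``fields`` maps (covariate_id, year, month) to contemporaneous monthly
    fields.  The climatology for (covariate, month) is the mean over the years
    of ``period`` (default: all input years); cell-months with no non-missing
    contributor are missing.  Contributor counts are retained on each output
    field.
    """
    if not fields:
        raise ValueError("no dynamic fields supplied")
    out: dict[tuple[str, int], CovariateField] = {}
    keys = sorted(fields.keys())
    covs = sorted({k[0] for k in keys})
    months = sorted({k[2] for k in keys})
    for cov in covs:
        for month in months:
            stack = [fields[k].values for k in keys
                     if k[0] == cov and k[2] == month
                     and (period is None or period[0] <= k[1] <= period[1])]
            if not stack:
                continue
            arr = np.stack(stack)
            counts = np.sum(~np.isnan(arr), axis=0)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", category=RuntimeWarning)
                mean = np.nanmean(arr, axis=0)
            mean = np.where(counts > 0, mean, np.nan)
            out[(cov, month)] = CovariateField(
                covariate_id=cov, kind="dynamic", values=mean, year=None,
                month=month, contributors=counts)
    return out


# -- dataset assembly --------------------------------------------------------

def _static_lookup(static: Mapping[str, CovariateField], name: str,
                   rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return static[name].values[rows, cols]


def build_available_dataset(effort, static: Mapping[str, CovariateField],
                            dynamic: Mapping[tuple[str, int, int], CovariateField],
                            covariate_names: Iterable[str] = ALL_COVARIATES,
                            dedupe: bool = True) -> EnvDataset:
    """Assemble the available dataset from surveyed (cell, year, month) strata.

    One record per (cell, year, month) with nonzero effort, pooled across all
    surveys (with ``dedupe=False``, one record per (cell, year, month,
    platform, organisation) stratum instead).  Static values come from the
    cell, dynamic values from that cell-year-month; records with any missing
    covariate are excluded and counted in ``dataset.qc``.
    """
    covariate_names = tuple(covariate_names)
    df = effort.frame
    df = df[df["effort_km"] > 0]
    if dedupe:
        cells = df[["cell_id", "year", "month"]].drop_duplicates()
    else:
        cells = df[["cell_id", "year", "month", "platform",
                    "organisation"]].drop_duplicates()
    cells = cells.sort_values(list(cells.columns)).reset_index(drop=True)
    grid = effort.grid
    rows, cols = grid.rowcol(cells["cell_id"].to_numpy())

    data = {"cell_id": cells["cell_id"].to_numpy(),
            "year": cells["year"].to_numpy(),
            "month": cells["month"].to_numpy()}
    missing_dynamic_strata = 0
    for name in covariate_names:
        if name in static:
            data[name] = _static_lookup(static, name, rows, cols)
        else:
            vals = np.full(len(cells), np.nan)
            for i, (y, m) in enumerate(zip(cells["year"], cells["month"])):
                fld = dynamic.get((name, int(y), int(m)))
                if fld is None:
                    missing_dynamic_strata += 1
                    continue
                vals[i] = fld.values[rows[i], cols[i]]
            data[name] = vals
    frame = pd.DataFrame(data)
    complete = ~frame[list(covariate_names)].isna().any(axis=1)
    qc = {"records_built": int(len(frame)),
          "records_excluded_missing": int((~complete).sum()),
          "missing_dynamic_strata": missing_dynamic_strata}
    frame = frame[complete].reset_index(drop=True)
    if frame.empty:
        raise ValueError("available dataset is empty; gap analysis impossible")
    return EnvDataset(role="available", covariate_names=covariate_names,
                      frame=frame, qc=qc)


def build_prediction_dataset(grid: StudyGrid, static: Mapping[str, CovariateField],
                             climatology: Mapping[tuple[str, int], CovariateField],
                             month: int | None,
                             covariate_names: Iterable[str] = ALL_COVARIATES,
                             ) -> EnvDataset:
    """Assemble the prediction dataset: all sea cells, climatological month.

    ``month=None`` requests a static-only (month-free) dataset and is valid
    only when every requested covariate is static.  Cells with any missing
    covariate are excluded and counted in ``dataset.qc``.
    """
    covariate_names = tuple(covariate_names)
    dynamic_requested = [c for c in covariate_names if c not in static]
    if month is None and dynamic_requested:
        raise ValueError("month required when dynamic covariates are requested")
    if month is not None and not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")

    cell_ids = grid.sea_cell_ids()
    rows, cols = grid.rowcol(cell_ids)
    data = {"cell_id": cell_ids,
            "year": np.full(len(cell_ids), np.nan),
            "month": np.full(len(cell_ids), np.nan if month is None else month)}
    for name in covariate_names:
        if name in static:
            data[name] = _static_lookup(static, name, rows, cols)
        else:
            fld = climatology.get((name, month))
            if fld is None:
                raise ValueError(f"no climatology for covariate {name!r}, month {month}")
            data[name] = fld.values[rows, cols]
    frame = pd.DataFrame(data)
    complete = ~frame[list(covariate_names)].isna().any(axis=1)
    qc = {"records_built": int(len(frame)),
          "records_excluded_missing": int((~complete).sum())}
    frame = frame[complete].reset_index(drop=True)
    return EnvDataset(role="prediction", covariate_names=covariate_names,
                      frame=frame, qc=qc)


# -- collinearity screen -----------------------------------------------------

def spearman_screen(dataset: EnvDataset, threshold: float = 0.6,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Spearman rank correlations between covariate pairs (advisory only).

    Pairs with \\|rho\\| >= ``threshold`` are flagged in the returned warning
    list; nothing is ever dropped.  Constant covariates yield undefined rho
    (NaN) and are reported as such.
    """
    from scipy.stats import spearmanr

    if dataset.n < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    names = dataset.covariate_names
    x = dataset.records
    k = len(names)
    rho = np.eye(k)
    msgs: list[str] = []
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(x[:, i]) == 0 or np.std(x[:, j]) == 0:
                r = np.nan
                msgs.append(f"rho undefined for ({names[i]}, {names[j]}): "
                            "constant covariate")
            else:
                r = spearmanr(x[:, i], x[:, j]).statistic
                if abs(r) >= threshold:
                    msgs.append(f"|rho|={abs(r):.3f} >= {threshold} for "
                                f"({names[i]}, {names[j]})")
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=list(names), columns=list(names)), msgs


# -- field I/O ---------------------------------------------------------------

def write_field(fld: CovariateField, grid: StudyGrid, directory: str | Path) -> Path:
    """Write a field as `COV.asc`, `COV_YYYY_MM.asc` or `COV_clim_MM.asc`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fld.kind == "static":
        name = f"{fld.covariate_id}.asc"
    elif fld.is_climatology:
        name = f"{fld.covariate_id}_clim_{fld.month:02d}.asc"
    else:
        name = f"{fld.covariate_id}_{fld.year:04d}_{fld.month:02d}.asc"
    path = directory / name
    write_ascii_grid(path, fld.values, grid.origin, grid.cell_size)
    return path
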