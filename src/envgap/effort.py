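"""Trackline-to-grid intersection and survey-effort summaries.

Each trackline is split at cell boundaries and every sub-segment's length is
credited to its containing cell under the trackline's stratum (year, month,
platform, organisation).  Cell extents are half-open, so a sub-segment lying
exactly on a shared boundary belongs to exactly one cell and a corner touch
contributes zero length.  Sub-segments falling outside the grid or over land
are clipped out and reported in a discard log; no effort is ever credited to
land.  Total credited effort equals total clipped trackline length.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import StudyGrid
from .tracklines import STUDY_PERIOD, Trackline, in_study_period

STRATA = ("year", "month", "platform", "organisation")


@dataclass
class EffortGrid:
    """Per-cell survey effort stratified by (year, month, platform, organisation).

    ``frame`` has columns cell_id, year, month, platform, organisation,
    effort_km — one row per nonzero (cell, stratum).
    """

    grid: StudyGrid
    frame: pd.DataFrame
    discard_log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["survey_id", "reason", "length_km"]))

    @property
    def total_km(self) -> float:
        return float(self.frame["effort_km"].sum())

    def per_cell(self) -> pd.Series:
        """Total effort per cell_id, collapsed over strata."""
        return self.frame.groupby("cell_id")["effort_km"].sum()

    def surveyed_cells(self) -> np.ndarray:
        """Ids of cells with any positive effort (no minimum-effort threshold)."""
        s = self.per_cell()
        return s[s > 0].index.to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _split_segment(p0: np.ndarray, p1: np.ndarray, grid: StudyGrid):
    """Split one segment at grid lines; yield (row, col, length) per piece."""
    d = p1 - p0
    seg_len = float(np.hypot(*d))
    if seg_len == 0.0:
        return
    ts = [0.0, 1.0]
    s = grid.cell_size
    for axis, orig in ((0, grid.origin[0]), (1, grid.origin[1])):
        if d[axis] == 0.0:
            continue
        lo, hi = sorted((p0[axis], p1[axis]))
        i0 = int(np.ceil((lo - orig) / s))
        i1 = int(np.floor((hi - orig) / s))
        for i in range(i0, i1 + 1):
            t = (orig + i * s - p0[axis]) / d[axis]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(ts)
    for a, b in zip(ts[:-1], ts[1:]):
        mid = p0 + 0.5 * (a + b) * d
        row, col = grid.locate(mid[0], mid[1])
        yield int(row), int(col), (b - a) * seg_len


def intersect_effort(tracklines: list[Trackline], grid: StudyGrid,
                     period: tuple[tuple[int, int], tuple[int, int]] = STUDY_PERIOD,
                     ) -> EffortGrid:
    """Intersect tracklines with the grid and sum effort per cell and stratum.

    Tracklines with fewer than two vertices or dated outside the study period
    are rejected with a warning and logged.  Returns an :class:`EffortGrid`
    whose total equals the summed clipped trackline length.
    """
    acc: dict[tuple, float] = {}
    discards: list[tuple[str, str, float]] = []
    for t in tracklines:
        if t.n_vertices < 2:
            _warnings.warn(f"trackline {t.survey_id}: fewer than 2 vertices; rejected")
            discards.append((t.survey_id, "too_few_vertices", 0.0))
            continue
        if not in_study_period(t.date, period):
            _warnings.warn(f"trackline {t.survey_id}: date {t.date} outside "
                           "study period; rejected")
            discards.append((t.survey_id, "outside_period", t.length_km))
            continue
        stratum = (t.year, t.month, t.platform, t.organisation)
        for p0, p1 in zip(t.vertices[:-1], t.vertices[1:]):
            for row, col, length in _split_segment(np.asarray(p0, float),
                                                   np.asarray(p1, float), grid):
                if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
                    discards.append((t.survey_id, "outside_grid", length))
                elif not grid.sea_mask[row, col]:
                    discards.append((t.survey_id, "land", length))
                else:
                    key = (grid.cell_id(row, col),) + stratum
                    acc[key] = acc.get(key, 0.0) + length
    frame = pd.DataFrame(
        [(int(k[0]), k[1], k[2], k[3], k[4], v) for k, v in acc.items()],
        columns=["cell_id", "year", "month", "platform", "organisation", "effort_km"],
    ).sort_values(["cell_id", "year", "month", "platform",
                   "organisation"]).reset_index(drop=True)
    log = pd.DataFrame(discards, columns=["survey_id", "reason", "length_km"])
    return EffortGrid(grid=grid, frame=frame, discard_log=log)


def subset_effort(effort: EffortGrid, by: dict) -> EffortGrid:
    """Restrict effort to matching strata; idempotent.

    ``by`` maps stratum keys (year, month, platform, organisation) to a value
    or list of values.
    """
    unknown = [k for k in by if k not in STRATA]
    if unknown:
        raise ValueError(f"unknown stratum keys: {unknown}; expected {STRATA}")
    frame = effort.frame
    for key, value in by.items():
        values = value if isinstance(value, (list, tuple, set, np.ndarray)) else [value]
        frame = frame[frame[key].isin(list(values))]
    return EffortGrid(grid=effort.grid, frame=frame.reset_index(drop=True),
                      discard_log=effort.discard_log)


@dataclass
class EffortSummary:
    """Tabular effort summaries: per subregion, year, month and platform."""

    per_subregion: pd.DataFrame  # subregion, area_km2, area_pct, effort_km, effort_pct
    per_year: pd.DataFrame
    per_month: pd.DataFrame
    per_platform: pd.DataFrame
    total_km: float
    zero_total: bool = False


def summarize_effort(effort: EffortGrid) -> EffortSummary:
    """Effort (km and % of total) per subregion, year, month and platform."""
    grid = effort.grid
    total = effort.total_km
    zero = total == 0.0
    denom = total if total > 0 else 1.0

    per_cell = effort.per_cell()
    rows, cols = grid.rowcol(per_cell.index.to_numpy(dtype=int))
    sub_of_cell = grid.subregion[rows, cols]
    sub_effort = pd.Series(per_cell.to_numpy()).groupby(sub_of_cell).sum()

    sub_labels = np.arange(grid.n_subregions)
    area_cells = np.array([(grid.subregion == s)[grid.sea_mask].sum()
                           for s in sub_labels], dtype=float)
    area_km2 = area_cells * grid.cell_area
    per_subregion = pd.DataFrame({
        "subregion": sub_labels,
        "area_km2": area_km2,
        "area_pct": 100.0 * area_km2 / area_km2.sum() if area_km2.sum() else 0.0,
        "effort_km": [float(sub_effort.get(s, 0.0)) for s in sub_labels],
    })
    per_subregion["effort_pct"] = 100.0 * per_subregion["effort_km"] / denom

    def series(key: str) -> pd.DataFrame:
        g = effort.frame.groupby(key)["effort_km"].sum().reset_index()
        g["effort_pct"] = 100.0 * g["effort_km"] / denom
        return g

    return EffortSummary(per_subregion=per_subregion, per_year=series("year"),
                         per_month=series("month"), per_platform=series("platform"),
                         total_km=total, zero_total=zero)


def aggregate_for_display(effort: EffortGrid, factor: int) -> EffortGrid:
    """Block-sum effort into factor x factor super-cells (for coarse maps).

    The coarse grid's cell is sea if any constituent fine cell is sea;
    remainder rows/columns form partial blocks.  Total effort is conserved.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return effort
    grid = effort.grid
    nr = -(-grid.n_rows // factor)
    nc = -(-grid.n_cols // factor)
    sea = np.zeros((nr, nc), dtype=bool)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if grid.sea_mask[r, c]:
                sea[r // factor, c // factor] = True
    coarse = StudyGrid(origin=grid.origin, cell_size=grid.cell_size * factor,
                       sea_mask=sea)
    frame = effort.frame.copy()
    rows, cols = grid.rowcol(frame["cell_id"].to_numpy())
    frame["cell_id"] = coarse.cell_id(rows // factor, cols // factor)
    frame = frame.groupby(["cell_id", "year", "month", "platform", "organisation"],
                          as_index=False)["effort_km"].sum()
    return EffortGrid(grid=coarse, frame=frame, discard_log=effort.discard_log)
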