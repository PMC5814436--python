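"""On-effort trackline data model and GeoJSON I/O.

A trackline is a dated, attributed polyline of on-effort survey segments in
projected planar coordinates (km).  The default study period matches the era
of full remote-sensing covariate availability (October 1997 - April 2016);
tracklines outside it are rejected by the effort-gridding inclusion filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

PLATFORMS = ("ship", "aircraft")

#: Default study period: (year, month) inclusive bounds.
STUDY_PERIOD = ((1997, 10), (2016, 4))


@dataclass
class Trackline:
    """One dated on-effort survey polyline.

    vertices : (n, 2) array of planar (x, y) km coordinates, n >= 2
    date : (year, month, day)
    platform : "ship" or "aircraft"
    """

    survey_id: str
    vertices: np.ndarray
    date: tuple[int, int, int]
    platform: str
    organisation: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def length_km(self) -> float:
        if self.n_vertices < 2:
            return 0.0
        return float(np.hypot(*np.diff(self.vertices, axis=0).T).sum())

    @property
    def year(self) -> int:
        return self.date[0]

    @property
    def month(self) -> int:
        return self.date[1]


def in_study_period(date: tuple[int, int, int],
                    period: tuple[tuple[int, int], tuple[int, int]] = STUDY_PERIOD) -> bool:
    """True if (year, month, day) falls inside the inclusive (year, month) period."""
    (y0, m0), (y1, m1) = period
    ym = (date[0], date[1])
    return (y0, m0) <= ym <= (y1, m1)


def write_tracklines_geojson(tracklines: list[Trackline], path: str | Path) -> None:
    features = []
    for t in tracklines:
        y, m, d = t.date
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(yy)] for x, yy in t.vertices]},
            "properties": {"survey_id": t.survey_id,
                           "date": f"{y:04d}-{m:02d}-{d:02d}",
                           "platform": t.platform,
                           "organisation": t.organisation},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_tracklines_geojson(path: str | Path) -> list[Trackline]:
    doc = json.loads(Path(path).read_text())
    out = []
    for f in doc["features"]:
        props = f["properties"]
        y, m, d = (int(v) for v in props["date"].split("-"))
        out.append(Trackline(
            survey_id=str(props["survey_id"]),
            vertices=np.asarray(f["geometry"]["coordinates"], dtype=float),
            date=(y, m, d),
            platform=props["platform"],
            organisation=str(props.get("organisation", "")),
        ))
    return out
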