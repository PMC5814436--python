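"""Environmental-space gap metrics.

Given an *available* dataset (surveyed environmental conditions) and a
*prediction* dataset (conditions everywhere a model would predict), this
module quantifies where prediction would rely on extrapolation:

* **univariate envelopes** — a prediction value below/within/above the
  [min, max] interval of the available data for each covariate;
* **convex-hull membership** — a prediction point inside the convex hull of
  the available points (in K-dimensional environmental space) is an
  interpolation, outside it an extrapolation.  Membership is decided by a
  convex-combination feasibility test solved as a linear program, which
  scales to K = 7 and thousands of available points where explicit facet
  enumeration does not;
* **Gower's distance** G2_ij = (1/K) * sum_k |x_ik - x_jk| / r_k, with r_k
  the available range of covariate k — a range-standardised mean absolute
  difference in which every covariate contributes equally;
* **proportion of data nearby** — the fraction of available points within a
  radius of one geometric mean Gower's distance (GV, the geometric mean of
  G2 over all pairs of available points) of each prediction point.  It grades
  extrapolations by how far outside the sampled space they fall, and flags
  interpolations that sit in sparsely sampled regions of environmental space.

The binary hull metric and the continuous proportion-of-data-nearby metric
are deliberately complementary: the first draws the boundary of the sampled
environmental space, the second measures the density of sampling around each
prediction point.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist, pdist

from .covariates import EnvDataset

#: Feasibility tolerance of the hull-membership LP, applied after the
#: per-covariate range standardisation; boundary points (within tolerance)
#: count as interpolation.
HULL_TOL = 1e-9

MONTH_NAMES = ("January", "February", "March", "April", "May", "June", "July",
               "August", "September", "October", "November", "December")


@dataclass
class Ranges:
    """Per-covariate [min, max] envelopes of the available dataset."""

    covariate_names: tuple[str, ...]
    min_k: np.ndarray
    max_k: np.ndarray

    @property
    def r_k(self) -> np.ndarray:
        return self.max_k - self.min_k

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of covariates with zero range (point envelopes)."""
        return self.r_k == 0

    def select(self, covariate_names) -> "Ranges":
        idx = [self.covariate_names.index(c) for c in covariate_names]
        return Ranges(covariate_names=tuple(covariate_names),
                      min_k=self.min_k[idx], max_k=self.max_k[idx])


def covariate_ranges(available: EnvDataset) -> Ranges:
    """Exact min/max per covariate over the available dataset."""
    if available.n == 0:
        raise ValueError("available dataset is empty")
    x = available.records
    ranges = Ranges(covariate_names=available.covariate_names,
                    min_k=x.min(axis=0), max_k=x.max(axis=0))
    if ranges.degenerate.any():
        names = [c for c, d in zip(ranges.covariate_names, ranges.degenerate) if d]
        _warnings.warn(f"constant covariate(s) with zero range: {names}")
    return ranges


def classify_univariate(ranges: Ranges, prediction: EnvDataset) -> pd.DataFrame:
    """Envelope class per prediction record and covariate.

    'below' if the value is under the available minimum, 'above' if over the
    maximum, 'within' otherwise; the interval endpoints are inclusive
    (interpolation).  For a zero-range covariate the envelope is the single
    available value.
    """
    if ranges.covariate_names != prediction.covariate_names:
        raise ValueError("ranges and prediction cover different covariates")
    x = prediction.records
    out = np.full(x.shape, "within", dtype=object)
    out[x < ranges.min_k] = "below"
    out[x > ranges.max_k] = "above"
    return pd.DataFrame(out, columns=list(ranges.covariate_names))


# -- convex-hull membership --------------------------------------------------

def _standardise(x: np.ndarray, ranges: Ranges) -> np.ndarray:
    """Divide each covariate by its available range (unit-range coordinates);
    zero-range covariates pass through unscaled (they are compared exactly)."""
    r = np.where(ranges.r_k > 0, ranges.r_k, 1.0)
    return x / r


def hull_membership(available: EnvDataset, prediction: EnvDataset,
                    tol: float = HULL_TOL) -> pd.Series:
    """'interpolation' or 'extrapolation' per prediction record.

    A point is an interpolation iff it is a convex combination of available
    points: there exist weights lambda >= 0 with sum(lambda) = 1 and
    A^T lambda = x.  Feasibility is decided per point by linear programming
    in range-standardised coordinates; points within ``tol`` of the hull
    boundary count as interpolation.  Points outside any univariate envelope
    are classified without a solve (the hull's axis projections are exactly
    the envelopes).  A solver failure flags the point rather than silently
    classifying it.
    """
    if available.n == 0:
        raise ValueError("available dataset is empty")
    if available.covariate_names != prediction.covariate_names:
        raise ValueError("available and prediction cover different covariates")
    ranges = covariate_ranges(available)
    a = _standardise(available.records, ranges)
    p = _standardise(prediction.records, ranges)
    n, k = a.shape

    labels = np.empty(len(p), dtype=object)
    # quick reject: outside the bounding box (with tolerance) => extrapolation
    lo, hi = a.min(axis=0), a.max(axis=0)
    outside = ((p < lo - tol) | (p > hi + tol)).any(axis=1)
    labels[outside] = "extrapolation"

    if k == 1:
        # the hull of one covariate is exactly the [min, max] interval, so
        # the bounding-box test is already the full membership test
        labels[~outside] = "interpolation"
        return pd.Series(labels, name="hull_class")

    todo = np.nonzero(~outside)[0]
    if todo.size:
        # the LP only needs the hull's generators: drop duplicate available
        # records, and in low dimension reduce to the hull vertices (cheap
        # with an exact facet enumeration at K <= 3, infeasible at K = 7)
        a = np.unique(a, axis=0)
        if k <= 4 and len(a) > k + 1:
            try:
                from scipy.spatial import ConvexHull
                a = a[ConvexHull(a).vertices]
            except Exception:  # degenerate (flat) hull: keep all points
                pass
        n = len(a)
        # solve each unique remaining point once
        uniq, inverse = np.unique(p[todo], axis=0, return_inverse=True)
        a_eq = np.vstack([a.T, np.ones(n)])
        uniq_labels = np.empty(len(uniq), dtype=object)
        for i, point in enumerate(uniq):
            b_eq = np.append(point, 1.0)
            res = linprog(c=np.zeros(n), A_eq=a_eq, b_eq=b_eq,
                          bounds=[(0, None)] * n, method="highs",
                          options={"primal_feasibility_tolerance": max(tol, 1e-10)})
            if res.status == 0:
                uniq_labels[i] = "interpolation"
            elif res.status == 2:
                uniq_labels[i] = "extrapolation"
            else:  # pragma: no cover - solver failure is exceptional
                uniq_labels[i] = "error"
                _warnings.warn(f"hull LP failed (status {res.status}) for a "
                               "prediction point; flagged as 'error'")
        labels[todo] = uniq_labels[inverse]
    return pd.Series(labels, name="hull_class")


# -- Gower's distance and the neighbourhood radius ---------------------------

def _gower_matrix(x: np.ndarray, y: np.ndarray, ranges: Ranges) -> np.ndarray:
    """All-pairs G2 between rows of x and rows of y.

    Zero-range covariates are excluded from the sum with K reduced (a
    documented deviation; the source formula assumes r_k > 0).
    """
    keep = ranges.r_k > 0
    if not keep.any():
        raise ValueError("all covariates have zero range; G2 undefined")
    if not keep.all():
        _warnings.warn("zero-range covariate(s) excluded from Gower's distance; "
                       "K reduced accordingly")
    k = int(keep.sum())
    xs = x[:, keep] / ranges.r_k[keep]
    ys = y[:, keep] / ranges.r_k[keep]
    return cdist(xs, ys, metric="cityblock") / k


def gower_distance(a: np.ndarray, b: np.ndarray, ranges: Ranges) -> float:
    """G2 between two single records (range-standardised mean |difference|)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return float(_gower_matrix(a, b, ranges)[0, 0])


def geometric_mean_gower(available: EnvDataset, ranges: Ranges | None = None,
                         ) -> float:
    """GV: geometric mean of G2 over all unordered pairs of available records.

    Duplicate environmental points are collapsed to their unique values
    before the pairwise distances are taken — a single duplicate would
    otherwise contribute a zero-distance pair and collapse the geometric
    mean to zero; the number of duplicates dropped is reported via a warning.
    """
    if available.n < 2:
        raise ValueError("need at least 2 available records for GV")
    if ranges is None:
        ranges = covariate_ranges(available)
    keep = ranges.r_k > 0
    if not keep.any():
        raise ValueError("all covariates have zero range; G2 undefined")
    x = available.records[:, keep] / ranges.r_k[keep]
    uniq = np.unique(x, axis=0)
    if len(uniq) < 2:
        raise ValueError("all available records coincide; no usable radius")
    if len(uniq) < len(x):
        _warnings.warn(f"{len(x) - len(uniq)} duplicate record(s) (zero-distance "
                       "pairs) excluded from the geometric mean")
    d = pdist(uniq, metric="cityblock") / int(keep.sum())
    return float(np.exp(np.mean(np.log(d))))


def proportion_nearby(available: EnvDataset, prediction: EnvDataset,
                      gv: float | None = None, ranges: Ranges | None = None,
                      ) -> pd.Series:
    """Fraction of available points within G2 <= GV of each prediction point."""
    if ranges is None:
        ranges = covariate_ranges(available)
    if gv is None:
        gv = geometric_mean_gower(available, ranges)
    if gv <= 0:
        raise ValueError("GV must be positive")
    if prediction.n == 0:
        return pd.Series(np.zeros(0), name="proportion_nearby")
    d = _gower_matrix(prediction.records, available.records, ranges)
    frac = (d <= gv).sum(axis=1) / available.n
    return pd.Series(frac, name="proportion_nearby")


# -- extents and summaries ---------------------------------------------------

def extrapolation_extent(hull_classes: pd.Series | np.ndarray) -> float:
    """Percentage of prediction records classified as extrapolation."""
    labels = np.asarray(hull_classes)
    if labels.size == 0:
        raise ValueError("no prediction records")
    return round(100.0 * float((labels == "extrapolation").sum()) / labels.size, 1)


@dataclass
class MonthlySummary:
    """Mean / min / max of monthly extrapolation extents, with arg-months."""

    mean: float
    min: float
    min_month: int
    max: float
    max_month: int

    def format(self) -> str:
        """E.g. ``'49.9% (8.1% in September - 55.1% in February)'``."""
        return (f"{self.mean:.1f}% ({self.min:.1f}% in "
                f"{MONTH_NAMES[self.min_month - 1]} - {self.max:.1f}% in "
                f"{MONTH_NAMES[self.max_month - 1]})")


def monthly_summary(extents: dict[int, float]) -> MonthlySummary:
    """Summarise per-month extents: arithmetic mean, min and max with months."""
    if not extents:
        raise ValueError("no monthly extents supplied")
    if len(extents) < 12:
        _warnings.warn(f"only {len(extents)} of 12 months supplied; summary "
                       "computed over available months")
    months = sorted(extents)
    values = np.array([extents[m] for m in months])
    i_min, i_max = int(values.argmin()), int(values.argmax())
    return MonthlySummary(mean=round(float(values.mean()), 1),
                          min=float(values[i_min]), min_month=months[i_min],
                          max=float(values[i_max]), max_month=months[i_max])


# -- orchestration over one combination --------------------------------------

@dataclass
class GapResult:
    """Gap metrics for one covariate combination and one prediction dataset."""

    covariate_names: tuple[str, ...]
    month: int | None
    table: pd.DataFrame       # cell_id, per-covariate class, hull_class, proportion_nearby
    extent_pct: float
    gv: float
    univariate_extent_pct: dict[str, float] = field(default_factory=dict)


def analyze_combination(available: EnvDataset, prediction: EnvDataset,
                        covariate_names=None, month: int | None = None) -> GapResult:
    """Run the full metric set for one covariate combination.

    The available dataset is the single pooled set of surveyed
    cell-year-month records; month-specific results vary only through the
    prediction dataset.
    """
    if covariate_names is not None:
        available = available.select(covariate_names)
        prediction = prediction.select(covariate_names)
    ranges = covariate_ranges(available)
    uni = classify_univariate(ranges, prediction)
    hull = hull_membership(available, prediction)
    gv = geometric_mean_gower(available, ranges)
    near = proportion_nearby(available, prediction, gv, ranges)
    table = pd.DataFrame({"cell_id": prediction.frame["cell_id"].to_numpy()})
    for c in available.covariate_names:
        table[f"class_{c}"] = uni[c].to_numpy()
    table["hull_class"] = hull.to_numpy()
    table["proportion_nearby"] = near.to_numpy()
    uni_extents = {
        c: round(100.0 * float((uni[c] != "within").sum()) / len(uni), 1)
        for c in available.covariate_names}
    return GapResult(covariate_names=available.covariate_names, month=month,
                     table=table, extent_pct=extrapolation_extent(hull),
                     gv=gv, univariate_extent_pct=uni_extents)
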