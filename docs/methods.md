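# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `envgap`, at the level of detail a maintainer or reviewer
needs to judge what the package does and does not demonstrate.

## The analysis model

The pipeline treats a survey program as a sample of environmental space and
asks how representative that sample is of the space where predictions are
wanted. Its assumptions:

* **Equal-area planar grid.** All inputs are in projected planar kilometres;
  cells are squares of `cell_size` km (default 10), identified row-major from
  the lower-left origin. Cell extents are half-open `[x, x + s)` so that any
  point, including points exactly on shared edges, belongs to exactly one
  cell, and a trackline touching a cell corner contributes zero length there.
  Reprojection from geographic coordinates is upstream of this package.
* **A surveyed cell is any cell with effort > 0** in a stratum; no
  minimum-effort threshold is applied (`EffortGrid.surveyed_cells`
  documents this; a threshold can be imposed by filtering the effort frame).
* **One available record per (cell, year, month).** Several tracklines
  surveying the same cell in the same month add no new environmental
  information, and duplicated points would bias the geometric-mean radius
  downward. `dedupe=False` keeps one record per (cell, year, month, platform,
  organisation) stratum instead, for sensitivity analysis.
* **Available versus prediction resolution.** Available records take
  *contemporaneous* dynamic values (the cell's field in the survey's month
  and year); prediction records take *climatological* values (per-cell
  monthly means over the climatology period). The comparison is therefore
  between surveyed conditions and long-term average conditions, not the
  conditions of any particular year. One pooled available dataset serves all
  twelve prediction months.
* **Missing values** (emulating cloud gaps in remote-sensing products) cause
  listwise exclusion of the affected record, with counts reported in a QC
  dict; no gap-filling or imputation is performed, since imputed values would
  manufacture environmental space that was never sampled.

## The metrics

For covariates k = 1..K with available ranges r_k = max_k − min_k:

* **Envelope classes**: below / within / above the available [min, max],
  endpoints inclusive (a prediction exactly at the minimum interpolates).
* **Hull membership**: interpolation iff the point is a convex combination of
  available points. Decided per point by an LP feasibility problem
  (variables λ ≥ 0, constraints Σλ = 1 and Aᵀλ = x) solved with HiGHS in
  range-standardised coordinates (each covariate divided by r_k, making the
  test invariant to units). Tolerance 1e-9 after standardisation; points
  within tolerance of the boundary count as interpolation. Two exact
  shortcuts change no answers: points outside the bounding box are
  extrapolations without a solve (the hull's axis projections are the
  envelopes), and for K = 1 the bounding-box test *is* the hull test. For
  K ≤ 4 the LP's generator set is reduced to the hull vertices (exact facet
  enumeration is cheap there); at K = 7 with ~10³ points the facet count
  makes enumeration impractical, which is why the per-point LP is the
  primary algorithm. A triangulation point-location oracle is kept in the
  test suite as an independent cross-check up to 3-D.
* **Gower's distance** G² = (1/K) Σ |Δx_k| / r_k. Covariates with r_k = 0
  (possible only in degenerate inputs) are dropped from the sum with K
  reduced, and their envelopes collapse to a point; a warning is emitted.
* **Neighbourhood radius GV**: the geometric mean of G² over all unordered
  pairs of *unique* available points. Duplicates are collapsed first —
  a single duplicated point would contribute a zero-distance pair and force
  the geometric mean to zero; under subset combinations (e.g. static-only,
  where many records share one cell's values) duplicates are routine.
  The dropped count is reported. "Nearby" is the closed ball G² ≤ GV.
* **Extent of extrapolation**: 100 × extrapolative / total prediction
  records, reported to 0.1%. Dynamic combinations are summarised over months
  by arithmetic mean, minimum and maximum with their arg-months.

## The synthetic basin

The generator produces the statistical structure the analysis assumes, not
the geography of any real sea. Defaults (all overridable via `BasinConfig`,
`FieldParams`, `SurveyDesign`):

* **Grid**: 60 × 30 cells of 10 km; land, when requested, is a connected
  band of sinusoidally varying width along the northern edge; subregions are
  eight contiguous longitudinal bands of ~equal sea-cell count.
* **Statics**: depth follows an exponential shelf–slope–abyss profile of the
  distance to coast (max 2800 m, e-folding 60 km); slope is the local depth
  gradient magnitude (m/km); seamount points are scattered over deep cells
  and canyon points over the northern slope, both on cell centres so host
  cells are at distance zero.
* **Dynamics** (monthly, per year): SST = 14 °C + 5 °C west→east gradient +
  6 °C seasonal cosine peaking in August + per-year anomaly (sd 0.3 °C) +
  noise; PP = 250 + 150 east→west gradient + a 300-unit Gaussian bloom
  centred on March (sd 1.5 months), doubled in the northern third of the
  basin, + noise; EKE = 40 + 400 × Gaussian bumps at three fixed hotspots
  (radius 60 km) with a winter-peaking seasonal modulation + noise. Noise is
  relative to each field's amplitude (`noise_sd`, default 0 so that tests
  can assert exact recovery of the closed forms; the demo scenario uses
  0.05). An optional `missing_fraction` blanks random (cell, month) values.
* **Surveys**: each survey is a 4-connected lattice random walk over sea
  cells joined through cell centres (guaranteeing every vertex and segment
  lies in sea), with Poisson-distributed length around
  `mean_trackline_length`/`cell_size` steps. Start cells and months are
  drawn with multiplicative weights 1 + concentration on the favoured
  subregion(s) and on May–September; platform is Bernoulli(`platform_mix`),
  organisations rotate round-robin.

What the generator does **not** emulate: spatially correlated noise,
advective structure connecting fields, inter-covariate dependence beyond the
shared gradients, observation effects (sea state, detection), or realistic
trackline geometry (parallel transect designs). Passing tests therefore show
the *metrics and plumbing* are correct under the assumed structure; they do
not validate conclusions about any real basin.

## Demonstration scenario and problem sizes

The bundled demo (`envgap report`, `scripts/acceptance.py`) uses an all-sea
60 × 30 basin (1800 cells), 3 years × 12 months of dynamics, and 150 surveys
with geographic concentration 30 on the four western subregions and seasonal
concentration 8 on May–September — a deliberately biased program in the
style of real aggregated survey archives. This yields ~940 available
records; the gap analysis runs the seven univariate and three multivariate
combinations over 12 climatological months. Property-test sizes (100 random
2-D/3-D hull instances with N, M ≤ 200; 50 random 7-covariate instances;
1000 random tracklines for effort conservation) were chosen so the whole
suite completes in a few minutes on one core.

## Numerical choices and edge cases

* Effort splitting computes exact parametric intersections with the grid
  lines; conservation (Σ per-cell = Σ clipped length) holds to 1e-9
  relative. Sub-segments over land or outside the grid are clipped into a
  discard log, never credited. Tracklines crossing the study-area boundary
  are clipped rather than dropped. A whole trackline carries its single
  recorded date (strata are monthly; sub-day precision is immaterial).
* Nearest-neighbour resampling assigns each grid-cell centre the value of
  the nearest source-cell centre; exact ties break toward the lower index.
* Climatology means skip missing contributors and keep per-cell contributor
  counts; a cell-month with zero contributors stays missing.
* The Spearman collinearity screen (threshold |ρ| ≥ 0.6) is advisory only:
  it warns, and never drops covariates.
* Degenerate hulls (available points in an affine subspace) are handled
  naturally by the LP: membership means membership in the flat hull.
* Zero total effort yields summaries flagged `zero_total` rather than an
  error; an empty available dataset is an error (the analysis is undefined).

## Known limitations

* The LP hull test is exact only up to the 1e-9 feasibility tolerance;
  points astronomically close to a facet may be classified either way.
* GV on unique points means the radius ignores sampling *multiplicity*;
  the proportion-of-data-nearby metric, by contrast, counts all available
  records and so does reflect multiplicity.
* Monthly summaries over fewer than 12 analysed months warn and summarise
  what exists.
* ESRI ASCII output stores full float repr for lossless round-trips, which
  is verbose; pass rasters through any GIS for compact storage.
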