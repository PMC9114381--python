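# Methods

This document describes the model implemented by `firegrowth`, the
assumptions behind it, every tunable parameter with its default and
rationale, the design of the synthetic validation module, and known
limitations.

## 1. Problem and data model

The goal is to reconstruct the daily growth of large wildfires from
satellite active-fire point detections and to estimate the daily rate of
spread (ROS) along the fire line. Inputs:

- **Active-fire detections** — a CSV in the VIIRS 375 m I-band dialect:
  latitude, longitude, acquisition date and time, fire radiative power (FRP,
  MW, possibly missing), a day/night flag and an overpass identifier. A
  polar orbiter yields roughly two observations per day: an afternoon
  overpass (~13:30 local) and a night overpass (~01:30 local).
- **Final fire perimeters** — GeoJSON polygons with ignition cause
  (`human`, `lightning` or `unknown`), alarm (ignition) date and containment
  date. Attribute names are remappable in the configuration.
- **Burn-severity rasters** (optional) — dNBR, rdNBR or percent basal-area
  tree mortality, as ESRI ASCII grids at ~30 m.

All geometry is processed on a projected equal-area plane in metres. A
hand-implemented ellipsoidal Albers equal-area conic (GRS80; standard
parallels 34° and 40.5°, origin −120°, false northing −4 000 000 m — the
standard California configuration) converts lon/lat to plane coordinates; its
forward/inverse pair round-trips to sub-millimetre accuracy and its area
distortion is zero by construction. Other regions can supply their own
parameters via `Config`.

## 2. Fire selection and detection extraction

- Fires smaller than **300 ha** (`min_area_ha`) or burning fewer than
  **2 days** (`min_days`) are excluded: below that size a fire rarely spans
  enough 375 m pixels across multiple days to support perimeter
  reconstruction.
- A fire's detections are those within a **750 m buffer** (`buffer_m`,
  two detection footprints) of its final perimeter, between alarm and
  containment dates padded by **±1 day** (`day_pad_days`) to absorb
  reporting-time ambiguity. When either date is missing, a **3-month
  window** (`fallback_window_months`) starting at the first in-buffer
  detection is used instead.
- Rows with coordinates outside WGS84 bounds are rejected and counted.

## 3. Fire days and sub-fires

- Detections are grouped into **fire days**: the local day boundary is
  06:00 (`day_start_hour`), so an afternoon overpass and the following
  night's overpass fall in the same group. The group's timestamp
  (`timestep_end`) is the last overpass in it; the interval Δt between
  consecutive groups (in days, possibly > 1 when overpasses are missed) is
  the time base for ROS.
- Where swaths overlap, the same pixel can be reported twice minutes apart;
  duplicates (coordinates equal after rounding to 1e-5°, `dedup_tol_deg`)
  keep only the **last** overpass.
- Each day's detections are split into single-linkage connected components
  at **1500 m** (`link_dist_m`, four footprints). Components continue the
  nearest existing sub-fire (within 1500 m of its latest perimeter), start a
  new sub-fire, or — when one component touches two or more sub-fires —
  **merge** them: the absorbed sub-fires go inactive and their history moves
  to the survivor, so subsequent perimeters are drawn around all of them
  together.

## 4. Perimeter reconstruction

Each sub-fire's daily perimeter is the **alpha hull** (concave hull) of all
its detections up to that day, treating each detection as the centre of a
burning pixel.

- **Alpha convention.** The hull keeps every Delaunay triangle whose
  circumradius is at most `alpha` (in km) and unions them. Small alpha
  yields a tight, possibly fragmented shape; alpha → ∞ yields the convex
  hull. This is the disc-radius convention of the common R implementation.
- **Adaptive escalation.** Starting at `alpha0_km = 0.05`, alpha is raised
  in `alpha_step_km = 0.05` steps until the hull is a **single connected
  polygon that contains every input point** (tolerance 1 m). Holes are
  filled: a fire's interior is burned even where no pixel was detected. If
  `alpha_max_km` (50) is exhausted, the convex hull is used and flagged with
  the sentinel `alpha_used = -1.0`.
- **Degenerate inputs.** One or two points, or collinear points, have no
  triangulation; they are buffered by half a footprint (187.5 m,
  `footprint_m / 2`), so a single detection becomes a disk of area
  π·187.5² m².
- **Monotonicity.** Day *k*'s polygon is the union of the new hull with day
  *k−1*'s polygon, so perimeters never shrink and cumulative area is
  non-decreasing. The fire-level daily area is the union over its active
  sub-fires.

## 5. Rate of spread

- The **fire line** on day *k* is the set of that day's detections within
  **100 m** (`line_band_m`) of the day-*k* perimeter boundary.
- Each fire-line detection's ROS is its Euclidean distance to the day-*k−1*
  perimeter (zero if inside it) divided by the elapsed Δt in days, in
  km/day. Day 1 has no ROS.
- The **daily ROS** is the **95th percentile** (`ros_percentile`, linear
  interpolation between order statistics) of the day's samples — high
  enough to capture the advancing head of the fire, robust to the single
  fastest outlier. The mean is reported alongside; zeros (flanks and
  interior cleanup) are included in both. Daily mean FRP over fire-line
  detections is reported, skipping missing values.

## 6. Analysis

- **Burned-area-weighted mean ROS** per fire:
  `ros_ba = Σ BA_i · RoS_i / Σ BA_i` over its fire days, where `BA_i` is day
  *i*'s newly burned area. This prevents slow tail days from dominating a
  fire's mean spread rate.
- **Group comparisons** (e.g. human vs lightning ignitions): Welch's
  unequal-variance *t* test — on log-transformed values for heavy-tailed
  size/ROS variables, with offset ε = half the smallest positive value when
  zeros are present — plus the two-sample Kolmogorov–Smirnov test, which is
  invariant under the log transform and is computed on the raw values.
- **Distributions and concentration**: ROS histograms weighted by fire days
  or by burned area, and the share of total burned area contributed by the
  fastest 10% of fire days (ties at the cutoff included).
- **Severity**: each day's *expansion* polygon (today's perimeter minus
  yesterday's, skipped below `min_expansion_ha = 1` ha) samples the severity
  raster by the pixel-centre rule, nodata excluded; daily severity means are
  regressed on daily ROS by OLS (slope, R², F = t², p), with a centred
  running mean (window = max(51, 5% of n)) for visualisation. Fire-level
  severity is the pixel-weighted mean of daily means, or the 95th percentile
  over the fire's pooled pixels.

## 7. Synthetic validation module

`firegrowth.synthetic` provides ground truth that real archives cannot:

- **Growth model.** Each fire has per-day true spread rates (km/day) and
  grows as a radial or elliptical (wind-driven) front from one or more
  ignition points; multi-ignition fires merge naturally when fronts meet.
  Daily true polygons, areas and directional spread rates are recorded
  exactly.
- **Observation model.** Detections are the centres of 375 m lattice cells
  (a fixed global lattice, mimicking sensor gridding) inside each day's
  newly burned band, emitted at the 13:30 overpass and again at the 01:30
  overpass of the following night — exercising the fire-day grouping and
  swath dedup logic. Each emission is kept with a configurable detection
  probability (swath gaps, cloud). FRP increases with local true ROS with
  lognormal noise and a configurable missing fraction. Zero-growth days emit
  a smouldering ring just inside the front. All randomness derives from one
  seed through a fixed PCG64 generator.
- **Severity model.** 30 m rasters where each burned pixel carries
  `link(local true ROS on its burn day)` plus Gaussian noise; the default
  link is a saturating mortality curve `min(15 + 16.5·ros, 100)` %, and
  unburned pixels are nodata.
- **Populations.** `population_scenarios` builds a two-cause population with
  log-normally distributed day-1 ROS (faster for the human-labelled group)
  on a coarse spatial grid so fires never interact.

`recovery_report` scores tracked output against truth (per-day ROS and area
relative errors, bias, RMSE). The benchmark in `scripts/acceptance.py` and
the acceptance tests use fires of 3–5 days and populations of 60 fires:
large enough for stable statistics, small enough to run in minutes on one
CPU.

## 8. Numerical choices

- Percentiles use linear interpolation between order statistics (numpy's
  default, type 7), pinned by oracle tests.
- Alpha-hull candidate alphas that do not change the kept-triangle set are
  skipped, and connectivity is pre-checked on the triangle adjacency graph
  before any polygon union, keeping escalation cheap.
- Geometry containment checks use a 1 m tolerance; GeoJSON output rounds
  coordinates to 1e-7° for byte-stable round trips.
- Statistical tests call SciPy (`ttest_ind(equal_var=False)`, `ks_2samp`);
  the test suite re-derives them from textbook formulas as an independent
  oracle.

## 9. Limitations

- **Lattice quantization floor.** A 375 m detection grid cannot resolve
  daily advances much below one cell: for a true ROS of 0.5 km/day the
  per-day estimates are quantized to lattice vector lengths (≈0.53 and
  0.75 km/day), a relative error floor of roughly +30% that disappears at
  finer spacing. ROS estimates for slow fires should be read with an
  absolute error bound of about one cell per day.
- **Hull-vs-front bias.** The hull of pixel centres lies inside the true
  front by up to half a cell, so tracked areas are biased a few percent low,
  most visibly on day 1 of small fires; the bias shrinks as the fire grows
  and as spacing decreases.
- Perimeters are monotone by construction, so unburned islands and
  perimeter corrections are not representable; interior holes are
  deliberately filled.
- Timestamps are treated as local clock time; data spanning time zones or
  DST changes need pre-normalisation.
- Shapefile and GeoTIFF I/O are not included; inputs must be GeoJSON and
  ESRI ASCII grids.
- The KS test uses the asymptotic distribution; p-values for very small
  groups (< ~10 per side) are approximate.
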