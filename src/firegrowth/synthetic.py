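"""Ground-truthed synthetic fires.

Emulates what the tracking method consumes — satellite-style point
detections on a ~375 m lattice at a 12-hour overpass cadence, final
perimeters with cause labels, and 30 m severity rasters — for fires whose
true daily growth is known exactly. Fires grow as radial or elliptical
fronts (a Huygens-style kinematic model; no fuel or weather physics), which
gives exact daily perimeters, areas and directional spread rates against
which the estimates can be scored. Multi-ignition scenarios produce fronts
that later merge, exercising the sub-fire splitting/merge logic. All
randomness flows from a single seed through numpy's PCG64 generator, so runs
are reproducible across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Callable, Sequence

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .io_formats import AlbersEqualArea, Detection, FireRecord, SeverityRaster

log = logging.getLogger(__name__)


@dataclass
class FireScenario:
    """Growth prescription for one synthetic fire.

    ``ros_schedule`` is the true spread rate (km/day) of the front's minor
    axis for each burning day; ``elongation`` stretches the front along
    ``orientation_deg`` (1 = circular), emulating wind-driven ellipses. All
    ignitions of a multi-ignition fire share the schedule.
    """

    fire_id: str
    cause: str                               # "human" | "lightning" | "unknown"
    ignitions: list[tuple[float, float]]     # projected metres
    ros_schedule: list[float]                # km/day, one entry per day
    elongation: float = 1.0
    orientation_deg: float = 0.0
    start_date: date = date(2017, 7, 1)


@dataclass
class SimConfig:
    """Observation-process parameters shared by all fires of a simulation."""

    seed: int
    scenarios: list[FireScenario] = field(default_factory=list)
    spacing_m: float = 375.0                 # detection lattice spacing
    detect_prob: float = 1.0                 # per-overpass detection probability
    day_overpass: time = time(13, 30)        # afternoon overpass (local)
    night_overpass: time = time(1, 30)       # following-night overpass (local)
    frp_base: float = 10.0                   # MW scale of simulated FRP
    frp_ros_gain: float = 20.0               # MW per (km/day) of local ROS
    frp_noise_sigma: float = 0.3             # lognormal sigma on FRP
    frp_missing_prob: float = 0.05           # fraction of missing FRP values
    rng_algorithm: str = "PCG64"             # fixed for cross-platform runs


@dataclass
class SimTruth:
    """Exact daily ground truth for one simulated fire."""

    fire_id: str
    start_date: date
    daily_polygons: list[BaseGeometry]       # strictly nested over time
    daily_area_km2: list[float]
    ros_schedule: list[float]                # km/day (minor axis)
    true_max_ros: list[float]                # km/day, fastest direction
    true_mean_ros: list[float]               # km/day, direction-averaged
    elongation: float
    orientation_deg: float
    ignitions: list[tuple[float, float]]


def _unit_ellipse_mean_radius(elong: float, n: int = 3600) -> float:
    """Direction-averaged radius of the ellipse with semi-axes (elong, 1)."""
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    r = elong / np.sqrt((np.cos(th)) ** 2 + (elong * np.sin(th)) ** 2)
    return float(np.mean(r))


def _front_polygon(center: tuple[float, float], b_m: float, elong: float,
                   orient_deg: float) -> BaseGeometry:
    """Elliptical front with semi-minor axis ``b_m`` metres."""
    circ = Point(0.0, 0.0).buffer(1.0, quad_segs=90)
    ell = affinity.scale(circ, xfact=elong * b_m, yfact=b_m)
    ell = affinity.rotate(ell, orient_deg)
    return affinity.translate(ell, xoff=center[0], yoff=center[1])


def _lattice_points_in(geom: BaseGeometry, spacing: float) -> np.ndarray:
    """Global-lattice pixel centers (spacing-aligned) falling inside a
    geometry. The lattice is anchored at the projection origin, mimicking a
    fixed sensor grid."""
    minx, miny, maxx, maxy = geom.bounds
    i0 = math.floor(minx / spacing)
    i1 = math.ceil(maxx / spacing)
    j0 = math.floor(miny / spacing)
    j1 = math.ceil(maxy / spacing)
    xs = (np.arange(i0, i1 + 1) + 0.5) * spacing
    ys = (np.arange(j0, j1 + 1) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    inside = shapely.contains_xy(geom, gx, gy)
    return np.column_stack([gx[inside], gy[inside]])


def simulate_fire(scenario: FireScenario, config: SimConfig,
                  projection: AlbersEqualArea | None = None,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[list[Detection], FireRecord, SimTruth]:
    """Simulate one fire's detections, final-perimeter record and truth.

    Each day the true front advances by the day's scheduled ROS; the newly
    burned band is sampled at the lattice points, each kept with the
    configured per-overpass probability at the afternoon overpass and again
    at the following night overpass (duplicate coordinates are left in — the
    grouping step is expected to deduplicate overlapping swaths).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    proj = projection or AlbersEqualArea()
    sched = list(scenario.ros_schedule)
    if not sched or any(r < 0 for r in sched):
        raise ValueError("ros_schedule must be non-empty and non-negative")

    mean_rad = _unit_ellipse_mean_radius(scenario.elongation)
    cums = np.cumsum(sched)  # km
    daily_polys: list[BaseGeometry] = []
    for k, cum_km in enumerate(cums):
        fronts = [_front_polygon(c, cum_km * 1000.0, scenario.elongation,
                                 scenario.orientation_deg)
                  for c in scenario.ignitions]
        daily_polys.append(unary_union(fronts))

    detections: list[Detection] = []
    det_n = 0
    for k, poly in enumerate(daily_polys):
        if k == 0:
            band = poly
        elif sched[k] == 0:
            # smoldering day: the front does not advance but the fire is
            # still detected along the previous front
            band = poly.difference(poly.buffer(-1.5 * config.spacing_m))
        else:
            band = poly.difference(daily_polys[k - 1])
        pts = _lattice_points_in(band, config.spacing_m)
        if len(pts) == 0 and sched[k] > 0:
            log.debug("fire %s day %d: empty band at this lattice spacing",
                      scenario.fire_id, k + 1)
        d_date = scenario.start_date + timedelta(days=k)
        overpasses = [
            (datetime.combine(d_date, config.day_overpass), "day",
             f"{d_date:%Y%m%d}_D"),
            (datetime.combine(d_date + timedelta(days=1),
                              config.night_overpass), "night",
             f"{d_date + timedelta(days=1):%Y%m%d}_N"),
        ]
        local_ros = sched[k]
        for when, dn, op_id in overpasses:
            keep = rng.random(len(pts)) < config.detect_prob
            for x, y in pts[keep]:
                lon, lat = proj.inverse(x, y)
                if rng.random() < config.frp_missing_prob:
                    frp = None
                else:
                    frp = float((config.frp_base
                                 + config.frp_ros_gain * local_ros)
                                * rng.lognormal(0.0, config.frp_noise_sigma))
                detections.append(Detection(
                    det_id=f"{scenario.fire_id}-{det_n}", lon=float(lon),
                    lat=float(lat), x=float(x), y=float(y), acq_time=when,
                    frp=frp, daynight=dn, overpass_id=op_id))
                det_n += 1

    final = daily_polys[-1]
    record = FireRecord(
        fire_id=scenario.fire_id, cause=scenario.cause, final_perimeter=final,
        alarm_date=scenario.start_date,
        containment_date=scenario.start_date + timedelta(days=len(sched)),
        final_area_km2=final.area / 1e6)
    truth = SimTruth(
        fire_id=scenario.fire_id, start_date=scenario.start_date,
        daily_polygons=daily_polys,
        daily_area_km2=[p.area / 1e6 for p in daily_polys],
        ros_schedule=sched,
        true_max_ros=[scenario.elongation * r for r in sched],
        true_mean_ros=[mean_rad * r for r in sched],
        elongation=scenario.elongation,
        orientation_deg=scenario.orientation_deg,
        ignitions=list(scenario.ignitions))
    return detections, record, truth


def simulate_all(config: SimConfig,
                 projection: AlbersEqualArea | None = None,
                 ) -> tuple[list[Detection], list[FireRecord], dict[str, SimTruth]]:
    """Simulate every scenario of a config with one shared RNG stream."""
    rng = np.random.default_rng(config.seed)
    dets: list[Detection] = []
    recs: list[FireRecord] = []
    truths: dict[str, SimTruth] = {}
    for sc in config.scenarios:
        d, r, t = simulate_fire(sc, config, projection, rng)
        dets.extend(d)
        recs.append(r)
        truths[sc.fire_id] = t
    return dets, recs, truths


# ---------------------------------------------------------------------------
# Severity
# ---------------------------------------------------------------------------

def default_mortality_link(ros) -> np.ndarray:
    """Saturating linear ROS -> percent tree mortality link used as the
    simulation regime: slow fronts (<0.5 km/day) average roughly 15-20%
    mortality and fast fronts (>2 km/day) roughly 50%, capped at 100."""
    return np.minimum(15.0 + 16.5 * np.asarray(ros, dtype=float), 100.0)


def simulate_severity(truth: SimTruth, link: Callable = default_mortality_link,
                      noise_sd: float = 0.0, cellsize_m: float = 30.0,
                      metric: str = "tree_mortality_pct",
                      seed: int = 0) -> SeverityRaster:
    """30 m severity raster tied to the true local spread rate.

    Each burned pixel gets ``link(local true ROS on its burn day)`` plus
    Gaussian noise; unburned pixels are nodata. The local true ROS accounts
    for the elliptical front: it is the day's scheduled rate scaled by the
    directional radius toward the pixel from its nearest ignition point.
    """
    rng = np.random.default_rng(seed)
    final = truth.daily_polygons[-1]
    minx, miny, maxx, maxy = final.bounds
    pad = 2 * cellsize_m
    xll = math.floor((minx - pad) / cellsize_m) * cellsize_m
    yll = math.floor((miny - pad) / cellsize_m) * cellsize_m
    ncols = int(math.ceil((maxx + pad - xll) / cellsize_m))
    nrows = int(math.ceil((maxy + pad - yll) / cellsize_m))
    xs = xll + (np.arange(ncols) + 0.5) * cellsize_m
    ys = yll + (nrows - np.arange(nrows) - 0.5) * cellsize_m
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()

    burn_day = np.full(gx.shape, -1, dtype=int)
    prev_inside = np.zeros(gx.shape, dtype=bool)
    for k, poly in enumerate(truth.daily_polygons):
        inside = shapely.contains_xy(poly, gx, gy)
        burn_day[inside & ~prev_inside] = k
        prev_inside |= inside

    # directional factor of the front toward each pixel
    cx = np.array([c[0] for c in truth.ignitions])
    cy = np.array([c[1] for c in truth.ignitions])
    d2 = (gx[:, None] - cx) ** 2 + (gy[:, None] - cy) ** 2
    nearest = np.argmin(d2, axis=1)
    th = (np.arctan2(gy - cy[nearest], gx - cx[nearest])
          - math.radians(truth.orientation_deg))
    e = truth.elongation
    dir_factor = e / np.sqrt(np.cos(th) ** 2 + (e * np.sin(th)) ** 2)

    nodata = -9999.0
    values = np.full(gx.shape, nodata)
    burned = burn_day >= 0
    sched = np.asarray(truth.ros_schedule)
    local_ros = sched[burn_day[burned]] * dir_factor[burned]
    v = np.asarray(link(local_ros), dtype=float)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    if metric == "tree_mortality_pct":
        v = np.clip(v, 0.0, 100.0)
    values[burned] = v
    return SeverityRaster(metric=metric, values=values.reshape(nrows, ncols),
                          xll=float(xll), yll=float(yll),
                          cellsize=float(cellsize_m), nodata=nodata)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def recovery_report(summaries, truth: SimTruth) -> dict:
    """Score tracked estimates against simulator truth.

    ``summaries`` are the tracker's FireDaySummary rows for this fire,
    day-aligned with the truth (fire day k estimates the growth of truth day
    k). Reports per-day relative errors of the daily ROS (vs the true
    fastest-direction rate) and of the cumulative area, plus suite-level
    bias and RMSE of the ROS errors for days 2 onward.
    """
    rows = []
    by_day = {s.day_index: s for s in summaries}
    for k in range(1, len(truth.ros_schedule) + 1):
        s = by_day.get(k)
        if s is None:
            continue
        true_area = truth.daily_area_km2[k - 1]
        row = {
            "fire_id": truth.fire_id, "day_index": k,
            "true_area_km2": true_area,
            "est_area_km2": s.cumulative_area_km2,
            "area_rel_err": (s.cumulative_area_km2 - true_area) / true_area,
            "true_max_ros": truth.true_max_ros[k - 1],
            "est_ros_p95": s.ros_p95,
        }
        if k >= 2 and not math.isnan(s.ros_p95) and truth.true_max_ros[k - 1] > 0:
            row["ros_rel_err"] = ((s.ros_p95 - truth.true_max_ros[k - 1])
                                  / truth.true_max_ros[k - 1])
        else:
            row["ros_rel_err"] = math.nan
        rows.append(row)
    errs = np.array([r["ros_rel_err"] for r in rows
                     if not math.isnan(r["ros_rel_err"])])
    return {
        "per_day": rows,
        "ros_bias": float(np.mean(errs)) if errs.size else math.nan,
        "ros_rmse": float(np.sqrt(np.mean(errs**2))) if errs.size else math.nan,
        "ros_median_rel_err": float(np.median(errs)) if errs.size else math.nan,
    }


# ---------------------------------------------------------------------------
# Population scenarios (ignition-cause contrast)
# ---------------------------------------------------------------------------

def population_scenarios(seed: int, n_human: int = 30, n_lightning: int = 30,
                         n_days: int = 3, human_ros_mu: float = 0.6,
                         lightning_ros_mu: float = -0.4,
                         ros_sigma: float = 0.6,
                         spacing_km: float = 60.0) -> list[FireScenario]:
    """Scenario population with faster day-1 spread for human-labelled fires.

    Day-1 true ROS is log-normal, ``exp(N(mu, sigma))`` km/day, with a higher
    location parameter for the human group; later days decay geometrically.
    Fires are laid out on a coarse grid so they never interact spatially.
    """
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for cause, n, mu in (("human", n_human, human_ros_mu),
                         ("lightning", n_lightning, lightning_ros_mu)):
        for i in range(n):
            r1 = float(rng.lognormal(mu, ros_sigma))
            sched = [r1 * (0.6 ** d) for d in range(n_days)]
            gx = (idx % 12) * spacing_km * 1000.0
            gy = (idx // 12) * spacing_km * 1000.0
            out.append(FireScenario(
                fire_id=f"{cause[:1]}{i:03d}", cause=cause,
                ignitions=[(gx, gy)], ros_schedule=sched,
                start_date=date(2017, 7, 1)))
            idx += 1
    return out
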