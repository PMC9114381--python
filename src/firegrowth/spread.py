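"""Rate-of-spread estimation along the daily fire line.

For each fire day, the detections forming the active fire line are those
within a narrow band (default 100 m, either side) of the current perimeter
boundary. Each line point's spread sample is the minimum distance to the
previous timestep's perimeter divided by the elapsed time between timesteps;
points that did not advance past the old perimeter score exactly zero. The
daily summary takes the 95th percentile over all line samples (a conservative
estimate of the day's maximum spread rate) as well as the mean, plus the
day's expansion area and the mean fire radiative power along the line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .io_formats import Detection

log = logging.getLogger(__name__)


@dataclass
class SpreadSample:
    """One detection's contribution to the daily spread-rate distribution."""

    det_id: str
    day_index: int
    dist_to_prev_m: float   # minimum distance to the previous perimeter
    dt_days: float          # elapsed time between the two timestep ends
    ros: float              # km / day

    def __post_init__(self):
        if self.dt_days <= 0:
            raise ValueError("dt must be positive")


@dataclass
class FireDaySummary:
    """Per fire-day summary. ROS fields are NaN on a fire's first day (no
    previous perimeter exists) and on days with no fire-line samples."""

    fire_id: str
    day_index: int
    ros_p95: float            # km/day, NaN if undefined
    ros_mean: float           # km/day, NaN if undefined
    expansion_area_km2: float
    cumulative_area_km2: float
    mean_frp: float           # MW over line detections with known FRP; NaN if none
    n_line_detections: int
    n_samples: int = 0


def fire_line_points(detections: list[Detection], perimeter_today: BaseGeometry,
                     band_m: float = 100.0) -> list[Detection]:
    """Detections on the active fire line: within ``band_m`` of today's
    perimeter boundary, on either side. Deep-interior (smoldering) points are
    excluded; an empty result simply yields no spread samples for the day."""
    if not detections:
        return []
    boundary = perimeter_today.boundary
    pts = shapely.points([(d.x, d.y) for d in detections])
    dist = shapely.distance(boundary, pts)
    return [d for d, dd in zip(detections, dist) if dd <= band_m]


def ros_samples(line_points: list[Detection], prev_perimeter: BaseGeometry,
                dt_days: float, day_index: int = 0) -> list[SpreadSample]:
    """Spread samples for one day's fire-line points.

    The distance is 0 for points inside the previous perimeter (fire detected
    but the line did not advance), otherwise the Euclidean distance to its
    boundary; ROS = (distance in km) / (elapsed days). Gaps in detection
    coverage lengthen ``dt_days`` rather than dropping days, so distance
    accrued over two days is divided by two days.
    """
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    if not line_points:
        return []
    pts = shapely.points([(d.x, d.y) for d in line_points])
    dist = shapely.distance(prev_perimeter, pts)  # 0 inside the polygon
    return [SpreadSample(det_id=d.det_id, day_index=day_index,
                         dist_to_prev_m=float(dd), dt_days=float(dt_days),
                         ros=(float(dd) / 1000.0) / dt_days)
            for d, dd in zip(line_points, dist)]


def summarize_fire_day(samples: list[SpreadSample],
                       frp_points: list[Detection],
                       areas_km2: tuple[float, float],
                       fire_id: str = "", day_index: int = 0,
                       percentile: float = 95.0) -> FireDaySummary:
    """Collapse one fire-day into its summary row.

    ``areas_km2`` is (previous cumulative, today cumulative). The percentile
    uses linear interpolation between order statistics (type-7), zeros
    included. FRP averages over fire-line detections whose FRP is not
    missing; a missing FRP is excluded, an observed 0 MW is included.
    """
    prev_km2, today_km2 = areas_km2
    ros = np.array([s.ros for s in samples], dtype=float)
    if ros.size:
        ros_p95 = float(np.percentile(ros, percentile))  # type-7 interpolation
        ros_mean = float(np.mean(ros))
    else:
        ros_p95 = ros_mean = math.nan
    frp_vals = [d.frp for d in frp_points if d.frp is not None]
    mean_frp = float(np.mean(frp_vals)) if frp_vals else math.nan
    return FireDaySummary(
        fire_id=fire_id, day_index=day_index,
        ros_p95=ros_p95, ros_mean=ros_mean,
        expansion_area_km2=max(today_km2 - prev_km2, 0.0),
        cumulative_area_km2=today_km2,
        mean_frp=mean_frp, n_line_detections=len(frp_points),
        n_samples=len(samples))


def fire_level_metrics(summaries: list[FireDaySummary],
                       final_area_km2: float,
                       mismatch_flag_frac: float = 0.25) -> dict:
    """Fire-level growth metrics from the day summaries of one fire.

    ``days_to_75`` is the first day_index whose cumulative area reaches 75%
    of the *tracked* final area (internally consistent with the perimeter
    series); ``area_mismatch_flag`` marks fires whose tracked final area
    disagrees with the reference final area by more than
    ``mismatch_flag_frac``. ``size_day_k`` is the cumulative area at the end
    of fire day k (k = 1..5), NaN when the fire had fewer fire days.
    """
    if not summaries:
        raise ValueError("need at least one fire-day summary")
    ss = sorted(summaries, key=lambda s: s.day_index)
    tracked_final = ss[-1].cumulative_area_km2
    days_to_75 = next(s.day_index for s in ss
                      if s.cumulative_area_km2 >= 0.75 * tracked_final)
    by_day = {s.day_index: s.cumulative_area_km2 for s in ss}
    ros_vals = [s.ros_p95 for s in ss if not math.isnan(s.ros_p95)]
    mismatch = (abs(tracked_final - final_area_km2)
                > mismatch_flag_frac * final_area_km2)
    out = {
        "fire_id": ss[0].fire_id,
        "n_fire_days": len(ss),
        "tracked_final_area_km2": tracked_final,
        "reference_final_area_km2": final_area_km2,
        "area_mismatch_flag": bool(mismatch),
        "days_to_75": days_to_75,
        "max_ros_p95": max(ros_vals) if ros_vals else math.nan,
        "mean_ros_p95": float(np.mean(ros_vals)) if ros_vals else math.nan,
    }
    for k in range(1, 6):
        out[f"size_day_{k}"] = by_day.get(k, math.nan)
    return out


def fire_level_table(summaries_by_fire: dict[str, list[FireDaySummary]],
                     final_areas_km2: dict[str, float]) -> pd.DataFrame:
    """``fire_level_metrics`` applied across fires, as a DataFrame."""
    rows = [fire_level_metrics(ss, final_areas_km2[fid])
            for fid, ss in summaries_by_fire.items() if ss]
    return pd.DataFrame(rows)
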