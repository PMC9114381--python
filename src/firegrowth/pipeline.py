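"""End-to-end fire tracking: detections -> daily perimeters -> ROS summaries.

Glue around :mod:`preprocess`, :mod:`perimeter` and :mod:`spread`: for each
selected fire, extract its detections, group them into fire days, maintain
the sub-fire partition day by day, advance each sub-fire's cumulative alpha
hull, and score rate-of-spread for the fire-line detections against the
previous day's perimeter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from shapely.ops import unary_union

from .config import Config
from .io_formats import Detection, FireRecord
from .perimeter import DailyPerimeter, advance_perimeter
from .preprocess import (SubFire, cluster_subfires, extract_detections,
                         group_timesteps, select_fires)
from .spread import (FireDaySummary, SpreadSample, fire_line_points,
                     ros_samples, summarize_fire_day)

log = logging.getLogger(__name__)


@dataclass
class TrackedFire:
    """Everything the tracker reconstructs for one fire."""

    fire: FireRecord
    subfires: list[SubFire] = field(default_factory=list)
    perimeters: list[DailyPerimeter] = field(default_factory=list)
    summaries: list[FireDaySummary] = field(default_factory=list)
    samples: list[SpreadSample] = field(default_factory=list)

    @property
    def fire_id(self) -> str:
        return self.fire.fire_id


def track_fire(fire: FireRecord, all_detections: list[Detection],
               cfg: Config | None = None) -> TrackedFire | None:
    """Track one fire. Returns None (with a log entry) when no detections
    fall inside the fire's spatio-temporal window."""
    cfg = cfg or Config()
    dets = extract_detections(fire, all_detections, cfg.buffer_m,
                              cfg.day_pad_days, cfg.fallback_window_months)
    if not dets:
        log.info("fire %s: skipped (no detections in window)", fire.fire_id)
        return None
    groups = group_timesteps(dets, fire.fire_id, cfg.day_start_hour,
                             cfg.dedup_tol_deg)
    tracked = TrackedFire(fire=fire)
    subfires: list[SubFire] = []
    last_end: dict[str, datetime] = {}   # per-subfire time of last timestep
    prev_fire_area = 0.0

    for group in groups:
        subfires = cluster_subfires(group, subfires, cfg.link_dist_m)
        day_samples: list[SpreadSample] = []
        day_line_pts: list[Detection] = []
        for sf in subfires:
            if not sf.active or group.day_index not in sf.detections_by_day:
                continue
            prev_poly = sf.last_perimeter
            poly, alpha = advance_perimeter(
                sf.all_points(), prev_poly, cfg.alpha0_km, cfg.alpha_step_km,
                cfg.alpha_max_km, cfg.footprint_m)
            sf.last_perimeter = poly
            tracked.perimeters.append(DailyPerimeter(
                fire_id=fire.fire_id, subfire_id=sf.subfire_id,
                day_index=group.day_index, polygon=poly, alpha_used=alpha))
            todays = sf.detections_by_day[group.day_index]
            line_pts = fire_line_points(todays, poly, cfg.line_band_m)
            day_line_pts.extend(line_pts)
            if prev_poly is not None:
                dt = (group.timestep_end
                      - last_end[sf.subfire_id]).total_seconds() / 86400.0
                if dt <= 0:
                    log.warning("fire %s subfire %s day %d: non-positive dt, "
                                "skipping ROS", fire.fire_id, sf.subfire_id,
                                group.day_index)
                else:
                    day_samples.extend(ros_samples(
                        line_pts, prev_poly, dt, group.day_index))
            last_end[sf.subfire_id] = group.timestep_end

        fire_area = unary_union(
            [sf.last_perimeter for sf in subfires
             if sf.active and sf.last_perimeter is not None]).area / 1e6
        tracked.summaries.append(summarize_fire_day(
            day_samples, day_line_pts, (prev_fire_area, fire_area),
            fire.fire_id, group.day_index, cfg.ros_percentile))
        tracked.samples.extend(day_samples)
        prev_fire_area = fire_area
    tracked.subfires = subfires
    log.info("fire %s: %d fire days, %.1f km2 tracked", fire.fire_id,
             len(tracked.summaries), prev_fire_area)
    return tracked


def track_all(fires: list[FireRecord], all_detections: list[Detection],
              cfg: Config | None = None,
              apply_selection: bool = True) -> list[TrackedFire]:
    """Track every (selected) fire; fires without detections are skipped."""
    cfg = cfg or Config()
    if apply_selection:
        fires = select_fires(fires, cfg.min_area_ha, cfg.min_days)
    out = []
    for fire in fires:
        tf = track_fire(fire, all_detections, cfg)
        if tf is not None:
            out.append(tf)
    return out
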