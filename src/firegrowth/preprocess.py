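"""Fire selection, detection extraction, daily grouping and sub-fire clustering.

A "fire day" pairs the afternoon overpass (~13:30 local) with the following
night overpass (~01:30 local the next calendar day), so the day boundary sits
at 06:00 local time. Multi-ignition fires are split into sub-fires whenever
point groups are more than 1500 m apart (single linkage) and re-merged, from
that timestep onwards, when a group bridges two previously separate sub-fires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

import shapely

from .io_formats import Detection, FireRecord

log = logging.getLogger(__name__)


@dataclass
class TimestepGroup:
    """All detections of one fire day (day_index 1 = first day with data)."""

    fire_id: str
    day_index: int
    fire_day: date            # local calendar day the group belongs to
    timestep_end: datetime    # time of the last overpass in the group
    detections: list[Detection]

    def __post_init__(self):
        if not self.detections:
            raise ValueError("a TimestepGroup must hold at least one detection")


@dataclass
class SubFire:
    """A connected group of detections tracked as its own fire front.

    After being absorbed in a merge the sub-fire is inactive and emits no
    further timesteps; its detections live on in the absorbing sub-fire.
    """

    subfire_id: str
    fire_id: str
    detections_by_day: dict[int, list[Detection]] = field(default_factory=dict)
    merge_history: list[tuple[int, str]] = field(default_factory=list)
    active: bool = True
    last_perimeter: BaseGeometry | None = None  # maintained by the tracker

    def all_points(self) -> np.ndarray:
        pts = [(d.x, d.y) for dets in self.detections_by_day.values()
               for d in dets]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Fire selection and detection extraction
# ---------------------------------------------------------------------------

def select_fires(fires: list[FireRecord], min_area_ha: float = 300.0,
                 min_days: int = 2) -> list[FireRecord]:
    """Retain large multiday fires: area strictly above ``min_area_ha`` and
    an alarm-to-containment duration of at least ``min_days`` (fires with
    missing dates are retained; their duration is resolved later through the
    fallback extraction window). Input ordering is preserved."""
    out = []
    for f in fires:
        if f.final_area_km2 * 100.0 <= min_area_ha:
            continue
        if f.alarm_date is not None and f.containment_date is not None:
            if (f.containment_date - f.alarm_date).days < min_days:
                continue
        out.append(f)
    return out


def extract_detections(fire: FireRecord, all_detections: list[Detection],
                       buffer_m: float = 750.0, day_pad: int = 1,
                       fallback_window_months: int = 3) -> list[Detection]:
    """Detections belonging to one fire.

    Spatial rule: the point lies within the final perimeter dilated by
    ``buffer_m``. Temporal rule: the acquisition date lies in
    [alarm - day_pad, containment + day_pad]; if either date is missing the
    window is [date of the first in-buffer detection, +``fallback_window_months``
    months].
    """
    if not all_detections:
        return []
    buffered = fire.final_perimeter.buffer(buffer_m)
    xs = np.array([d.x for d in all_detections])
    ys = np.array([d.y for d in all_detections])
    inside = shapely.contains_xy(buffered, xs, ys)
    candidates = [d for d, ok in zip(all_detections, inside) if ok]
    if not candidates:
        log.info("fire %s: no detections within %.0f m buffer",
                 fire.fire_id, buffer_m)
        return []
    candidates.sort(key=lambda d: d.acq_time)
    if fire.alarm_date is not None and fire.containment_date is not None:
        lo = fire.alarm_date - timedelta(days=day_pad)
        hi = fire.containment_date + timedelta(days=day_pad)
    else:
        t0 = candidates[0].acq_time.date()
        lo = t0
        hi = (pd.Timestamp(t0) + pd.DateOffset(months=fallback_window_months)).date()
    kept = [d for d in candidates if lo <= d.acq_time.date() <= hi]
    if not kept:
        log.info("fire %s: no detections inside the temporal window", fire.fire_id)
    return kept


# ---------------------------------------------------------------------------
# Daily timestep grouping
# ---------------------------------------------------------------------------

def _fire_day(t: datetime, day_start_hour: int) -> date:
    return (t - timedelta(hours=day_start_hour)).date()


def group_timesteps(detections: list[Detection], fire_id: str = "",
                    day_start_hour: int = 6,
                    dedup_tol_deg: float = 1e-5) -> list[TimestepGroup]:
    """Group detections into fire days.

    A detection seen in two overlapping swaths in the same fire day
    (identical coordinates within ``dedup_tol_deg``) is kept once, at the
    later overpass time. The group's ``timestep_end`` is the time of the last
    contributing overpass. Days with no detections produce no group; the time
    gap shows up downstream as a longer interval between ``timestep_end``
    values. Output is independent of input row order.
    """
    if not detections:
        return []
    by_day: dict[date, dict[tuple[int, int], Detection]] = {}
    for d in sorted(detections, key=lambda d: (d.acq_time, d.det_id)):
        day = _fire_day(d.acq_time, day_start_hour)
        key = (round(d.lat / dedup_tol_deg), round(d.lon / dedup_tol_deg))
        slot = by_day.setdefault(day, {})
        prev = slot.get(key)
        if prev is None or d.acq_time >= prev.acq_time:
            slot[key] = d  # later overpass wins
    groups = []
    for i, day in enumerate(sorted(by_day), start=1):
        dets = sorted(by_day[day].values(), key=lambda d: (d.acq_time, d.det_id))
        groups.append(TimestepGroup(
            fire_id=fire_id, day_index=i, fire_day=day,
            timestep_end=max(d.acq_time for d in dets), detections=dets))
    return groups


# ---------------------------------------------------------------------------
# Sub-fire clustering (single linkage, 1500 m)
# ---------------------------------------------------------------------------

def _connected_components(xy: np.ndarray, link_dist_m: float) -> np.ndarray:
    """Single-linkage components: labels of the graph joining pairs within
    ``link_dist_m`` (Euclidean, projected metres)."""
    n = len(xy)
    if n == 1:
        return np.zeros(1, dtype=int)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=link_dist_m, output_type="ndarray")
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def cluster_subfires(group: TimestepGroup, prior: list[SubFire],
                     link_dist_m: float = 1500.0) -> list[SubFire]:
    """Assign one timestep's detections to sub-fires and handle merges.

    Detections are partitioned into single-linkage components at
    ``link_dist_m``. Each component is attached to every active prior
    sub-fire within ``link_dist_m`` of its latest perimeter (or points, before
    a perimeter exists); a component touching two or more priors merges them
    — the absorbed sub-fires go inactive and their detection history moves to
    the survivor, so subsequent perimeters are drawn around all of them
    together. Components touching no prior start new sub-fires. Returns the
    updated sub-fire list (priors plus any new ones).
    """
    dets = group.detections
    xy = np.array([(d.x, d.y) for d in dets], dtype=float).reshape(-1, 2)
    labels = _connected_components(xy, link_dist_m)
    subfires = list(prior)
    next_id = len(subfires)

    for comp in range(labels.max() + 1):
        idx = np.nonzero(labels == comp)[0]
        comp_pts = shapely.points(xy[idx])
        touched = []
        for sf in subfires:
            if not sf.active:
                continue
            if sf.last_perimeter is not None:
                target = sf.last_perimeter
            else:
                pts = sf.all_points()
                if not len(pts):
                    continue
                target = shapely.multipoints(pts)
            if float(np.min(shapely.distance(target, comp_pts))) <= link_dist_m:
                touched.append(sf)
        if not touched:
            sf = SubFire(subfire_id=f"{group.fire_id}/s{next_id}",
                         fire_id=group.fire_id)
            next_id += 1
            subfires.append(sf)
            host = sf
        else:
            host = touched[0]
            for other in touched[1:]:
                # merge: host absorbs the other's history and perimeter
                log.info("fire %s day %d: subfire %s absorbs %s",
                         group.fire_id, group.day_index, host.subfire_id,
                         other.subfire_id)
                for day, ds in other.detections_by_day.items():
                    host.detections_by_day.setdefault(day, []).extend(ds)
                if other.last_perimeter is not None:
                    host.last_perimeter = (
                        other.last_perimeter if host.last_perimeter is None
                        else host.last_perimeter.union(other.last_perimeter))
                host.merge_history.append((group.day_index, other.subfire_id))
                other.active = False
        host.detections_by_day.setdefault(group.day_index, []).extend(
            dets[i] for i in idx)
    return subfires
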