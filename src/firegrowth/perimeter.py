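"""Alpha-hull perimeter construction.

The end-of-day fire perimeter is the alpha-shape of all detections observed
so far: the union of Delaunay triangles whose circumradius does not exceed
alpha (expressed in kilometres; larger alpha admits larger triangles and the
shape tends to the convex hull). Starting from a small alpha, the value is
escalated in fixed steps until the shape is a single connected polygon
embedding every point — the adaptive schedule that keeps complex fire shapes
from fragmenting into disconnected pieces. Perimeters are forced to be
monotonically non-shrinking by unioning each day's hull with the previous
day's polygon, and interior holes are filled (unburned islands cannot be
resolved from point detections).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Point, Polygon, MultiPoint, LineString
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .preprocess import SubFire

log = logging.getLogger(__name__)

#: alpha_used value recorded when escalation hit alpha_max and the convex
#: hull was used instead
CONVEX_FALLBACK_ALPHA = -1.0

#: tolerance (m) for the "polygon embeds every point" check
CONTAINMENT_TOL_M = 1.0


class DegenerateInput(ValueError):
    """Fewer than 3 points, or all points collinear."""


@dataclass
class DailyPerimeter:
    """Reconstructed end-of-day perimeter of one sub-fire."""

    fire_id: str
    subfire_id: str
    day_index: int
    polygon: BaseGeometry        # projected metres, holes filled
    alpha_used: float            # km; CONVEX_FALLBACK_ALPHA for the fallback

    @property
    def cumulative_area_km2(self) -> float:
        return self.polygon.area / 1e6


# ---------------------------------------------------------------------------
# Alpha shape
# ---------------------------------------------------------------------------

def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each triangle: R = abc / (4 * area)."""
    p = pts[simplices]  # (m, 3, 2)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _fill_holes(geom: BaseGeometry) -> BaseGeometry:
    if geom.geom_type == "Polygon":
        return Polygon(geom.exterior)
    if geom.geom_type == "MultiPolygon":
        return unary_union([Polygon(g.exterior) for g in geom.geoms])
    return geom


def _embeds_all(poly: BaseGeometry, pts: np.ndarray,
                tol: float = CONTAINMENT_TOL_M) -> bool:
    return bool(np.all(shapely.dwithin(poly, shapely.points(pts), tol)))


class _Triangulation:
    """Delaunay triangulation with cached circumradii, reused across the
    alpha-escalation loop so the triangulation is computed once."""

    def __init__(self, pts: np.ndarray):
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 3:
            raise DegenerateInput("need at least 3 points")
        try:
            self.tri = Delaunay(pts)
        except QhullError as exc:  # collinear input
            raise DegenerateInput(str(exc)) from exc
        if self.tri.simplices.size == 0:
            raise DegenerateInput("degenerate (collinear) point set")
        self.pts = pts
        self.radii = _circumradii(pts, self.tri.simplices)

    def shape_at(self, alpha_km: float):
        """Alpha shape at the given alpha, or None if it is empty, leaves a
        point uncovered, is disconnected, or fails the embedding check."""
        keep = self.radii <= alpha_km * 1000.0
        if not keep.any():
            return None
        simp = self.tri.simplices[keep]
        # cheap necessary checks before paying for the polygon union:
        # every point must be a vertex of a kept triangle, and the kept
        # triangles must form one edge-connected component
        if len(np.unique(simp)) < len(self.pts):
            return None
        if not _edge_connected(simp):
            return None
        polys = shapely.polygons(self.pts[simp])
        geom = _fill_holes(unary_union(polys))
        if geom.geom_type != "Polygon" or geom.is_empty:
            return None
        if not _embeds_all(geom, self.pts):
            return None
        return geom


def _edge_connected(simplices: np.ndarray) -> bool:
    """True if the triangle set is connected through shared edges."""
    m = len(simplices)
    if m <= 1:
        return True
    edge_owner: dict[tuple[int, int], int] = {}
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t, (i, j, k) in enumerate(simplices):
        for e in ((i, j), (j, k), (k, i)):
            e = (min(e), max(e))
            o = edge_owner.get(e)
            if o is None:
                edge_owner[e] = t
            else:
                ra, rb = find(o), find(t)
                if ra != rb:
                    parent[rb] = ra
    return len({find(t) for t in range(m)}) == 1


def alpha_hull(points: np.ndarray, alpha_km: float) -> BaseGeometry | None:
    """Alpha-shape polygon of a 2-D point set (coordinates in metres,
    ``alpha_km`` in kilometres).

    Returns ``None`` (failure) when the result is empty, disconnected, or
    does not embed every point; raises :class:`DegenerateInput` for fewer
    than 3 points or a collinear set, so the caller can apply its fallback.
    """
    return _Triangulation(np.asarray(points, dtype=float)).shape_at(alpha_km)


def _tiny_set_fallback(pts: np.ndarray, footprint_m: float) -> BaseGeometry:
    """Perimeter for 1-2 points or a collinear set: the points (joined as a
    line when more than one) dilated by half the sensor footprint."""
    r = footprint_m / 2.0
    if len(pts) == 1:
        return Point(pts[0]).buffer(r, quad_segs=64)
    if len(pts) == 2:
        return LineString(pts).buffer(r, quad_segs=64)
    hull = MultiPoint(pts).convex_hull  # LineString for collinear input
    return hull.buffer(r, quad_segs=64)


def adaptive_perimeter(points: np.ndarray, alpha0_km: float = 0.05,
                       step_km: float = 0.05, alpha_max_km: float = 50.0,
                       footprint_m: float = 375.0,
                       ) -> tuple[BaseGeometry, float]:
    """Alpha hull with the adaptive alpha schedule.

    Tries alpha0, alpha0+step, ... until the alpha shape is a single
    connected polygon embedding all points, and returns (polygon, alpha).
    If ``alpha_max_km`` is reached without success the convex hull is
    returned with ``alpha_used = CONVEX_FALLBACK_ALPHA``. Point sets that
    admit no triangulation (1-2 points, collinear) fall back to
    half-footprint dilation, reported at ``alpha0_km``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points")
    pts = np.unique(pts, axis=0)
    try:
        tri = _Triangulation(pts)
    except DegenerateInput:
        return _tiny_set_fallback(pts, footprint_m), alpha0_km

    alpha = alpha0_km
    n_tried = 0
    prev_kept = -1
    while alpha <= alpha_max_km + 1e-12:
        kept = int(np.sum(tri.radii <= alpha * 1000.0))
        if kept != prev_kept:  # skip alphas that change nothing
            prev_kept = kept
            geom = tri.shape_at(alpha)
            if geom is not None:
                if n_tried:
                    log.debug("alpha escalated %d steps to %.2f", n_tried, alpha)
                return geom, round(alpha, 10)
        n_tried += 1
        alpha = alpha0_km + n_tried * step_km
    log.warning("alpha escalation exhausted at %.2f km; using convex hull",
                alpha_max_km)
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        hull = hull.buffer(footprint_m / 2.0)
    return hull, CONVEX_FALLBACK_ALPHA


# ---------------------------------------------------------------------------
# Daily perimeter series
# ---------------------------------------------------------------------------

def advance_perimeter(cum_points: np.ndarray, prev: BaseGeometry | None,
                      alpha0_km: float = 0.05, step_km: float = 0.05,
                      alpha_max_km: float = 50.0, footprint_m: float = 375.0,
                      ) -> tuple[BaseGeometry, float]:
    """One day's perimeter: adaptive hull of the cumulative point set,
    unioned with the previous perimeter so the series never shrinks."""
    hull, alpha = adaptive_perimeter(cum_points, alpha0_km, step_km,
                                     alpha_max_km, footprint_m)
    if prev is not None:
        hull = _fill_holes(hull.union(prev))
    return hull, alpha


def build_daily_perimeters(subfire: SubFire, alpha0_km: float = 0.05,
                           step_km: float = 0.05, alpha_max_km: float = 50.0,
                           footprint_m: float = 375.0) -> list[DailyPerimeter]:
    """End-of-day perimeters for every timestep of a sub-fire.

    Each day's polygon is the adaptive alpha hull over all detections
    observed up to and including that day, unioned with the previous day's
    polygon: areas are monotonically non-decreasing and every detection to
    date lies inside its day's polygon.
    """
    if not subfire.detections_by_day:
        raise ValueError("sub-fire has no timesteps")
    out: list[DailyPerimeter] = []
    cum: list[tuple[float, float]] = []
    prev: BaseGeometry | None = None
    for day in sorted(subfire.detections_by_day):
        cum.extend((d.x, d.y) for d in subfire.detections_by_day[day])
        poly, alpha = advance_perimeter(np.asarray(cum), prev, alpha0_km,
                                        step_km, alpha_max_km, footprint_m)
        prev = poly
        out.append(DailyPerimeter(
            fire_id=subfire.fire_id, subfire_id=subfire.subfire_id,
            day_index=day, polygon=poly, alpha_used=alpha))
    return out
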