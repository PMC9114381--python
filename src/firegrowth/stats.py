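"""Analysis layer over the fire-day summaries.

Implements the burned-area-normalized mean spread rate

    ros_ba = sum_i BA_i * RoS_i / sum_i BA_i,

Welch two-sample t tests (with optional log transform for heavy-tailed
variables) and two-sample Kolmogorov-Smirnov tests between ignition-cause
groups, ROS frequency distributions weighted by fire-days or burned area,
the burned-area share of the fastest decile of fire days, zonal severity
sampling of 30 m rasters over daily expansion polygons, and ordinary
least-squares relationships between spread rate and severity/FRP with a
running mean for presentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry.base import BaseGeometry

from .io_formats import SeverityRaster
from .spread import FireDaySummary

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Burned-area-normalized spread
# ---------------------------------------------------------------------------

def ba_weighted_mean_ros(ba_km2, ros) -> float:
    """Burned-area weighted mean spread rate (km/day).

    Weights each fire day's spread rate by that day's burned area, so slow
    days that contribute little area no longer dominate the mean.
    """
    ba = np.asarray(ba_km2, dtype=float)
    r = np.asarray(ros, dtype=float)
    if ba.shape != r.shape:
        raise ValueError("burned-area and ROS vectors must align")
    if np.any(ba < 0):
        raise ValueError("burned areas must be non-negative")
    total = ba.sum()
    if total == 0:
        raise ValueError("no burned area: weighted mean undefined")
    return float(np.sum(ba * r) / total)


# ---------------------------------------------------------------------------
# Two-group comparison (Welch t + KS)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]          # on the original scale
    iqr: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float
    ks_statistic: float
    ks_p: float
    log_transformed: bool
    log_epsilon: float | None = None   # offset used for zeros, if any


def compare_groups(x, y, labels: tuple[str, str] = ("x", "y"),
                   variable: str = "", log_transform: bool = False,
                   ) -> GroupComparison:
    """Welch two-sample t test and two-sample KS test between two samples.

    With ``log_transform`` the t test runs on log(v + eps) where eps is half
    the smallest positive value across both samples (0 when no zeros are
    present); the offset is recorded in the result. The KS statistic is
    invariant under this monotone transform and is computed on the raw data.
    Reported means and IQRs stay on the original scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    eps = None
    tx, ty = x, y
    if log_transform:
        both = np.concatenate([x, y])
        if np.any(both < 0):
            raise ValueError("log transform requires non-negative data")
        pos = both[both > 0]
        eps = 0.0 if (both > 0).all() else float(pos.min() / 2.0)
        tx, ty = np.log(x + eps), np.log(y + eps)
    if np.var(tx) == 0 and np.var(ty) == 0:
        raise ValueError("zero variance in both groups: t undefined")
    tres = sps.ttest_ind(tx, ty, equal_var=False)
    ks = sps.ks_2samp(x, y, method="asymp")
    return GroupComparison(
        variable=variable, labels=labels, n=(len(x), len(y)),
        mean=(float(np.mean(x)), float(np.mean(y))),
        iqr=(float(sps.iqr(x)), float(sps.iqr(y))),
        t_statistic=float(tres.statistic), df=float(tres.df),
        p_value=float(tres.pvalue),
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        log_transformed=log_transform, log_epsilon=eps)


# ---------------------------------------------------------------------------
# ROS frequency distributions and concentration
# ---------------------------------------------------------------------------

def ros_distribution(days: list[FireDaySummary], by: str = "fire_day",
                     bins=None) -> pd.DataFrame:
    """Percentage of fire days (``by="fire_day"``) or of burned area
    (``by="burned_area"``) falling in each daily-ROS bin. Percentages sum to
    100 over days with a defined ROS; an empty input yields an empty table."""
    if by not in ("fire_day", "burned_area"):
        raise ValueError("by must be 'fire_day' or 'burned_area'")
    rows = [(s.ros_p95, s.expansion_area_km2) for s in days
            if not math.isnan(s.ros_p95)]
    if not rows:
        return pd.DataFrame(columns=["bin_left", "bin_right", "percent"])
    ros = np.array([r for r, _ in rows])
    if bins is None:
        bins = np.arange(0.0, ros.max() + 0.5, 0.5)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    weights = (np.ones_like(ros) if by == "fire_day"
               else np.array([a for _, a in rows]))
    hist, edges = np.histogram(ros, bins=bins, weights=weights)
    total = weights.sum()
    pct = 100.0 * hist / total if total > 0 else hist * 0.0
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "percent": pct})


def top_decile_ba_share(days: list[FireDaySummary]) -> float:
    """Share (%) of total expansion area contributed by the fastest 10% of
    fire days ranked by daily ROS. Days tied with the cutoff ROS are all
    included, so the share can exceed the nominal decile."""
    rows = [(s.ros_p95, s.expansion_area_km2) for s in days
            if not math.isnan(s.ros_p95)]
    if len(rows) < 10:
        raise ValueError("need at least 10 fire days with a defined ROS")
    ros = np.array([r for r, _ in rows])
    area = np.array([a for _, a in rows])
    k = max(1, int(math.ceil(0.1 * len(ros))))
    cutoff = np.sort(ros)[-k]
    sel = ros >= cutoff
    total = area.sum()
    if total == 0:
        raise ValueError("no burned area")
    return float(100.0 * area[sel].sum() / total)


# ---------------------------------------------------------------------------
# Zonal severity sampling
# ---------------------------------------------------------------------------

@dataclass
class SeveritySummary:
    fire_id: str
    day_index: int
    metric: str
    mean: float
    p95: float
    n_pixels: int


def sample_severity(raster: SeverityRaster, expansion_polygon: BaseGeometry,
                    fire_id: str = "", day_index: int = 0,
                    ) -> SeveritySummary | None:
    """Mean and 95th percentile of the severity pixels whose centers fall
    inside one day's expansion polygon (pixel-center zonal rule, nodata
    excluded). Returns None, with a log entry, when no valid pixel falls
    inside."""
    xs, ys = raster.pixel_centers()
    minx, miny, maxx, maxy = expansion_polygon.bounds
    ci = np.nonzero((xs >= minx - raster.cellsize) & (xs <= maxx + raster.cellsize))[0]
    ri = np.nonzero((ys >= miny - raster.cellsize) & (ys <= maxy + raster.cellsize))[0]
    if ci.size == 0 or ri.size == 0:
        log.info("fire %s day %d: expansion outside raster extent",
                 fire_id, day_index)
        return None
    cx, ry = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(expansion_polygon, cx.ravel(), ry.ravel())
    vals = raster.values[np.ix_(ri, ci)].ravel()[inside]
    vals = vals[vals != raster.nodata]
    if vals.size == 0:
        log.info("fire %s day %d: no valid severity pixels", fire_id, day_index)
        return None
    return SeveritySummary(
        fire_id=fire_id, day_index=day_index, metric=raster.metric,
        mean=float(np.mean(vals)), p95=float(np.percentile(vals, 95)),
        n_pixels=int(vals.size))


def severity_pixels(raster: SeverityRaster,
                    polygon: BaseGeometry) -> np.ndarray:
    """Raw valid pixel values under a polygon (pixel-center rule)."""
    xs, ys = raster.pixel_centers()
    cx, ry = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, cx.ravel(), ry.ravel())
    vals = raster.values.ravel()[inside]
    return vals[vals != raster.nodata]


# ---------------------------------------------------------------------------
# Severity / FRP vs ROS relationships
# ---------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    running_mean: pd.DataFrame   # columns: ros, response (ROS-sorted)


def severity_vs_ros(ros, response, running_min_window: int = 51,
                    running_frac: float = 0.05) -> RegressionSummary:
    """OLS of a response (daily severity or FRP) on daily ROS.

    Reports slope, intercept, R^2, the regression F statistic and its p
    value, plus a centered running mean of the response over ROS-sorted
    points (window = max(``running_min_window``, ``running_frac`` * n),
    presentational only).
    """
    x = np.asarray(ros, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 aligned (ros, response) pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor: constant ROS")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    n = len(x)
    # F = t^2 for a single predictor; an exact fit has stderr 0 -> inf
    f_stat = (res.slope / res.stderr) ** 2 if res.stderr > 0 else math.inf
    order = np.argsort(x, kind="stable")
    win = max(running_min_window, int(round(running_frac * n)))
    win = min(win, n)
    rm = (pd.Series(y[order]).rolling(win, center=True, min_periods=1).mean())
    running = pd.DataFrame({"ros": x[order], "response_mean": rm.to_numpy()})
    return RegressionSummary(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), f_statistic=float(f_stat),
        p_value=float(res.pvalue), n=n, running_mean=running)


# ---------------------------------------------------------------------------
# Fire-level severity
# ---------------------------------------------------------------------------

def fire_level_severity(daily: list[SeveritySummary], mode: str = "mean",
                        raster: SeverityRaster | None = None,
                        burned_polygon: BaseGeometry | None = None) -> float:
    """Fire-level severity from daily summaries.

    ``mode="mean"``: pixel-count-weighted mean of the daily means (exactly
    the mean over all sampled pixels). ``mode="maximum"``: the 95th
    percentile over the fire's full pixel distribution, which requires pixel
    access — pass the raster and the fire's burned polygon; daily summaries
    alone cannot recover a percentile of the pooled distribution.
    """
    if mode == "mean":
        if not daily:
            raise ValueError("no daily severity summaries")
        n = np.array([d.n_pixels for d in daily], dtype=float)
        m = np.array([d.mean for d in daily])
        return float(np.sum(n * m) / np.sum(n))
    if mode == "maximum":
        if raster is None or burned_polygon is None:
            raise ValueError("maximum mode needs raster + burned polygon "
                             "to access the pixel distribution")
        vals = severity_pixels(raster, burned_polygon)
        if vals.size == 0:
            raise ValueError("no valid pixels under the burned polygon")
        return float(np.percentile(vals, 95))
    raise ValueError("mode must be 'mean' or 'maximum'")
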