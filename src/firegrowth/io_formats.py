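"""External formats and the projected-coordinate contract.

Every geometric operation in the pipeline works in metres in a single
projected, equal-area CRS. This module owns that contract: the
:class:`AlbersEqualArea` projection (an ellipsoidal Albers conic with
California-Albers defaults), the domain record types
(:class:`Detection`, :class:`FireRecord`, :class:`SeverityRaster`), and the
readers/writers for the active-fire CSV dialect, GeoJSON fire perimeters,
GeoJSON daily-perimeter output, CSV summary tables and ASCII-grid severity
rasters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .config import (
    Config,
    DEFAULT_CAUSE_MAP,
    DEFAULT_DETECTION_COLUMNS,
    DEFAULT_PERIMETER_ATTRS,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

# GRS80 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257222101
_E2 = 2 * _F - _F * _F
_E = math.sqrt(_E2)


def _q(sin_phi: np.ndarray) -> np.ndarray:
    """Authalic-latitude helper q(phi) of the ellipsoidal Albers projection."""
    es = _E * sin_phi
    return (1 - _E2) * (
        sin_phi / (1 - _E2 * sin_phi**2) - (1 / (2 * _E)) * np.log((1 - es) / (1 + es))
    )


def _m(phi: float) -> float:
    return math.cos(phi) / math.sqrt(1 - _E2 * math.sin(phi) ** 2)


class AlbersEqualArea:
    """Ellipsoidal Albers equal-area conic projection (GRS80).

    Defaults reproduce a California Albers parameterisation (standard
    parallels 34 and 40.5 N, origin 120 W / 0 N, false northing -4000 km).
    Forward maps (lon, lat) degrees to (x, y) metres; inverse inverts it to
    better than 1e-8 degrees.
    """

    def __init__(self, lat0: float = 0.0, lon0: float = -120.0,
                 lat1: float = 34.0, lat2: float = 40.5,
                 false_easting: float = 0.0,
                 false_northing: float = -4_000_000.0):
        self.lat0, self.lon0 = lat0, lon0
        self.lat1, self.lat2 = lat1, lat2
        self.fe, self.fn = false_easting, false_northing
        p1, p2 = math.radians(lat1), math.radians(lat2)
        m1, m2 = _m(p1), _m(p2)
        q1 = float(_q(np.sin(p1)))
        q2 = float(_q(np.sin(p2)))
        if abs(lat1 - lat2) < 1e-12:
            self.n = math.sin(p1)
        else:
            self.n = (m1 * m1 - m2 * m2) / (q2 - q1)
        self.C = m1 * m1 + self.n * q1
        q0 = float(_q(math.sin(math.radians(lat0))))
        self.rho0 = _A * math.sqrt(self.C - self.n * q0) / self.n

    @classmethod
    def from_config(cls, cfg: Config) -> "AlbersEqualArea":
        return cls(cfg.proj_lat0, cfg.proj_lon0, cfg.proj_lat1, cfg.proj_lat2,
                   cfg.proj_false_easting, cfg.proj_false_northing)

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres. Accepts scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        phi = np.radians(lat)
        q = _q(np.sin(phi))
        rho = _A * np.sqrt(self.C - self.n * q) / self.n
        theta = self.n * np.radians(lon - self.lon0)
        x = self.fe + rho * np.sin(theta)
        y = self.fn + self.rho0 - rho * np.cos(theta)
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees. Accepts scalars or arrays."""
        x = np.asarray(x, dtype=float) - self.fe
        y = np.asarray(y, dtype=float) - self.fn
        dy = self.rho0 - y
        rho = np.hypot(x, dy)
        if self.n < 0:
            rho = -rho
            theta = np.arctan2(-x, -dy)
        else:
            theta = np.arctan2(x, dy)
        q = (self.C - (rho * self.n / _A) ** 2) / self.n
        # iterate for latitude (Snyder's fixed-point scheme)
        phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
        for _ in range(15):
            sp = np.sin(phi)
            es = _E * sp
            denom = 1 - _E2 * sp * sp
            corr = (denom**2 / (2 * np.cos(phi))) * (
                q / (1 - _E2) - sp / denom + (1 / (2 * _E)) * np.log((1 - es) / (1 + es))
            )
            phi = phi + corr
        lon = self.lon0 + np.degrees(theta / self.n)
        lat = np.degrees(phi)
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """Project a lon/lat geometry into working metres."""
        return shapely.transform(geom, lambda c: np.column_stack(
            self.forward(c[:, 0], c[:, 1])))

    def unproject_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """Inverse-project a working-metres geometry back to lon/lat."""
        return shapely.transform(geom, lambda c: np.column_stack(
            self.inverse(c[:, 0], c[:, 1])))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Detection:
    """One satellite active-fire point observation.

    ``frp`` is fire radiative power in MW; ``None`` means the value is
    missing, which is distinct from an observed 0. ``x, y`` are metres in the
    working projection, a deterministic function of ``lon, lat``.
    """

    det_id: str
    lon: float
    lat: float
    x: float
    y: float
    acq_time: datetime
    frp: float | None
    daynight: str              # "day" or "night"
    overpass_id: str | None = None


@dataclass
class FireRecord:
    """One fire event from a final-perimeter database."""

    fire_id: str
    cause: str                                 # "human" | "lightning" | "unknown"
    final_perimeter: BaseGeometry              # projected metres
    alarm_date: date | None
    containment_date: date | None
    final_area_km2: float

    def __post_init__(self):
        if self.cause not in ("human", "lightning", "unknown"):
            raise ValueError(f"invalid cause {self.cause!r}")


@dataclass
class SeverityRaster:
    """Single-band severity grid (dNBR, rdNBR or percent tree mortality).

    ``values[0, 0]`` is the north-west pixel; ``xll, yll`` are the lower-left
    corner in working metres and ``cellsize`` the pixel edge (30 m nominal).
    """

    metric: str                # "dNBR" | "rdNBR" | "tree_mortality_pct"
    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.metric == "tree_mortality_pct":
            valid = self.values != self.nodata
            v = self.values[valid]
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError("tree mortality values must lie in [0, 100]")

    @property
    def shape(self):
        return self.values.shape

    def pixel_centers(self):
        """(xs, ys) arrays of pixel-center coordinates, row/col order."""
        nrows, ncols = self.values.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return xs, ys


# ---------------------------------------------------------------------------
# Detections (active-fire CSV dialect)
# ---------------------------------------------------------------------------

class DetectionList(list):
    """A list of Detections carrying the count of rejected input rows."""

    n_rejected: int = 0


def _parse_acq_time(d: str, t) -> datetime:
    t = str(t).split(".")[0].zfill(4)
    return datetime.strptime(f"{d} {t[:2]}:{t[2:]}", "%Y-%m-%d %H:%M")


def read_detections(path: str | Path, projection: AlbersEqualArea,
                    columns: dict | None = None) -> DetectionList:
    """Read an active-fire detection table.

    Expected columns (renameable via ``columns``): latitude, longitude,
    acq_date (YYYY-MM-DD), acq_time (HHMM), frp, daynight, and optionally an
    overpass id. Rows whose coordinates fall outside WGS84 bounds or fail to
    parse are rejected; the rejection count is logged and exposed as
    ``result.n_rejected``. No deduplication happens at read time.
    """
    cols = dict(DEFAULT_DETECTION_COLUMNS)
    cols.update(columns or {})
    out = DetectionList()
    out.n_rejected = 0
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return out
    for key in ("latitude", "longitude", "acq_date", "acq_time", "frp", "daynight"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing mandatory column {cols[key]!r}")
    if df.empty:
        return out
    has_overpass = cols["overpass_id"] in df.columns

    for i, row in df.iterrows():
        try:
            lat = float(row[cols["latitude"]])
            lon = float(row[cols["longitude"]])
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError("out of WGS84 bounds")
            acq = _parse_acq_time(str(row[cols["acq_date"]]), row[cols["acq_time"]])
        except (ValueError, TypeError):
            out.n_rejected += 1
            continue
        frp_raw = row[cols["frp"]]
        frp = None if pd.isna(frp_raw) else float(frp_raw)
        dn = str(row[cols["daynight"]]).strip().upper()
        daynight = "day" if dn.startswith("D") else "night"
        x, y = projection.forward(lon, lat)
        out.append(Detection(
            det_id=str(i), lon=lon, lat=lat, x=x, y=y, acq_time=acq,
            frp=frp, daynight=daynight,
            overpass_id=str(row[cols["overpass_id"]]) if has_overpass else None,
        ))
    if out.n_rejected:
        log.warning("rejected %d detection rows with unparseable coordinates/times",
                    out.n_rejected)
    return out


def write_detections(dets: list[Detection], path: str | Path) -> None:
    """Write detections in the same CSV dialect ``read_detections`` accepts."""
    rows = [{
        "latitude": d.lat, "longitude": d.lon,
        "acq_date": d.acq_time.strftime("%Y-%m-%d"),
        "acq_time": d.acq_time.strftime("%H%M"),
        "frp": "" if d.frp is None else d.frp,
        "daynight": "D" if d.daynight == "day" else "N",
        "overpass_id": d.overpass_id or "",
    } for d in dets]
    pd.DataFrame(rows, columns=["latitude", "longitude", "acq_date", "acq_time",
                                "frp", "daynight", "overpass_id"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Fire perimeters (GeoJSON)
# ---------------------------------------------------------------------------

def _parse_date(v) -> date | None:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return datetime.strptime(str(v)[:10], "%Y-%m-%d").date()


def repair_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Repair an invalid polygon by zero-width buffering."""
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


def read_fire_perimeters(path: str | Path, projection: AlbersEqualArea,
                         attrs: dict | None = None,
                         cause_map: dict | None = None) -> list[FireRecord]:
    """Read final fire perimeters from a GeoJSON FeatureCollection.

    Positions are lon/lat WGS84 and are projected into working metres.
    Cause strings are mapped through ``cause_map`` (case-insensitive); an
    unmappable cause is recorded as "unknown" with a warning, never dropped.
    ``final_area_km2`` is recomputed from the projected geometry.
    """
    amap = dict(DEFAULT_PERIMETER_ATTRS)
    amap.update(attrs or {})
    cmap = {k.lower(): v for k, v in (cause_map or DEFAULT_CAUSE_MAP).items()}
    with open(path) as fh:
        fc = json.load(fh)
    records = []
    for k, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties", {})
        geom = repair_geometry(shape(feat["geometry"]))
        proj_geom = repair_geometry(projection.project_geometry(geom))
        raw_cause = str(props.get(amap["cause"], "unknown")).strip().lower()
        cause = cmap.get(raw_cause)
        if cause is None:
            log.warning("fire %s: unmappable cause %r recorded as unknown",
                        props.get(amap["fire_id"], k), raw_cause)
            cause = "unknown"
        records.append(FireRecord(
            fire_id=str(props.get(amap["fire_id"], k)),
            cause=cause,
            final_perimeter=proj_geom,
            alarm_date=_parse_date(props.get(amap["alarm_date"])),
            containment_date=_parse_date(props.get(amap["containment_date"])),
            final_area_km2=proj_geom.area / 1e6,
        ))
    return records


def write_fire_perimeters(fires: list[FireRecord], path: str | Path,
                          projection: AlbersEqualArea) -> None:
    """Write FireRecords as a WGS84 GeoJSON FeatureCollection."""
    feats = []
    for f in fires:
        geom = projection.unproject_geometry(f.final_perimeter)
        feats.append({
            "type": "Feature",
            "geometry": mapping(shapely.set_precision(geom, 1e-7)),
            "properties": {
                "fire_id": f.fire_id,
                "cause": f.cause,
                "alarm_date": f.alarm_date.isoformat() if f.alarm_date else None,
                "containment_date": (f.containment_date.isoformat()
                                     if f.containment_date else None),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Pipeline outputs (daily perimeters + fire-day summaries)
# ---------------------------------------------------------------------------

#: stable column order of the fire-day summary table
SUMMARY_COLUMNS = [
    "fire_id", "day_index", "ros_p95", "ros_mean", "expansion_area_km2",
    "cumulative_area_km2", "mean_frp", "n_line_detections",
]


def write_outputs(perimeters, summaries, outdir: str | Path,
                  projection: AlbersEqualArea) -> tuple[Path, Path]:
    """Write daily perimeters (GeoJSON, WGS84) and summaries (CSV).

    One GeoJSON feature per fire-day with properties fire_id, subfire_id,
    day_index, alpha_used, cumulative_area_km2; coordinates are rounded to
    1e-7 degrees so a write/read round trip is byte-stable. Summaries use the
    documented :data:`SUMMARY_COLUMNS` order. Empty inputs produce valid
    empty files with headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = []
    for p in perimeters:
        geom = projection.unproject_geometry(p.polygon)
        feats.append({
            "type": "Feature",
            "geometry": mapping(shapely.set_precision(geom, 1e-7)),
            "properties": {
                "fire_id": p.fire_id,
                "subfire_id": p.subfire_id,
                "day_index": int(p.day_index),
                "alpha_used": float(p.alpha_used),
                "cumulative_area_km2": float(p.cumulative_area_km2),
            },
        })
    geo_path = outdir / "daily_perimeters.geojson"
    with open(geo_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)

    rows = []
    for s in summaries:
        rows.append({
            "fire_id": s.fire_id, "day_index": s.day_index,
            "ros_p95": s.ros_p95, "ros_mean": s.ros_mean,
            "expansion_area_km2": s.expansion_area_km2,
            "cumulative_area_km2": s.cumulative_area_km2,
            "mean_frp": s.mean_frp, "n_line_detections": s.n_line_detections,
        })
    csv_path = outdir / "fire_day_summaries.csv"
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(csv_path, index=False)
    return geo_path, csv_path


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_daily_perimeters(path: str | Path,
                          projection: AlbersEqualArea) -> list[dict]:
    """Read a daily-perimeter GeoJSON back into projected geometries."""
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc.get("features", []):
        rec = dict(feat["properties"])
        rec["polygon"] = projection.project_geometry(shape(feat["geometry"]))
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Severity rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_severity_raster(path: str | Path, metric: str) -> SeverityRaster:
    """Read a single-band ESRI ASCII grid (.asc) in working-CRS metres."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:][: int(header["nrows"])], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid shape does not match header")
    return SeverityRaster(
        metric=metric, values=values,
        xll=header["xllcorner"], yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0))


def write_severity_raster(raster: SeverityRaster, path: str | Path) -> None:
    nrows, ncols = raster.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {raster.xll!r}\nyllcorner {raster.yll!r}\n"
                 f"cellsize {raster.cellsize!r}\nnodata_value {raster.nodata!r}\n")
        np.savetxt(fh, raster.values, fmt="%.6g")
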