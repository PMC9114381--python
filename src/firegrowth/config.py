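"""Runtime configuration.

Every algorithm constant of the tracking method (selection thresholds,
buffers, clustering cutoff, alpha schedule, fire-line band, percentile) is a
field here so a single YAML file can override any of them. Defaults are the
method's published values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Default mapping from detection-CSV column names to Detection fields.
DEFAULT_DETECTION_COLUMNS = {
    "latitude": "latitude",
    "longitude": "longitude",
    "acq_date": "acq_date",
    "acq_time": "acq_time",
    "frp": "frp",
    "daynight": "daynight",
    "overpass_id": "overpass_id",  # optional in the file
}

#: Default mapping from fire-perimeter attribute names to FireRecord fields.
DEFAULT_PERIMETER_ATTRS = {
    "fire_id": "fire_id",
    "cause": "cause",
    "alarm_date": "alarm_date",
    "containment_date": "containment_date",
}

#: Ignition-cause dictionary: raw attribute string (lower-cased) -> enum value.
#: Anything not listed maps to "unknown" with a warning. All causes related
#: to human activity are treated as human ignitions.
DEFAULT_CAUSE_MAP = {
    "lightning": "lightning",
    "human": "human",
    "arson": "human",
    "campfire": "human",
    "debris": "human",
    "debris burning": "human",
    "equipment use": "human",
    "playing with fire": "human",
    "powerline": "human",
    "power line": "human",
    "railroad": "human",
    "smoking": "human",
    "vehicle": "human",
    "escaped prescribed burn": "human",
    "structure": "human",
    "firefighter training": "human",
    "unknown": "unknown",
    "undetermined": "unknown",
    "miscellaneous": "unknown",
}


@dataclass
class Config:
    """All tunable parameters of the tracking and analysis pipeline."""

    # -- working projection: Albers equal-area conic (California Albers
    #    style, GRS80). Distances/areas are computed in projected metres.
    proj_lat0: float = 0.0
    proj_lon0: float = -120.0
    proj_lat1: float = 34.0
    proj_lat2: float = 40.5
    proj_false_easting: float = 0.0
    proj_false_northing: float = -4_000_000.0

    # -- fire selection
    min_area_ha: float = 300.0        # retain fires strictly larger than this
    min_days: int = 2                 # minimum alarm-to-containment duration

    # -- detection extraction
    buffer_m: float = 750.0           # dilation of the final perimeter
    day_pad_days: int = 1             # temporal pad around alarm/containment
    fallback_window_months: int = 3   # window when dates are missing

    # -- timestep grouping
    day_start_hour: int = 6           # local hour at which a fire day begins
    dedup_tol_deg: float = 1e-5       # coordinate tolerance for swath-overlap dedup

    # -- sub-fire clustering (single linkage)
    link_dist_m: float = 1500.0

    # -- perimeter construction
    alpha0_km: float = 0.05           # starting alpha (circumradius, km)
    alpha_step_km: float = 0.05
    alpha_max_km: float = 50.0
    footprint_m: float = 375.0        # sensor pixel footprint (I-band)

    # -- rate of spread
    line_band_m: float = 100.0        # fire-line band around today's boundary
    ros_percentile: float = 95.0      # daily summary percentile (type-7 interp)

    # -- analysis
    min_expansion_ha: float = 1.0     # severity-vs-ROS expansion filter
    running_mean_min_window: int = 51
    running_mean_frac: float = 0.05

    # -- file-format mappings
    detection_columns: dict = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_COLUMNS))
    perimeter_attrs: dict = field(
        default_factory=lambda: dict(DEFAULT_PERIMETER_ATTRS))
    cause_map: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_MAP))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        """Load a config, overriding defaults with keys found in the file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
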