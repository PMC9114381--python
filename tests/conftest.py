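"""Shared fixtures for the firegrowth test suite."""

from datetime import datetime

import numpy as np
import pytest
from shapely.geometry import Polygon

from firegrowth.io_formats import AlbersEqualArea, Detection, FireRecord


@pytest.fixture(scope="session")
def proj():
    return AlbersEqualArea()


def make_detection(x, y, t=datetime(2017, 7, 1, 13, 30), frp=10.0,
                   daynight="day", det_id=None, proj=None, overpass_id=None):
    """Detection at projected (x, y) metres; lon/lat derived when a
    projection is supplied, else placed near the projection origin."""
    if proj is not None:
        lon, lat = proj.inverse(x, y)
    else:
        lon, lat = -120.0 + x / 90_000.0, 37.0 + y / 110_000.0
    return Detection(det_id=det_id or f"{x:.0f}_{y:.0f}_{t:%H%M}",
                     lon=lon, lat=lat, x=float(x), y=float(y), acq_time=t,
                     frp=frp, daynight=daynight, overpass_id=overpass_id)


def make_fire(fire_id="F1", cause="human", side_km=2.0, alarm=None,
              containment=None, center=(0.0, 0.0)):
    """Square fire perimeter of the given side length, in projected metres."""
    h = side_km * 500.0
    cx, cy = center
    poly = Polygon([(cx - h, cy - h), (cx + h, cy - h),
                    (cx + h, cy + h), (cx - h, cy + h)])
    return FireRecord(fire_id=fire_id, cause=cause, final_perimeter=poly,
                      alarm_date=alarm, containment_date=containment,
                      final_area_km2=poly.area / 1e6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
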