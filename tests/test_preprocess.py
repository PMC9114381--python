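"""Fire selection, extraction windows, daily grouping, sub-fire clustering."""

import random
from datetime import date, datetime

import numpy as np
import pytest

from _oracles import connected_components_oracle
from conftest import make_detection, make_fire
from firegrowth.preprocess import (SubFire, TimestepGroup, cluster_subfires,
                                   extract_detections, group_timesteps,
                                   select_fires)


class TestSelectFires:
    @pytest.mark.parametrize("side_km,days,kept", [
        # 2.99 km2 = 299 ha over 5 days: below the area threshold
        (np.sqrt(2.99), 5, False),
        # 301 ha but a single day of burning: below the duration threshold
        (np.sqrt(3.01), 1, False),
        (np.sqrt(3.01), 2, True),
        (2.0, 5, True),
    ])
    def test_thresholds(self, side_km, days, kept):
        f = make_fire(side_km=side_km, alarm=date(2017, 7, 1),
                      containment=date(2017, 7, 1 + days))
        assert (select_fires([f]) == [f]) is kept

    def test_missing_dates_retained(self):
        f = make_fire(side_km=2.0, alarm=None, containment=None)
        assert select_fires([f]) == [f]  # duration resolved by the 3-month window

    def test_exactly_300ha_excluded(self):
        f = make_fire(side_km=np.sqrt(3.0), alarm=date(2017, 7, 1),
                      containment=date(2017, 7, 9))
        assert select_fires([f]) == []


class TestExtractDetections:
    def _fire(self):
        return make_fire(side_km=2.0, alarm=date(2017, 7, 1),
                         containment=date(2017, 7, 5))

    def test_spatial_buffer(self):
        fire = self._fire()  # square with edges at +/-1000 m
        t = datetime(2017, 7, 2, 13, 30)
        inside = make_detection(1500, 0, t)    # 500 m outside the perimeter
        outside = make_detection(1800, 0, t)   # 800 m outside
        got = extract_detections(fire, [inside, outside], buffer_m=750)
        assert got == [inside]

    def test_temporal_pad(self):
        fire = self._fire()
        ok = make_detection(0, 0, datetime(2017, 7, 6, 13, 30))      # +1 day
        late = make_detection(0, 0, datetime(2017, 7, 7, 13, 30))    # +2 days
        early = make_detection(0, 0, datetime(2017, 6, 30, 1, 30))   # -1 day
        got = extract_detections(fire, [early, ok, late], day_pad=1)
        assert got == [early, ok]

    def test_missing_dates_fallback_window(self):
        fire = make_fire(side_km=2.0, alarm=None, containment=None)
        first = make_detection(0, 0, datetime(2017, 7, 1, 13, 30))
        within = make_detection(0, 100, datetime(2017, 9, 20, 13, 30))
        beyond = make_detection(0, 200, datetime(2017, 10, 2, 13, 30))
        got = extract_detections(fire, [beyond, first, within],
                                 fallback_window_months=3)
        assert got == [first, within]

    def test_no_detections_in_window(self):
        fire = self._fire()
        far = make_detection(90_000, 0, datetime(2017, 7, 2, 13, 30))
        assert extract_detections(fire, [far]) == []


class TestGroupTimesteps:
    def test_day_and_following_night_form_one_group(self):
        d1 = make_detection(0, 0, datetime(2017, 7, 1, 13, 30))
        d2 = make_detection(400, 0, datetime(2017, 7, 2, 1, 30),
                            daynight="night")
        (g,) = group_timesteps([d1, d2], "F")
        assert g.day_index == 1
        assert g.timestep_end == datetime(2017, 7, 2, 1, 30)
        assert len(g.detections) == 2

    def test_overlapping_swaths_deduplicated_to_last_overpass(self):
        a = make_detection(0, 0, datetime(2017, 7, 1, 13, 0), det_id="a")
        b = make_detection(0, 0, datetime(2017, 7, 1, 13, 6), det_id="b")
        (g,) = group_timesteps([a, b], "F")
        assert [d.det_id for d in g.detections] == ["b"]
        assert g.timestep_end == datetime(2017, 7, 1, 13, 6)

    def test_gap_days_produce_consecutive_indices(self):
        d1 = make_detection(0, 0, datetime(2017, 7, 1, 13, 30))
        d2 = make_detection(0, 0, datetime(2017, 7, 3, 13, 30))
        g1, g2 = group_timesteps([d1, d2], "F")
        assert (g1.day_index, g2.day_index) == (1, 2)
        dt = (g2.timestep_end - g1.timestep_end).total_seconds() / 86400
        assert dt == pytest.approx(2.0)

    def test_order_independence_and_idempotence(self):
        rng = random.Random(7)
        dets = [make_detection(i * 400.0, 0,
                               datetime(2017, 7, 1 + i % 3, 13, 30),
                               det_id=f"d{i}") for i in range(12)]
        ref = group_timesteps(dets, "F")
        shuffled = dets[:]
        rng.shuffle(shuffled)
        got = group_timesteps(shuffled, "F")
        assert [(g.day_index, [d.det_id for d in g.detections]) for g in got] \
            == [(g.day_index, [d.det_id for d in g.detections]) for g in ref]

    def test_empty_input(self):
        assert group_timesteps([], "F") == []


def _group(xy, day=1, fire_id="F"):
    dets = [make_detection(x, y, det_id=f"p{i}")
            for i, (x, y) in enumerate(xy)]
    return TimestepGroup(fire_id=fire_id, day_index=day,
                         fire_day=date(2017, 7, day),
                         timestep_end=datetime(2017, 7, day, 13, 30),
                         detections=dets)


class TestClusterSubfires:
    def test_far_pair_splits(self):
        subs = cluster_subfires(_group([(0, 0), (1600, 0)]), [])
        assert len(subs) == 2

    def test_chain_links_into_one(self):
        subs = cluster_subfires(_group([(i * 1000.0, 0) for i in range(5)]), [])
        assert len(subs) == 1
        assert len(subs[0].detections_by_day[1]) == 5

    def test_bridge_component_merges_two_priors(self):
        subs = cluster_subfires(_group([(0, 0), (10_000, 0)], day=1), [])
        a, b = subs
        # day 2: a component within 1500 m of both priors
        bridge = _group([(1400, 0), (2700, 0), (4000, 0), (5300, 0),
                         (6600, 0), (7900, 0), (9200, 0)], day=2)
        subs = cluster_subfires(bridge, subs)
        active = [s for s in subs if s.active]
        assert len(active) == 1
        assert active[0].merge_history == [(2, b.subfire_id)]
        assert not b.active
        # the absorbed history moved over: all detections in one sub-fire
        assert sum(len(v) for v in active[0].detections_by_day.values()) == 9

    def test_partition_property(self, rng):
        xy = rng.uniform(0, 8000, size=(60, 2))
        subs = cluster_subfires(_group(xy), [])
        ids = [d.det_id for s in subs for d in s.detections_by_day[1]]
        assert sorted(ids) == sorted(f"p{i}" for i in range(60))

    def test_matches_brute_force_components(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 120))
            xy = rng.uniform(0, 12_000, size=(n, 2))
            subs = cluster_subfires(_group(xy), [])
            labels = connected_components_oracle(xy, 1500.0)
            got = {}
            for s in subs:
                members = frozenset(d.det_id for d in s.detections_by_day[1])
                got[members] = True
            expected = {}
            for c in range(labels.max() + 1):
                members = frozenset(f"p{i}" for i in np.nonzero(labels == c)[0])
                expected[members] = True
            assert got.keys() == expected.keys()
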