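# firegrowth

Reconstruct daily wildfire perimeters and rates of spread from satellite
active-fire point detections, and analyse how spread rate relates to fire
size, burned area and burn severity.

Polar-orbiting sensors such as VIIRS detect actively burning pixels at ~375 m
resolution twice a day. `firegrowth` turns those point detections into a daily
growth history for each fire:

1. **Extraction** — detections are matched to a fire's final perimeter
   (within a 750 m buffer) and its burning period, then grouped into *fire
   days*: one afternoon overpass plus the following night's overpass, with
   overlapping-swath duplicates resolved to the last overpass.
2. **Sub-fire clustering** — each day's detections are partitioned by
   single-linkage clustering at 1500 m; separate ignitions are tracked as
   individual sub-fires until they merge, after which one perimeter is drawn
   around all of them together.
3. **Perimeter reconstruction** — the cumulative detections of each sub-fire
   are wrapped in an adaptive alpha hull (a concave hull built from the
   Delaunay triangulation): the alpha parameter starts at 0.05 km and is
   raised in 0.05 km steps until a single connected polygon contains every
   point. Daily perimeters are monotone non-decreasing by construction.
4. **Rate of spread (ROS)** — detections within 100 m of today's perimeter
   form the fire line; each one's ROS is its distance to the previous day's
   perimeter divided by the elapsed time. The daily fire-line ROS is the 95th
   percentile of those samples (km/day); points that did not advance count
   as zero.
5. **Analysis** — burned-area-weighted mean ROS per fire, Welch-*t* and
   Kolmogorov–Smirnov comparisons between ignition-cause groups, ROS
   frequency distributions weighted by fire days or burned area, the
   burned-area share of the fastest decile of fire days, and zonal sampling
   of burn-severity rasters over each day's newly burned area with OLS
   regression of severity on ROS.

A ground-truthed synthetic fire simulator (`firegrowth.synthetic`) generates
growing elliptical fires that emit lattice detections at the real overpass
cadence, with known true daily spread, multi-ignition merging fires, and
severity rasters whose values increase with local spread rate. It is used to
validate the whole pipeline end to end.

## Quick start (Python)

```python
from firegrowth import FireScenario, SimConfig, simulate_fire, track_fire

scenario = FireScenario("demo", "lightning", ignitions=[(0.0, 0.0)],
                        ros_schedule=[1.0, 2.0, 0.5, 1.5])   # km/day
detections, record, truth = simulate_fire(scenario, SimConfig(seed=7))

tracked = track_fire(record, detections)
for s in tracked.summaries:
    print(f"day {s.day_index}: ros_p95={s.ros_p95:.2f} km/d  "
          f"area={s.cumulative_area_km2:.1f} km2")
```

Output (1112 simulated detections; true daily areas are 3.1, 28.3, 38.5 and
78.5 km²):

```
day 1: ros_p95=nan km/d  area=2.4 km2
day 2: ros_p95=2.12 km/d  area=26.0 km2
day 3: ros_p95=0.53 km/d  area=35.0 km2
day 4: ros_p95=1.55 km/d  area=73.0 km2
```

Day 1 has no ROS because there is no previous perimeter to measure from. The
daily ROS estimates track the prescribed schedule (1.0, 2.0, 0.5, 1.5 km/day)
to within the quantization of the 375 m detection lattice, and the tracked
areas sit a few percent below truth because the hull of lattice points is
slightly inside the true front.

## Command line

```bash
firegrowth simulate --seed 5 --n-fires 10 --out sim/        # synthetic inputs
firegrowth track --detections sim/detections.csv \
                 --perimeters sim/perimeters.geojson --out tracked/
firegrowth ros --tracked tracked/ --out fire_level.csv
firegrowth severity --raster severity.asc --tracked tracked/ --out sev.csv
firegrowth stats --summaries tracked/fire_day_summaries.csv \
                 --fires tracked/fires.csv --out stats.json
```

`track` reads a VIIRS-style detection CSV and a GeoJSON of final fire
perimeters (with ignition-cause and date attributes) and writes daily
perimeters plus per-fire-day ROS summaries; the remaining commands operate on
those outputs. Column and attribute names are remappable via `--config`
(YAML, see `firegrowth.config.Config`).

## Documentation

`docs/methods.md` describes the method, its parameters and defaults, the
synthetic generator's design, and known limitations.
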