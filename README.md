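# tidechan

Tidal channel network extraction and watershed-scale network metrics for
coastal wetlands (salt marshes and mangroves), plus the supporting analyses:
order-removal correction of satellite-derived metrics, channel-length/area
power-law scaling, nonparametric group comparisons, and flume-experiment
surface analyses. Everything is exercisable on synthetic wetlands with known
ground truth — no external data required.

## What it does

- **scene_io** — GeoTIFF rasters (via `tifffile` + GeoTIFF pixel-scale /
  tiepoint tags), GeoJSON channel networks, CSV metric tables, YAML config.
  Coordinates are planar meters; pixel centers at
  `(x0 + (col+0.5)·ps, y0 − (row+0.5)·ps)`.
- **synthetic_data** — grows vector channel trees draining to the seaward
  (bottom) edge, rasterizes them at order-dependent widths, renders 4-band
  scenes (NDWI-separable spectra) and channelized DEMs, and samples
  power-law `(Area, ΣL)` datasets. Also a deterministic self-similar
  fractal tree whose length-per-order decays geometrically.
- **channel_extraction** — unsupervised Gaussian maximum-likelihood
  clustering of 4-band pixels (k-means seeded, full covariances),
  NDWI-based reclassification to a binary channel mask, a moving-median
  DEM thresholding route, and mask cleanup.
- **network_graph** — skeletonization, centerline graph tracing (rook steps
  = pixel size, diagonal steps = √2×), outlet identification, Strahler
  ordering, order pruning, rasterization.
- **watershed_metrics** — Euclidean allocation of wetland pixels to channel
  components, exact distance transforms, and per-watershed records of
  drainage density `D = ΣL/A`, Hortonian length `l_H = 1/D`, mean
  unchanneled path length `mUpl`, and geometric efficiency `GE = l_H/mUpl`.
- **correction** — order-removal curves (metric vs removed Strahler order),
  exponential fits `α·exp(β·r)`, and curve-inversion correction of
  satellite metrics back to the full-resolution level.
- **stats_scaling** — log-log OLS power-law fits with regression
  F-statistics, nested-model comparison between groups, exact/approximate
  two-sided Wilcoxon rank-sum, Shapiro–Wilk gate.
- **flume_analysis** — hydrodynamic scaling parameter `U·T/L`, sediment
  mobility `BSS/BSS_crit`, sedimentation–erosion maps, channel counts along
  flume transects, experimental `D` and `mUpl`.

## CLI

```bash
tidechan --seed 3 synth network --shape 400 400 --n-outlets 2 --out-prefix w
tidechan --seed 1 classify scene.tif aoi.tif mask.tif --k 10
tidechan extract w_mask.tif --seaward bottom --out network.geojson
tidechan metrics w_mask.tif network.geojson --location siteA --type saltmarsh --out metrics.csv
tidechan scaling metrics.csv --group wetland_type --out scaling.json
tidechan correct metrics.csv --model model.yaml --out corrected.csv
tidechan flume diff t0.tif t1.tif --out sedero.tif
tidechan flume count sedero.tif --threshold 0.002
```

Global flags: `--config config.yaml` (per-module namespaces, overridden by
CLI flags), `--seed`, `--log-level`.

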