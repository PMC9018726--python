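"""Euclidean watershed delineation and the three network metrics.

Watersheds are the Euclidean allocation of in-AOI pixels to channel
COMPONENTS (one watershed per connected channel network), matching the
distance transform used for the unchanneled path length. Per watershed:

  D    = sum(L) / A           Hortonian drainage density (1/m)
  l_H  = 1 / D                Hortonian length (m)
  mUpl = mean platform distance to the nearest channel (m)
  GE   = l_H / mUpl           geometric efficiency (-)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from tidechan.network_graph import ChannelNetwork, component_lengths
from tidechan.scene_io import ChannelMask, RasterGrid

logger = logging.getLogger("tidechan")

_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class WatershedMap:
    """Per-pixel watershed ids (0 outside the AOI) and their areas in m2."""

    labels: RasterGrid
    areas: dict[int, float]


@dataclass
class MetricRecord:
    watershed_id: int
    location: str
    wetland_type: str
    area_m2: float
    total_length_m: float
    drainage_density: float  # 1/m; 0 when the watershed has no channels
    mupl: float | None  # m; None when the watershed has no platform pixels
    hortonian_length: float | None  # m; None when D == 0
    geometric_efficiency: float | None  # -; None when undefined


def _component_seeds(mask: ChannelMask, network: ChannelNetwork):
    """Map watershed ids to boolean seed rasters (channel pixels).

    Network components own the mask components their polylines run through;
    channel blobs not touched by any edge get fresh ids above the maximum
    network component id.
    """
    chan = mask.channel
    lbl, n_blobs = ndimage.label(chan, structure=_EIGHT)
    grid = mask.grid
    blob_owner: dict[int, int] = {}
    for eid in sorted(network.edges):
        e = network.edges[eid]
        for x, y in e.points:
            r, c = grid.world_to_pixel(x, y)
            r, c = int(round(r)), int(round(c))
            if not (0 <= r < lbl.shape[0] and 0 <= c < lbl.shape[1]):
                continue
            blob = lbl[r, c]
            if blob == 0:  # polyline point rounded just off the blob
                window = lbl[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
                nz = window[window > 0]
                blob = int(nz[0]) if nz.size else 0
            if blob and blob not in blob_owner:
                blob_owner[blob] = e.component_id
    next_id = max(network.component_ids(), default=0)
    for blob in range(1, n_blobs + 1):
        if blob not in blob_owner:
            next_id += 1
            blob_owner[blob] = next_id
    seeds: dict[int, np.ndarray] = {}
    for blob, wid in blob_owner.items():
        seeds.setdefault(wid, np.zeros(chan.shape, dtype=bool))
        seeds[wid] |= lbl == blob
    return seeds


def delineate_watersheds(mask: ChannelMask, network: ChannelNetwork) -> WatershedMap:
    """Assign each in-AOI pixel to the nearest channel component.

    Distances are Euclidean between pixel centers; ties go to the smaller
    watershed id. Without any channel pixels the whole AOI becomes one
    watershed with id 0 (warned).
    """
    aoi = mask.aoi
    ps = mask.pixel_size
    shape = aoi.shape
    labels = np.zeros(shape, dtype=int)

    if not mask.channel.any():
        logger.warning("no channel pixels; AOI returned as a single watershed (id 0)")
        areas = {0: float(aoi.sum()) * ps * ps}
        return WatershedMap(
            RasterGrid(labels, ps, 0, mask.grid.origin), areas
        )

    seeds = _component_seeds(mask, network)
    best_dist = np.full(shape, np.inf)
    best_id = np.zeros(shape, dtype=int)
    for wid in sorted(seeds):
        dist = ndimage.distance_transform_edt(~seeds[wid])
        closer = dist < best_dist - 1e-9  # strict: ties keep the smaller id
        best_dist[closer] = dist[closer]
        best_id[closer] = wid

    labels[aoi] = best_id[aoi]
    ids, counts = np.unique(labels[aoi], return_counts=True)
    areas = {int(i): float(c) * ps * ps for i, c in zip(ids, counts)}
    return WatershedMap(RasterGrid(labels, ps, 0, mask.grid.origin), areas)


def unchanneled_distance(mask: ChannelMask) -> RasterGrid:
    """Exact Euclidean distance (m) from each platform pixel center to the
    nearest channel pixel center; 0 on channels, NaN outside the AOI."""
    chan = mask.channel
    if not chan.any():
        raise ValueError("channel set is empty")
    dist = ndimage.distance_transform_edt(~chan) * mask.pixel_size
    out = dist.astype(float)
    out[~mask.aoi] = np.nan
    return RasterGrid(out, mask.pixel_size, float("nan"), mask.grid.origin)


def compute_metrics(
    watersheds: WatershedMap,
    network: ChannelNetwork,
    distances: RasterGrid,
    mask: ChannelMask,
    location: str = "",
    wetland_type: str = "",
) -> list[MetricRecord]:
    """Per-watershed metric records (missing values stay None, never NaN)."""
    lengths = component_lengths(network)
    labels = watersheds.labels.values
    chan = mask.channel
    aoi = mask.aoi
    dvals = distances.values
    records = []
    for wid in sorted(watersheds.areas):
        area = watersheds.areas[wid]
        sigma_l = float(lengths.get(wid, 0.0))
        d = sigma_l / area if area > 0 else 0.0
        member = (labels == wid) & aoi
        platform = member & ~chan
        if platform.any():
            mupl = float(np.nanmean(dvals[platform]))
        else:
            mupl = None
        l_h = (1.0 / d) if d > 0 else None
        ge = (l_h / mupl) if (l_h is not None and mupl and mupl > 0) else None
        records.append(
            MetricRecord(
                watershed_id=int(wid),
                location=location,
                wetland_type=wetland_type,
                area_m2=area,
                total_length_m=sigma_l,
                drainage_density=d,
                mupl=mupl,
                hortonian_length=l_h,
                geometric_efficiency=ge,
            )
        )
    return records


def wetland_drainage_density(records_or_network, aoi_area: float) -> float:
    """Total channel length over the entire wetland area (1/m)."""
    if not aoi_area > 0:
        raise ValueError("aoi_area must be > 0")
    if isinstance(records_or_network, ChannelNetwork):
        total = sum(e.length for e in records_or_network.edges.values())
    else:
        total = sum(r.total_length_m for r in records_or_network)
    return float(total) / float(aoi_area)


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "watershed_id": [r.watershed_id for r in records],
            "location": [r.location for r in records],
            "wetland_type": [r.wetland_type for r in records],
            "area_m2": [r.area_m2 for r in records],
            "total_length_m": [r.total_length_m for r in records],
            "drainage_density_per_m": [r.drainage_density for r in records],
            "mupl_m": [np.nan if r.mupl is None else r.mupl for r in records],
            "hortonian_length_m": [
                np.nan if r.hortonian_length is None else r.hortonian_length
                for r in records
            ],
            "geometric_efficiency": [
                np.nan if r.geometric_efficiency is None else r.geometric_efficiency
                for r in records
            ],
        }
    )


def summarize_locations(records: list[MetricRecord] | pd.DataFrame):
    """Per-location means/SEs and per-type vectors of location means.

    Returns ``(per_location, per_type)``: a DataFrame indexed by location
    with mean and standard error (sd / sqrt(n), NaN for n = 1) of D, mUpl
    and GE over watersheds, and a dict mapping wetland type to the
    DataFrame of its location means (the units compared between types).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    metrics = ["drainage_density_per_m", "mupl_m", "geometric_efficiency"]
    rows = []
    for (loc, wtype), grp in df.groupby(["location", "wetland_type"], sort=True):
        row = {"location": loc, "wetland_type": wtype, "n_watersheds": len(grp)}
        for m in metrics:
            vals = grp[m].dropna()
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    per_location = pd.DataFrame(rows).set_index("location")
    per_type = {
        wtype: grp[[f"{m}_mean" for m in metrics]]
        for wtype, grp in per_location.groupby("wetland_type")
    }
    return per_location, per_type
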