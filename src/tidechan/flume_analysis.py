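"""Flume-experiment calculators: hydrodynamic scaling, sediment mobility,
sedimentation-erosion maps, transect channel counts, and experimental
drainage density / unchanneled path length.

The flume's long axis runs along raster columns by convention
(``axis="long"`` samples cross-sections at column positions); pass
``axis="cross"`` for the transposed layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tidechan.network_graph import build_network, skeletonize, total_length
from tidechan.scene_io import ChannelMask, RasterGrid


@dataclass
class ScalingCheck:
    flow_velocity: float  # U, m/s
    tidal_period: float  # T, s
    characteristic_length: float  # L, m

    @property
    def value(self) -> float:
        return scaling_parameter(
            self.flow_velocity, self.tidal_period, self.characteristic_length
        )


@dataclass
class MobilityCheck:
    bss: float  # bed shear stress, N/m2
    bss_crit: float  # critical shear stress, N/m2

    @property
    def value(self) -> float:
        return mobility(self.bss, self.bss_crit)


def scaling_parameter(flow_velocity: float, tidal_period: float, length: float) -> float:
    """Dimensionless hydrodynamic scaling parameter U * T / L."""
    if flow_velocity <= 0 or tidal_period <= 0 or length <= 0:
        raise ValueError("U, T and L must all be > 0")
    return flow_velocity * tidal_period / length


def mobility(bss: float, bss_crit: float) -> float:
    """Sediment mobility: bed shear stress over its critical value."""
    if bss_crit <= 0:
        raise ValueError("bss_crit must be > 0")
    return bss / bss_crit


def sed_erosion_map(dem_start: RasterGrid, dem_end: RasterGrid) -> RasterGrid:
    """Signed elevation change (m): positive deposition, negative erosion.

    Nodata in either input propagates to the output.
    """
    if dem_start.shape != dem_end.shape:
        raise ValueError("DEMs must share the grid shape")
    if dem_start.pixel_size != dem_end.pixel_size:
        raise ValueError("DEMs must share the pixel size")
    a = dem_start.values.astype(float)
    b = dem_end.values.astype(float)
    diff = b - a
    bad = np.isnan(a) | np.isnan(b)
    for grid, vals in ((dem_start, a), (dem_end, b)):
        if grid.nodata is not None and not np.isnan(grid.nodata):
            bad |= vals == grid.nodata
    diff[bad] = np.nan
    return RasterGrid(diff, dem_start.pixel_size, float("nan"), dem_start.origin)


def _count_runs(line: np.ndarray, threshold: float, min_run: int = 2) -> int:
    """Number of maximal runs of >= min_run contiguous pixels eroded below
    -threshold."""
    eroded = np.nan_to_num(line, nan=0.0) <= -threshold
    count = run = 0
    for v in eroded:
        if v:
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 0
    if run >= min_run:
        count += 1
    return count


def count_channels_transects(
    sedero: RasterGrid,
    threshold: float = 0.002,
    axis: str = "long",
    spacing: int = 1,
) -> pd.DataFrame:
    """Channel counts along the flume.

    Cross-sections perpendicular to the long axis are sampled every
    ``spacing`` pixels; a channel is a maximal run of >= 2 contiguous
    pixels eroded below ``-threshold``. Returns columns ``position_m`` and
    ``n_channels``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vals = sedero.values
    if axis == "cross":
        vals = vals.T
    elif axis != "long":
        raise ValueError("axis must be 'long' or 'cross'")
    positions = range(0, vals.shape[1], max(int(spacing), 1))
    rows = [
        {
            "position_px": pos,
            "position_m": (pos + 0.5) * sedero.pixel_size,
            "n_channels": _count_runs(vals[:, pos], threshold),
        }
        for pos in positions
    ]
    return pd.DataFrame(rows)


def erosion_mask(sedero: RasterGrid, threshold: float = 0.002) -> ChannelMask:
    """Threshold an erosion map into a channel mask over the whole domain."""
    chan = np.nan_to_num(sedero.values, nan=0.0) <= -threshold
    aoi = np.ones_like(chan, dtype=np.uint8)
    return ChannelMask(
        RasterGrid(chan.astype(np.uint8), sedero.pixel_size, None, sedero.origin),
        RasterGrid(aoi, sedero.pixel_size, None, sedero.origin),
    )


def experiment_metrics(
    sedero_or_mask, pixel_size: float | None = None, threshold: float = 0.002
):
    """Whole-domain drainage density (1/m) and mean unchanneled path length
    (m) of a flume surface; mUpl is None when no channels are present."""
    from tidechan.watershed_metrics import unchanneled_distance

    if isinstance(sedero_or_mask, ChannelMask):
        mask = sedero_or_mask
    else:
        mask = erosion_mask(sedero_or_mask, threshold)
    ps = pixel_size if pixel_size is not None else mask.pixel_size
    area = float(mask.aoi.sum()) * ps * ps
    if not mask.channel.any():
        return 0.0, None
    skel = skeletonize(mask)
    net = build_network(skel, ps)
    d = total_length(net) / area
    dist = unchanneled_distance(mask)
    platform = mask.aoi & ~mask.channel
    mupl = float(np.nanmean(dist.values[platform])) if platform.any() else None
    return d, mupl
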