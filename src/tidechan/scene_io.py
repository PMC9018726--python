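"""Raster, vector and tabular I/O plus grid conventions.

Grid convention: 0-based (row, col); the world coordinate of the center of
pixel (row, col) is ``(x0 + (col + 0.5) * pixel_size, y0 - (row + 0.5) *
pixel_size)`` where ``(x0, y0)`` is the upper-left pixel corner. Areas are
pixel counts times ``pixel_size ** 2``. Only square pixels are supported.

Rasters are stored as plain TIFF with the GeoTIFF ``ModelPixelScale`` /
``ModelTiepoint`` tags (and ``GDAL_NODATA``), which is enough to carry the
planar-meter frame used throughout; no CRS is read or validated.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("tidechan")

BAND_NAMES = ("R", "G", "B", "NIR")

# GeoTIFF / GDAL private TIFF tags
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """Single-band raster on a square-pixel grid in planar meters."""

    values: np.ndarray
    pixel_size: float
    nodata: float | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_to_world(self, row, col):
        """World coordinates of pixel centers."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y):
        """Inverse of :meth:`pixel_to_world` (exact for pixel centers)."""
        x0, y0 = self.origin
        col = (np.asarray(x) - x0) / self.pixel_size - 0.5
        row = (y0 - np.asarray(y)) / self.pixel_size - 0.5
        return row, col

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values, self.pixel_size, self.nodata, self.origin)


@dataclass
class Scene:
    """Four co-registered bands keyed R, G, B, NIR."""

    bands: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if tuple(self.bands.keys()) != BAND_NAMES:
            raise ValueError(f"bands must be exactly {BAND_NAMES} in order")
        ref = self.bands["R"]
        for name, band in self.bands.items():
            if band.shape != ref.shape or band.pixel_size != ref.pixel_size:
                raise ValueError(f"band {name} does not match grid of band R")

    @property
    def pixel_size(self) -> float:
        return self.bands["R"].pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["R"].shape

    @property
    def origin(self) -> tuple[float, float]:
        return self.bands["R"].origin

    def stack(self) -> np.ndarray:
        """(rows, cols, 4) float array in R, G, B, NIR order."""
        return np.stack([self.bands[b].values for b in BAND_NAMES], axis=-1).astype(float)


@dataclass
class ChannelMask:
    """Binary channel raster clipped to a wetland area of interest.

    ``grid`` holds 1 on channel pixels, ``wetland`` holds 1 inside the AOI;
    channel pixels are always a subset of wetland pixels.
    """

    grid: RasterGrid
    wetland: RasterGrid

    def __post_init__(self) -> None:
        if self.grid.shape != self.wetland.shape:
            raise ValueError("channel and wetland grids must share shape")
        if self.grid.pixel_size != self.wetland.pixel_size:
            raise ValueError("channel and wetland grids must share pixel_size")
        chan = self.grid.values.astype(bool)
        wet = self.wetland.values.astype(bool)
        if np.any(chan & ~wet):
            raise ValueError("channel pixels must lie inside the wetland AOI")

    @property
    def channel(self) -> np.ndarray:
        return self.grid.values.astype(bool)

    @property
    def aoi(self) -> np.ndarray:
        return self.wetland.values.astype(bool)

    @property
    def pixel_size(self) -> float:
        return self.grid.pixel_size


# ---------------------------------------------------------------------------
# Raster I/O


def _geo_extratags(pixel_size: float, origin: tuple[float, float], nodata):
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(pixel_size), float(pixel_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
    ]
    if nodata is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    return tags


def write_raster(obj: RasterGrid | Scene, path) -> None:
    """Write a RasterGrid (1 band) or Scene (4 bands, R,G,B,NIR order) as GeoTIFF."""
    path = Path(path)
    if isinstance(obj, Scene):
        data = np.stack([obj.bands[b].values for b in BAND_NAMES], axis=0)
        pixel_size, origin = obj.pixel_size, obj.origin
        nodata = obj.bands["R"].nodata
    else:
        data = obj.values
        pixel_size, origin, nodata = obj.pixel_size, obj.origin, obj.nodata
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        extratags=_geo_extratags(pixel_size, origin, nodata),
    )


def read_raster(path, band_order: tuple[str, ...] | None = None):
    """Read a GeoTIFF into a Scene (4 bands) or RasterGrid (1 band).

    ``band_order`` names the stored band order for multiband files; it must
    be a permutation of ("R", "G", "B", "NIR") and defaults to that order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        if abs(scale[0] - scale[1]) > 1e-12 * max(abs(scale[0]), 1.0):
            raise ValueError(
                f"non-square pixels ({scale[0]} x {scale[1]}) are not supported"
            )
        pixel_size = float(scale[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        else:
            origin = (0.0, 0.0)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)

    if data.ndim == 2:
        return RasterGrid(data, pixel_size, nodata, origin)
    if data.ndim == 3:
        # accept band-first or (rows, cols, 4) band-last layouts
        if data.shape[0] == 1:
            return RasterGrid(data[0], pixel_size, nodata, origin)
        if data.shape[0] == 4:
            bands3 = data
        elif data.shape[-1] == 4 and data.shape[0] > 8:
            bands3 = np.moveaxis(data, -1, 0)
        else:
            raise ValueError(
                f"unsupported band count: expected 1 or 4, got {data.shape[0]}"
            )
        order = tuple(band_order) if band_order is not None else BAND_NAMES
        if sorted(order) != sorted(BAND_NAMES):
            raise ValueError(f"band_order must be a permutation of {BAND_NAMES}")
        by_name = {name: bands3[i] for i, name in enumerate(order)}
        return Scene(
            {b: RasterGrid(by_name[b], pixel_size, nodata, origin) for b in BAND_NAMES}
        )
    raise ValueError(f"unsupported raster dimensionality: {data.ndim}")


# ---------------------------------------------------------------------------
# Network I/O (GeoJSON)


def write_network(network, path) -> None:
    """Write a ChannelNetwork as a GeoJSON FeatureCollection of LineStrings.

    Every feature carries ``length_m``, ``strahler_order`` and
    ``component_id``; coordinates are pixel centers in the world frame.
    Raises if any edge has no assigned Strahler order.
    """
    features = []
    for eid in sorted(network.edges):
        edge = network.edges[eid]
        if edge.strahler_order is None:
            raise ValueError("orders not assigned")
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in edge.points],
                },
                "properties": {
                    "edge_id": eid,
                    "length_m": edge.length,
                    "strahler_order": edge.strahler_order,
                    "component_id": edge.component_id,
                },
            }
        )
    collection = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"pixel_size": network.pixel_size},
    }
    Path(path).write_text(json.dumps(collection))


def read_network(path):
    """Re-read a GeoJSON network written by :func:`write_network`."""
    from tidechan.network_graph import ChannelNetwork, Edge

    data = json.loads(Path(path).read_text())
    pixel_size = float(data.get("properties", {}).get("pixel_size", 1.0))
    net = ChannelNetwork(pixel_size=pixel_size)
    node_ids: dict[tuple[float, float], int] = {}

    def _node(pt, role="junction"):
        key = (round(pt[0], 9), round(pt[1], 9))
        if key not in node_ids:
            node_ids[key] = net.add_node(pt[0], pt[1], role)
        return node_ids[key]

    for feat in data["features"]:
        coords = [tuple(map(float, p)) for p in feat["geometry"]["coordinates"]]
        props = feat["properties"]
        a = _node(coords[0])
        b = _node(coords[-1])
        net.add_edge(
            a,
            b,
            coords,
            strahler_order=props.get("strahler_order"),
            component_id=props.get("component_id", 0),
        )
    return net


# ---------------------------------------------------------------------------
# Metric table I/O

METRIC_COLUMNS = (
    "watershed_id",
    "location",
    "wetland_type",
    "area_m2",
    "total_length_m",
    "drainage_density_per_m",
    "mupl_m",
    "hortonian_length_m",
    "geometric_efficiency",
)


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, float):
        return format(value, ".12g")
    return str(value)


def write_metrics(records, path) -> None:
    """Write MetricRecords to CSV (floats at 12 significant digits)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METRIC_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.watershed_id,
                    rec.location,
                    rec.wetland_type,
                    _fmt(rec.area_m2),
                    _fmt(rec.total_length_m),
                    _fmt(rec.drainage_density),
                    _fmt(rec.mupl),
                    _fmt(rec.hortonian_length),
                    _fmt(rec.geometric_efficiency),
                ]
            )


def read_metrics(path):
    """Read a metrics CSV into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Config and logging


def load_config(path) -> dict:
    """Load a YAML config; top-level keys are module namespaces."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
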