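"""Ground-truthed synthetic wetlands: networks, masks, scenes, DEMs, scaling data.

Channel networks are grown as vector trees (grid-free) from outlets on the
seaward (bottom) raster edge and only then rasterized, so the returned
vector network is exact ground truth for lengths and Strahler orders. Each
outlet grows inside its own corridor of columns, which keeps trees from
different outlets disjoint on the raster.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tidechan.network_graph import ChannelNetwork, assign_strahler, rasterize_network
from tidechan.scene_io import BAND_NAMES, ChannelMask, RasterGrid, Scene

DEFAULT_SPECTRA = {
    # digital numbers (R, G, B, NIR) and noise sd; NDWI-separable
    "vegetation": ((90.0, 80.0, 60.0, 200.0), 5.0),
    "channel": ((60.0, 70.0, 80.0, 30.0), 5.0),
}


@dataclass
class SyntheticSpec:
    domain_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    n_outlets: int = 2
    branch_prob: float = 0.3
    segment_len: float = 20.0  # meters (mean)
    max_order: int = 4
    width_per_order: dict[int, int] = field(default_factory=lambda: {1: 1, 2: 2, 3: 3})
    spectra: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.n_outlets < 1:
            raise ValueError("n_outlets must be >= 1")
        if any(w < 1 for w in self.width_per_order.values()):
            raise ValueError("channel widths must be >= 1 pixel")

    def width_for_order(self, order: int) -> int:
        if order in self.width_per_order:
            return int(self.width_per_order[order])
        return int(max(self.width_per_order.values(), default=1))


def _reference_grid(spec: SyntheticSpec) -> RasterGrid:
    return RasterGrid(
        np.zeros(spec.domain_shape, dtype=np.uint8), spec.pixel_size, None, (0.0, 0.0)
    )


def generate_network(spec: SyntheticSpec):
    """Grow a branching channel network draining to the bottom edge.

    Returns ``(network, mask, ground_truth)`` where the network is the exact
    vector tree (lengths and Strahler orders are ground truth), the mask is
    its rasterization at order-dependent widths, and ``ground_truth`` is a
    per-edge table (edge_id, component_id, length_m, strahler_order).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.domain_shape
    ps = spec.pixel_size
    margin_px = 3
    min_corridor = 8
    if cols < spec.n_outlets * min_corridor or rows < 4 * margin_px:
        raise ValueError("domain too small to place outlets")

    ref = _reference_grid(spec)
    net = ChannelNetwork(ps)

    corridor_w = cols / spec.n_outlets
    x_max_world = cols * ps
    y_top = ref.pixel_to_world(margin_px, 0)[1]  # landward limit (high y)

    max_gen = max(4, int(math.ceil(3.0 * spec.max_order / max(spec.branch_prob, 0.1))))
    seg_cap = 60 * 2**spec.max_order

    # occupancy of centerline pixels; tips die before touching other branches
    # so the rasterized mask stays (nearly) a tree and skeleton ΣL matches truth
    occ = np.zeros(spec.domain_shape, dtype=bool)
    max_w = max(spec.width_per_order.values(), default=1)
    clear = 2 * (max_w // 2) + 2  # min centerline gap keeping dilated strokes apart
    start_ignore = clear + 3  # channels near a segment's own junction are connected anyway
    win = int(math.ceil(clear))

    def _line_pixels(x0, y0, x1, y1):
        r0, c0 = ref.world_to_pixel(x0, y0)
        r1, c1 = ref.world_to_pixel(x1, y1)
        from skimage.draw import line as draw_line

        rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        return rr[ok], cc[ok]

    def _truncate_at_collision(x0, y0, x1, y1):
        """Largest collision-free prefix of the segment (None = all of it)."""
        rr, cc = _line_pixels(x0, y0, x1, y1)
        for idx in range(len(rr)):
            r, c = int(rr[idx]), int(cc[idx])
            r_lo, c_lo = max(r - win, 0), max(c - win, 0)
            window = occ[r_lo : r + win + 1, c_lo : c + win + 1]
            if not window.any():
                continue
            orr, occ_cc = np.nonzero(window)
            orr, occ_cc = orr + r_lo, occ_cc + c_lo
            d_cand = np.hypot(orr - r, occ_cc - c)
            d_start = np.hypot(orr - float(rr[0]), occ_cc - float(cc[0]))
            if np.any((d_cand <= clear) & (d_start > start_ignore)):
                keep = max(idx - win, 1)
                frac = keep / max(len(rr) - 1, 1)
                return x0 + frac * (x1 - x0), y0 + frac * (y1 - y0)
        return None

    for i in range(spec.n_outlets):
        x_lo = (i * corridor_w + margin_px) * ps
        x_hi = ((i + 1) * corridor_w - margin_px) * ps
        out_col = int((i + 0.5) * corridor_w)
        out_x, out_y = ref.pixel_to_world(rows - 1, out_col)
        root = net.add_node(out_x, out_y, role="outlet")
        # tips: (node_id, x, y, heading, generation)
        tips = [(root, float(out_x), float(out_y), math.pi / 2, 0)]
        n_segments = 0
        while tips and n_segments < seg_cap:
            nid, x, y, heading, gen = tips.pop(0)
            if gen > max_gen:
                continue
            length = spec.segment_len * rng.uniform(0.7, 1.3)
            heading = 0.6 * heading + 0.4 * (math.pi / 2) + rng.normal(0.0, 0.25)
            nx_, ny_ = x + length * math.cos(heading), y + length * math.sin(heading)
            alive = True
            # truncate at the corridor / landward boundary and stop the tip
            if not (x_lo <= nx_ <= x_hi) or ny_ > y_top:
                t = 1.0
                if nx_ != x:
                    if nx_ < x_lo:
                        t = min(t, (x_lo - x) / (nx_ - x))
                    if nx_ > x_hi:
                        t = min(t, (x_hi - x) / (nx_ - x))
                if ny_ > y_top and ny_ != y:
                    t = min(t, (y_top - y) / (ny_ - y))
                t = max(t, 0.0)
                nx_, ny_ = x + t * (nx_ - x), y + t * (ny_ - y)
                alive = False
            clipped = _truncate_at_collision(x, y, nx_, ny_)
            if clipped is not None:
                nx_, ny_ = clipped
                alive = False
            if math.hypot(nx_ - x, ny_ - y) < 0.5 * ps:
                continue
            child = net.add_node(nx_, ny_, role="endpoint")
            net.add_edge(nid, child, [(x, y), (nx_, ny_)], component_id=i + 1)
            rr, cc = _line_pixels(x, y, nx_, ny_)
            occ[rr, cc] = True
            n_segments += 1
            if not alive:
                continue
            if rng.random() < spec.branch_prob and gen < max_gen:
                spread = rng.uniform(0.35, 0.6)
                tips.append((child, nx_, ny_, heading + spread, gen + 1))
                tips.append((child, nx_, ny_, heading - spread, gen + 1))
            else:
                tips.append((child, nx_, ny_, heading, gen + 1))

    # fix node roles: interior nodes are junctions, leaves endpoints
    inc = net.incident()
    for nid, node in net.nodes.items():
        if node.role == "outlet":
            continue
        node.role = "endpoint" if len(inc[nid]) <= 1 else "junction"

    assign_strahler(net)

    widths = {
        o: spec.width_for_order(o) for o in range(1, max(net.max_order(), 1) + 1)
    }
    chan = rasterize_network(net, ref, widths)
    wetland = np.ones(spec.domain_shape, dtype=np.uint8)
    mask = ChannelMask(
        RasterGrid(chan.astype(np.uint8), ps, None, (0.0, 0.0)),
        RasterGrid(wetland, ps, None, (0.0, 0.0)),
    )

    truth = pd.DataFrame(
        {
            "edge_id": sorted(net.edges),
            "component_id": [net.edges[e].component_id for e in sorted(net.edges)],
            "length_m": [net.edges[e].length for e in sorted(net.edges)],
            "strahler_order": [net.edges[e].strahler_order for e in sorted(net.edges)],
        }
    )
    return net, mask, truth


def generate_fractal_network(
    levels: int = 9,
    domain_shape: tuple[int, int] = (700, 900),
    pixel_size: float = 1.0,
    shrink: float = 0.62,
    branch_angle_deg: float = 40.0,
    width_per_order: dict[int, int] | None = None,
):
    """Deterministic self-similar binary tree draining to the bottom edge.

    A vertical trunk splits into two branches rotated ``+-branch_angle_deg``
    from the parent heading, with lengths shrinking by ``shrink`` per
    generation, for ``levels`` generations. Every junction joins two equal
    Strahler orders, so a generation-g segment has order ``levels - g``
    exactly and total length per order decays geometrically (ratio
    ``1 / (2 * shrink)``), making the order-removal curve of the correction
    procedure exponential by construction. Returns
    ``(network, mask, ground_truth)`` like :func:`generate_network`.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not 0 < shrink < 1:
        raise ValueError("shrink must be in (0, 1)")
    rows, cols = domain_shape
    ps = pixel_size
    ref = _reference_grid(SyntheticSpec(domain_shape=domain_shape, pixel_size=ps))
    margin = 4 * ps
    # conservative bound on the canopy radius from the trunk tip
    l0 = (rows * ps - 2 * margin) / (1.0 + shrink / (1.0 - shrink))
    theta = math.radians(branch_angle_deg)

    net = ChannelNetwork(ps)
    x_root, y_root = ref.pixel_to_world(rows - 1, cols // 2)
    root = net.add_node(x_root, y_root, role="outlet")

    def grow(nid, x, y, heading, gen):
        length = l0 * shrink**gen
        nx_, ny_ = x + length * math.cos(heading), y + length * math.sin(heading)
        child = net.add_node(nx_, ny_, role="endpoint")
        net.add_edge(nid, child, [(x, y), (nx_, ny_)], component_id=1)
        if gen + 1 < levels:
            grow(child, nx_, ny_, heading + theta, gen + 1)
            grow(child, nx_, ny_, heading - theta, gen + 1)

    grow(root, x_root, y_root, math.pi / 2, 0)

    inc = net.incident()
    for nid, node in net.nodes.items():
        if node.role != "outlet":
            node.role = "endpoint" if len(inc[nid]) <= 1 else "junction"
    assign_strahler(net)

    if width_per_order is None:
        width_per_order = {o: min(o, 3) for o in range(1, net.max_order() + 1)}
    chan = rasterize_network(net, ref, dict(width_per_order))
    mask = ChannelMask(
        RasterGrid(chan.astype(np.uint8), ps, None, (0.0, 0.0)),
        RasterGrid(np.ones(domain_shape, dtype=np.uint8), ps, None, (0.0, 0.0)),
    )
    truth = pd.DataFrame(
        {
            "edge_id": sorted(net.edges),
            "component_id": [net.edges[e].component_id for e in sorted(net.edges)],
            "length_m": [net.edges[e].length for e in sorted(net.edges)],
            "strahler_order": [net.edges[e].strahler_order for e in sorted(net.edges)],
        }
    )
    return net, mask, truth


def generate_scene(mask: ChannelMask, spec: SyntheticSpec) -> Scene:
    """Render a 4-band scene from a channel mask using the spec's spectra."""
    for cls in ("vegetation", "channel"):
        if cls not in spec.spectra:
            raise ValueError(f"spectra for class {cls!r} not defined")
    rng = np.random.default_rng([spec.seed, 17])
    chan = mask.channel
    shape = chan.shape
    bands = {}
    veg_mean, veg_sd = spec.spectra["vegetation"]
    chan_mean, chan_sd = spec.spectra["channel"]
    for bi, name in enumerate(BAND_NAMES):
        vals = np.where(chan, float(chan_mean[bi]), float(veg_mean[bi]))
        sd = np.where(chan, float(chan_sd), float(veg_sd))
        vals = vals + rng.normal(0.0, 1.0, shape) * sd
        bands[name] = RasterGrid(
            vals, mask.pixel_size, None, mask.grid.origin
        )
    return Scene(bands)


def generate_dem(
    mask: ChannelMask,
    platform_z: float = 1.0,
    channel_depth: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RasterGrid:
    """Channelized DEM: platform at ``platform_z``, channels incised by
    ``channel_depth``, plus Gaussian elevation noise."""
    if not channel_depth > 0:
        raise ValueError("channel_depth must be > 0")
    rng = np.random.default_rng([seed, 29])
    chan = mask.channel
    z = np.where(chan, platform_z - channel_depth, platform_z).astype(float)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, chan.shape)
    return RasterGrid(z, mask.pixel_size, None, mask.grid.origin)


def generate_scaling_dataset(
    a: float,
    b: float,
    n: int,
    area_range: tuple[float, float] = (1e3, 1e7),
    log_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(Area, total length) samples on a power law with lognormal scatter.

    Areas are log-uniform on ``area_range``; lengths follow
    ``a * Area**b * exp(eps)`` with ``eps ~ N(0, log_noise_sd**2)``.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    lo, hi = area_range
    if not (lo > 0 and hi > 0):
        raise ValueError("areas must be > 0")
    rng = np.random.default_rng([seed, 41])
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    eps = rng.normal(0.0, log_noise_sd, n) if log_noise_sd > 0 else np.zeros(n)
    lengths = a * areas**b * np.exp(eps)
    return pd.DataFrame({"area_m2": areas, "total_length_m": lengths})
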