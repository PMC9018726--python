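"""Order-removal correction of satellite-derived channel metrics.

Coarse imagery misses low-order channels. The correction (1) takes a
high-resolution (DEM-derived) network, (2) successively removes channels of
Strahler order 1..5 and recomputes the wetland-wide metric after each
removal, and (3) fits metric = alpha * exp(beta * r) against the removed
order r. A satellite metric is then corrected by locating the effective
removed order r* at which the fitted curve matches the observation and
restoring the r = 0 level:

    r* = ln(value / alpha) / beta, clamped to [0, 5]
    corrected = value * alpha / (alpha * exp(beta * r*))

which equals alpha exactly when the observation sits on the curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from tidechan.network_graph import ChannelNetwork, prune_orders, rasterize_network, total_length
from tidechan.scene_io import ChannelMask, RasterGrid
from tidechan.watershed_metrics import unchanneled_distance

logger = logging.getLogger("tidechan")

MAX_REMOVED_ORDER = 5


@dataclass
class OrderRemovalCurve:
    metric_name: str  # "D" | "mUpl"
    wetland_type: str
    points: dict[int, float] = field(default_factory=dict)  # removed order -> value


@dataclass
class CorrectionModel:
    metric_name: str
    wetland_type: str
    alpha: float  # level at r = 0
    beta: float  # exponential rate per removed order
    fit_r2: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")

    def __call__(self, r: float) -> float:
        return self.alpha * math.exp(self.beta * r)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "metric": self.metric_name,
                    "type": self.wetland_type,
                    "alpha": float(self.alpha),
                    "beta": float(self.beta),
                    "r2": float(self.fit_r2),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["metric"], d["type"], d["alpha"], d["beta"], d.get("r2", float("nan")))


def _wetland_metric(
    network: ChannelNetwork, wetland: RasterGrid, metric_name: str
) -> float:
    """Wetland-wide D or mUpl for a (possibly pruned) network.

    The network is re-rasterized at 1-pixel width so that mUpl responds to
    pruning; D uses the exact vector lengths.
    """
    aoi = wetland.values.astype(bool)
    ps = wetland.pixel_size
    if metric_name == "D":
        return total_length(network) / (float(aoi.sum()) * ps * ps)
    if metric_name == "mUpl":
        chan = rasterize_network(network, wetland, 1) & aoi
        if not chan.any():
            raise ValueError("pruned network has no channel pixels inside the AOI")
        mask = ChannelMask(
            RasterGrid(chan.astype(np.uint8), ps, None, wetland.origin),
            RasterGrid(aoi.astype(np.uint8), ps, None, wetland.origin),
        )
        dist = unchanneled_distance(mask)
        platform = aoi & ~chan
        return float(np.nanmean(dist.values[platform]))
    raise ValueError(f"unknown metric: {metric_name}")


def order_removal_curve(
    dem_network: ChannelNetwork,
    wetland: RasterGrid,
    metric_name: str,
    wetland_type: str = "",
) -> OrderRemovalCurve:
    """Metric value after removing channels of order <= r, for r = 0..min(5,
    max_order - 1)."""
    max_order = dem_network.max_order()
    if max_order < 1:
        raise ValueError("network has no assigned orders")
    if max_order < 2:
        logger.warning("max order 1: order-removal curve has only the r = 0 point")
    curve = OrderRemovalCurve(metric_name, wetland_type)
    for r in range(0, min(MAX_REMOVED_ORDER, max_order - 1) + 1):
        pruned = prune_orders(dem_network, r)
        curve.points[r] = _wetland_metric(pruned, wetland, metric_name)
    return curve


def fit_exponential(curve: OrderRemovalCurve) -> CorrectionModel:
    """OLS of ln(metric) on removed order; alpha = exp(intercept), beta = slope."""
    rs = np.array(sorted(curve.points), dtype=float)
    vals = np.array([curve.points[int(r)] for r in rs], dtype=float)
    if len(rs) < 3:
        raise ValueError("need >= 3 points to fit the exponential")
    bad = np.nonzero(vals <= 0)[0]
    if len(bad):
        raise ValueError(
            f"non-positive metric value at removed order r={int(rs[bad[0]])}"
        )
    y = np.log(vals)
    slope, intercept = np.polyfit(rs, y, 1)
    resid = y - (intercept + slope * rs)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CorrectionModel(
        curve.metric_name, curve.wetland_type, math.exp(intercept), float(slope), r2
    )


def apply_correction(satellite_value: float, model: CorrectionModel) -> float:
    """Correct a satellite metric back to the full-resolution (r = 0) level.

    Solves model(r*) = satellite_value for the effective removed order r*,
    clamps it to [0, 5], and rescales by alpha / model(r*); r* = 0 returns
    the value unchanged.
    """
    if not satellite_value > 0:
        raise ValueError("satellite_value must be > 0")
    if model.beta == 0:
        logger.warning("beta = 0: correction is the identity")
        return float(satellite_value)
    r_star = math.log(satellite_value / model.alpha) / model.beta
    r_star = min(max(r_star, 0.0), float(MAX_REMOVED_ORDER))
    if r_star == 0.0:
        return float(satellite_value)
    return float(satellite_value) * model.alpha / model(r_star)
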