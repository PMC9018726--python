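"""Binary channel-mask extraction from multispectral scenes or DEMs.

The spectral route is an unsupervised Gaussian maximum-likelihood
clustering of the 4-band vectors (k-means seeded, full per-class
covariances), after which classes whose mean NDWI = (G - NIR) / (G + NIR)
exceeds a threshold are reclassified as channel. A manual class map can
override the NDWI rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from tidechan.scene_io import ChannelMask, RasterGrid, Scene

logger = logging.getLogger("tidechan")

_FOUR = ndimage.generate_binary_structure(2, 1)
_EIGHT = ndimage.generate_binary_structure(2, 2)

NODATA_LABEL = -1


@dataclass
class ClassRaster:
    """Integer class labels over the wetland AOI plus per-class statistics."""

    grid: RasterGrid  # labels 0..k-1 inside the AOI, NODATA_LABEL outside
    k: int
    class_means: np.ndarray  # (k, 4)
    class_covs: np.ndarray  # (k, 4, 4)

    @property
    def labels(self) -> np.ndarray:
        return self.grid.values

    @property
    def aoi(self) -> np.ndarray:
        return self.grid.values != NODATA_LABEL


def _class_log_likelihood(X: np.ndarray, mean: np.ndarray, cov: np.ndarray, ridge: float):
    """Gaussian log-density, ridge-regularizing a singular covariance."""
    d = X.shape[1]
    for attempt in range(2):
        try:
            chol = np.linalg.cholesky(cov)
            break
        except np.linalg.LinAlgError:
            if attempt == 1:
                raise
            logger.warning("singular class covariance; adding ridge %.3g", ridge)
            cov = cov + ridge * np.eye(d)
    diff = X - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))


def classify_scene(
    scene: Scene,
    wetland: RasterGrid,
    k: int = 10,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
) -> ClassRaster:
    """Unsupervised Gaussian maximum-likelihood clustering of band vectors.

    Initialized with seeded k-means, then alternates maximum-likelihood
    assignment (full per-class covariance, equal priors) with mean /
    covariance re-estimation until fewer than ``tol`` of the in-AOI pixels
    change label. Deterministic given ``seed``. Pixels outside the AOI are
    never labeled.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    aoi = wetland.values.astype(bool)
    X = scene.stack()[aoi]
    n, d = X.shape
    if n < k:
        raise ValueError("wetland must contain at least k pixels")

    km = KMeans(n_clusters=k, n_init=4, random_state=int(seed)).fit(X)
    labels = km.labels_.astype(int)
    ridge = 1e-6 * float(np.mean(np.var(X, axis=0)))

    means = np.zeros((k, d))
    covs = np.zeros((k, d, d))
    for it in range(max_iter):
        loglik = np.full((n, k), -np.inf)
        for c in range(k):
            members = X[labels == c]
            if len(members) == 0:
                continue
            means[c] = members.mean(axis=0)
            cov = np.cov(members.T) if len(members) > 1 else np.eye(d) * ridge
            cov = np.atleast_2d(cov) + ridge * np.eye(d)
            covs[c] = cov
            loglik[:, c] = _class_log_likelihood(X, means[c], cov, ridge)
        new_labels = np.argmax(loglik, axis=1)

        # re-seed empty classes from the worst-explained pixel
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(np.max(loglik, axis=1)))
                new_labels[worst] = c
                loglik[worst] = -np.inf

        changed = float(np.mean(new_labels != labels))
        labels = new_labels
        if changed < tol:
            break

    # final statistics on converged labels
    for c in range(k):
        members = X[labels == c]
        if len(members):
            means[c] = members.mean(axis=0)
            cov = np.cov(members.T) if len(members) > 1 else np.eye(d) * ridge
            covs[c] = np.atleast_2d(cov) + ridge * np.eye(d)

    label_grid = np.full(aoi.shape, NODATA_LABEL, dtype=int)
    label_grid[aoi] = labels
    grid = RasterGrid(label_grid, scene.pixel_size, NODATA_LABEL, scene.origin)
    return ClassRaster(grid, k, means, covs)


def to_channel_mask(
    classes: ClassRaster,
    scene: Scene,
    ndwi_threshold: float = 0.0,
    manual_map: dict[int, str] | None = None,
) -> ChannelMask:
    """Reclassify clusters to a binary channel mask.

    Without ``manual_map``, a class is channel when its mean NDWI over
    member pixels exceeds ``ndwi_threshold``. ``manual_map`` maps class
    label -> "channel" | "wetland" and overrides the NDWI rule entirely.
    """
    if classes.grid.shape != scene.shape:
        raise ValueError("classes and scene must share the grid")
    labels = classes.labels
    aoi = classes.aoi
    if manual_map is not None:
        channel_classes = {c for c, v in manual_map.items() if v == "channel"}
    else:
        g = scene.bands["G"].values.astype(float)
        nir = scene.bands["NIR"].values.astype(float)
        channel_classes = set()
        for c in range(classes.k):
            member = labels == c
            if not member.any():
                continue
            gm, nm = g[member].mean(), nir[member].mean()
            ndwi = (gm - nm) / (gm + nm) if (gm + nm) != 0 else 0.0
            if ndwi > ndwi_threshold:
                channel_classes.add(c)
        if not channel_classes:
            logger.warning("no class exceeded the NDWI threshold; all-platform mask")
        elif channel_classes == set(np.unique(labels[aoi])):
            logger.warning("all classes exceeded the NDWI threshold; all-channel mask")

    chan = np.isin(labels, sorted(channel_classes)) & aoi
    ps = classes.grid.pixel_size
    return ChannelMask(
        RasterGrid(chan.astype(np.uint8), ps, None, classes.grid.origin),
        RasterGrid(aoi.astype(np.uint8), ps, None, classes.grid.origin),
    )


def dem_to_mask(
    dem: RasterGrid, wetland: RasterGrid, window: int = 15, depth: float = 0.5
) -> ChannelMask:
    """Channel where the DEM sits more than ``depth`` below the local
    moving median over a ``window x window`` neighborhood."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if not depth > 0:
        raise ValueError("depth must be > 0")
    if window > min(dem.shape):
        raise ValueError("window larger than grid")
    med = ndimage.median_filter(dem.values.astype(float), size=window, mode="nearest")
    aoi = wetland.values.astype(bool)
    chan = (dem.values < med - depth) & aoi
    return ChannelMask(
        RasterGrid(chan.astype(np.uint8), dem.pixel_size, None, dem.origin),
        RasterGrid(aoi.astype(np.uint8), dem.pixel_size, None, dem.origin),
    )


def clean_mask(
    mask: ChannelMask, min_component: int = 5, max_hole: int = 5
) -> ChannelMask:
    """Drop 8-connected channel specks below ``min_component`` pixels and
    fill fully channel-enclosed 4-connected platform holes below
    ``max_hole`` pixels. Idempotent."""
    chan = mask.channel.copy()
    aoi = mask.aoi

    lbl, n = ndimage.label(chan, structure=_EIGHT)
    if n:
        sizes = np.bincount(lbl.ravel())
        small = np.nonzero(sizes < min_component)[0]
        small = small[small != 0]
        if len(small):
            chan[np.isin(lbl, small)] = False

    holes, nh = ndimage.label(~chan, structure=_FOUR)
    if nh:
        sizes = np.bincount(holes.ravel())
        border = set(np.unique(holes[0, :])) | set(np.unique(holes[-1, :]))
        border |= set(np.unique(holes[:, 0])) | set(np.unique(holes[:, -1]))
        for h in range(1, nh + 1):
            if h in border or sizes[h] >= max_hole:
                continue
            chan[holes == h] = True

    chan &= aoi
    ps = mask.pixel_size
    return ChannelMask(
        RasterGrid(chan.astype(np.uint8), ps, None, mask.grid.origin),
        RasterGrid(aoi.astype(np.uint8), ps, None, mask.grid.origin),
    )
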