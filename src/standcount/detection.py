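"""Spectral local-maximum detection and NDVI-based pseudo-point removal.

The detector computes a moving-window maximum (clipped at the raster
borders), subtracts it from the original band and keeps pixels where the
difference is zero; 4-connected plateaus of such pixels collapse to one
point at the plateau's centroid pixel. Detected points carry the NDVI value
of the multispectral pixel containing them, and points below a configurable
NDVI threshold are discarded as pseudo crown points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, RasterGridError

DEFAULT_WINDOW_SIZES = (3, 5, 7, 9, 11)
DEFAULT_NDVI_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


class WindowSizeError(ValueError):
    pass


class NdviLookupError(ValueError):
    pass


@dataclass
class DetectionParams:
    band: str = "PAN"
    window_size: int = 3
    ndvi_threshold: float | None = 0.3

    def __post_init__(self) -> None:
        self.band = self.band.upper()
        if self.band not in ("PAN", "NIR"):
            raise ValueError(f"detection band must be PAN or NIR, got {self.band!r}")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise WindowSizeError(f"window_size must be odd and >= 3, got {self.window_size}")
        if self.ndvi_threshold is not None and not -1 <= self.ndvi_threshold <= 1:
            raise ValueError("ndvi_threshold must be in [-1, 1] or None")


@dataclass
class LMPoint:
    x: float
    y: float
    value: float
    ndvi: float | None = None


@dataclass
class LMPointSet:
    points: list[LMPoint]
    source_band: str | None = None
    window_size: int | None = None
    ndvi_threshold_applied: float | None = None

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def xs(self) -> np.ndarray:
        return np.array([p.x for p in self.points], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.array([p.y for p in self.points], dtype=float)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.xs,
                "y": self.ys,
                "value": [p.value for p in self.points],
                "ndvi": [p.ndvi for p in self.points],
            }
        )


def compute_ndvi(red: Raster, nir: Raster) -> Raster:
    """(NIR - red) / (NIR + red), 0 where the denominator is 0."""
    if not red.same_grid(nir):
        raise RasterGridError(
            f"red {red.shape}@{red.pixel_size} and nir {nir.shape}@{nir.pixel_size} "
            "must share one grid"
        )
    r = red.data.astype(np.float64)
    n = nir.data.astype(np.float64)
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom == 0, 0.0, (n - r) / np.where(denom == 0, 1.0, denom))
    return Raster(ndvi, origin=red.origin, pixel_size=red.pixel_size)


def local_maxima(raster: Raster, window_size: int) -> LMPointSet:
    """Filter-subtract-zero local maxima with plateau collapse.

    The w x w maximum window is clipped at the raster borders. Zero-difference
    pixels that are 4-connected (necessarily equal-valued for w >= 3) form one
    plateau and yield a single point at the centroid pixel's centre.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise WindowSizeError(f"window_size must be odd and >= 3, got {window_size}")
    if window_size > min(raster.shape):
        raise WindowSizeError(
            f"window_size {window_size} exceeds raster dimension {min(raster.shape)}"
        )
    data = raster.data.astype(np.float64)
    win_max = ndimage.maximum_filter(data, size=window_size, mode="constant", cval=-np.inf)
    mask = data == win_max  # filter-subtract: difference zero
    labels, n_comp = ndimage.label(mask, structure=_FOUR_CONN)
    points: list[LMPoint] = []
    if n_comp:
        coords = np.argwhere(mask)
        labs = labels[mask]
        order = np.argsort(labs, kind="stable")
        coords = coords[order]
        labs = labs[order]
        bounds = np.searchsorted(labs, np.arange(1, n_comp + 2))
        start = 0
        for end in bounds:
            sub = coords[start:end]
            start = end
            if sub.size == 0:
                continue
            centroid = sub.mean(axis=0)
            # centroid pixel = component pixel nearest the centroid (a ring
            # plateau's raw centroid can fall off the component); ties break
            # deterministically by (row, col)
            d2 = ((sub - centroid) ** 2).sum(axis=1)
            idx = np.lexsort((sub[:, 1], sub[:, 0], d2))[0]
            row, col = int(sub[idx, 0]), int(sub[idx, 1])
            x, y = raster.center_of(row, col)
            points.append(LMPoint(x=x, y=y, value=float(data[row, col])))
    points.sort(key=lambda p: (p.y, p.x))
    return LMPointSet(points=points, window_size=window_size)


def filter_by_ndvi(points: LMPointSet, ndvi: Raster, threshold: float | None) -> LMPointSet:
    """Annotate points with NDVI (nearest pixel across grids) and drop those
    below the threshold; ``threshold=None`` annotates only."""
    nrows, ncols = ndvi.shape
    kept: list[LMPoint] = []
    for p in points:
        row, col = ndvi.pixel_of(p.x, p.y)
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise NdviLookupError(
                f"point ({p.x}, {p.y}) falls outside the NDVI raster {ndvi.bounds}"
            )
        value = float(ndvi.data[row, col])
        annotated = LMPoint(x=p.x, y=p.y, value=p.value, ndvi=value)
        if threshold is None or value >= threshold:
            kept.append(annotated)
    return LMPointSet(
        points=kept,
        source_band=points.source_band,
        window_size=points.window_size,
        ndvi_threshold_applied=threshold,
    )


def detect(scene, params: DetectionParams) -> LMPointSet:
    """Compose band selection, local-maxima extraction and NDVI filtering."""
    band = scene.band(params.band)
    pts = local_maxima(band, params.window_size)
    pts.source_band = params.band
    ndvi = compute_ndvi(scene.red, scene.nir)
    return filter_by_ndvi(pts, ndvi, params.ndvi_threshold)
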