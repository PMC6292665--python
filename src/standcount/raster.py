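"""Minimal single-band georeferenced raster container with GeoTIFF I/O.

The scene frame is an image frame in metres: x grows with column, y grows
with row, pixel (0, 0) is the top-left corner of the raster and a point's
pixel is found by ``floor((coord - origin) / pixel_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class RasterGridError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass
class Raster:
    """A 2-D grid of values with an origin (top-left corner) and pixel size.

    Parameters
    ----------
    data : ndarray
        2-D array; row 0 is the top of the scene.
    origin : tuple of float
        ``(x0, y0)`` scene-frame coordinates of the raster's top-left corner.
    pixel_size : float
        Side length of a (square) pixel in metres.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got {self.data.ndim}-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in scene metres."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.pixel_size, y0 + nrows * self.pixel_size)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.origin == other.origin
            and self.pixel_size == other.pixel_size
        )

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing scene point (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.pixel_size))
        row = int(np.floor((y - self.origin[1]) / self.pixel_size))
        return row, col

    def pixels_of(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = np.floor((np.asarray(xs) - self.origin[0]) / self.pixel_size).astype(int)
        rows = np.floor((np.asarray(ys) - self.origin[1]) / self.pixel_size).astype(int)
        return rows, cols

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """Scene coordinates of a pixel centre."""
        x = self.origin[0] + (col + 0.5) * self.pixel_size
        y = self.origin[1] + (row + 0.5) * self.pixel_size
        return x, y

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmin <= x < xmax) and (ymin <= y < ymax)

    def value_at(self, x: float, y: float) -> float:
        row, col = self.pixel_of(x, y)
        nrows, ncols = self.data.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise IndexError(f"point ({x}, {y}) outside raster bounds {self.bounds}")
        return float(self.data[row, col])

    # -- I/O --------------------------------------------------------------

    def write_geotiff(self, path) -> None:
        data = self.data
        if data.dtype.kind == "f" and data.dtype.itemsize > 4:
            data = data.astype(np.float32)
        ps = float(self.pixel_size)
        extratags = [
            (_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.origin[0], self.origin[1], 0.0)),
        ]
        tifffile.imwrite(str(path), data, extratags=extratags)

    @classmethod
    def read_geotiff(cls, path) -> "Raster":
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            data = page.asarray()
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tiepoint = page.tags[_MODEL_TIEPOINT].value
        return cls(data=data, origin=(tiepoint[3], tiepoint[4]), pixel_size=scale[0])


def block_mean(data: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a 2-D array by non-overlapping ``factor x factor`` means."""
    nrows, ncols = data.shape
    if nrows % factor or ncols % factor:
        raise ValueError(f"shape {data.shape} not divisible by block factor {factor}")
    return data.reshape(nrows // factor, factor, ncols // factor, factor).mean(axis=(1, 3))
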