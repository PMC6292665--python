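"""Wall-to-wall stand-density mapping on a fishnet grid.

Detected points are binned into a regular square-cell grid (default 20 m),
a calibrated per-stratum model converts each cell's count to trees per
400 m^2 and then to trees/ha; ragged edge cells are area-normalized rather
than dropped, and negative model predictions are floored at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DensityModel
from .detection import LMPointSet
from .raster import Raster
from .synthetic_scene import UNCLASSIFIED

REFERENCE_PLOT_AREA_M2 = 400.0
HA_M2 = 10000.0


class PointOutsideExtentError(ValueError):
    pass


class MissingModelError(KeyError):
    pass


@dataclass
class Fishnet:
    """Axis-aligned grid of square cells anchored at the extent origin.

    The last row/column may be ragged; those cells keep their true smaller
    area so densities stay comparable.
    """

    origin: tuple[float, float]
    cell_size_m: float
    extent: tuple[float, float]  # (width, height) in metres
    counts: np.ndarray | None = None
    predicted_per_ha: np.ndarray | None = None
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")

    @property
    def n_cols(self) -> int:
        return math.ceil(self.extent[0] / self.cell_size_m - 1e-12)

    @property
    def n_rows(self) -> int:
        return math.ceil(self.extent[1] / self.cell_size_m - 1e-12)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_widths(self) -> np.ndarray:
        cs, w = self.cell_size_m, self.extent[0]
        edges = np.arange(self.n_cols) * cs
        return np.minimum(cs, w - edges)

    def cell_heights(self) -> np.ndarray:
        cs, h = self.cell_size_m, self.extent[1]
        edges = np.arange(self.n_rows) * cs
        return np.minimum(cs, h - edges)

    def cell_areas(self) -> np.ndarray:
        return np.outer(self.cell_heights(), self.cell_widths())

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.origin[0] + col * self.cell_size_m
        y0 = self.origin[1] + row * self.cell_size_m
        return (x0, y0, x0 + self.cell_widths()[col], y0 + self.cell_heights()[row])

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        areas = self.cell_areas()
        data = {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "area_m2": areas.ravel(),
        }
        if self.counts is not None:
            data["count"] = self.counts.ravel()
        if self.predicted_per_ha is not None:
            data["density_per_ha"] = self.predicted_per_ha.ravel()
        if self.strata is not None:
            data["stratum"] = self.strata.ravel()
        return pd.DataFrame(data)

    def to_geojson(self) -> str:
        features = []
        areas = self.cell_areas()
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                x0, y0, x1, y1 = self.cell_bounds(row, col)
                props = {"row": row, "col": col, "area_m2": float(areas[row, col])}
                if self.counts is not None:
                    props["count"] = int(self.counts[row, col])
                if self.predicted_per_ha is not None:
                    props["density_per_ha"] = float(self.predicted_per_ha[row, col])
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {
                            "type": "Polygon",
                            "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
                        },
                        "properties": props,
                    }
                )
        return json.dumps({"type": "FeatureCollection", "features": features})


def build_fishnet(extent: tuple[float, float], cell_size_m: float = 20.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> Fishnet:
    """Grid anchored at the origin covering (width, height); ragged last
    row/column cells are retained with their true area."""
    return Fishnet(origin=origin, cell_size_m=cell_size_m, extent=extent)


def count_per_cell(points: LMPointSet, fishnet: Fishnet) -> Fishnet:
    """Half-open binning by floor division; errors on out-of-extent points."""
    counts = np.zeros(fishnet.shape, dtype=int)
    x0, y0 = fishnet.origin
    w, h = fishnet.extent
    cs = fishnet.cell_size_m
    for p in points:
        if not (x0 <= p.x < x0 + w and y0 <= p.y < y0 + h):
            raise PointOutsideExtentError(
                f"point ({p.x}, {p.y}) lies outside the fishnet extent "
                f"[{x0}, {x0 + w}) x [{y0}, {y0 + h})"
            )
        col = int((p.x - x0) // cs)
        row = int((p.y - y0) // cs)
        counts[row, col] += 1
    fishnet.counts = counts
    return fishnet


def predict_density(
    fishnet: Fishnet,
    models: dict[str, DensityModel],
    stratum_mask: np.ndarray | None = None,
) -> tuple[Fishnet, Raster]:
    """Apply per-stratum models to cell counts and emit a density raster.

    Counts are scaled to a 400 m^2 equivalent before prediction (models
    operate in trees per 400 m^2); predictions convert to trees/ha and are
    floored at 0. Without a stratum mask the unclassified model applies
    everywhere.
    """
    if fishnet.counts is None:
        raise ValueError("fishnet has no counts; run count_per_cell first")
    if stratum_mask is None:
        strata = np.full(fishnet.shape, UNCLASSIFIED, dtype=object)
    else:
        strata = np.asarray(stratum_mask, dtype=object)
        if strata.shape != fishnet.shape:
            raise ValueError(
                f"stratum mask shape {strata.shape} != fishnet shape {fishnet.shape}"
            )
    for stratum in np.unique(strata.astype(str)):
        if stratum not in models:
            raise MissingModelError(
                f"no density model configured for stratum {stratum!r}"
            )

    areas = fishnet.cell_areas()
    scaled = fishnet.counts * (REFERENCE_PLOT_AREA_M2 / areas)
    predicted_plot = np.zeros(fishnet.shape, dtype=float)
    for stratum in np.unique(strata.astype(str)):
        mask = strata.astype(str) == stratum
        predicted_plot[mask] = models[stratum].predict(scaled[mask])
    per_ha = np.maximum(predicted_plot, 0.0) * (HA_M2 / REFERENCE_PLOT_AREA_M2)
    fishnet.predicted_per_ha = per_ha
    fishnet.strata = strata
    raster = Raster(per_ha.astype(np.float32), origin=fishnet.origin,
                    pixel_size=fishnet.cell_size_m)
    return fishnet, raster
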