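"""Per-plot point counting, plot stratification and density unit conversion."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detection import DetectionParams, LMPointSet, detect, filter_by_ndvi, local_maxima, compute_ndvi
from .synthetic_scene import BROADLEAF, CONIFEROUS, UNCLASSIFIED, Scene, TreeRecord

PURE_STAND_FRACTION = 0.70  # strict "exceeds seventy percent" rule


class StratificationError(ValueError):
    pass


@dataclass
class PlotObservation:
    """One plot's true count (NT) and detected count (N', the NSLMP)."""

    plot_id: str
    stratum: str
    nt: int
    n_prime: int
    area_m2: float = 400.0

    @property
    def nt_per_ha(self) -> float:
        return to_trees_per_ha(self.nt, self.area_m2)

    @property
    def n_prime_per_ha(self) -> float:
        return to_trees_per_ha(self.n_prime, self.area_m2)


def count_points_in_plot(points: LMPointSet, polygon) -> int:
    """Half-open point-in-square count: xmin <= x < xmax, ymin <= y < ymax."""
    xmin, ymin, xmax, ymax = polygon.bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("plot polygon has zero area")
    count = 0
    for p in points:
        if xmin <= p.x < xmax and ymin <= p.y < ymax:
            count += 1
    return count


def stratify_plot(trees_in_plot: list[TreeRecord]) -> str:
    """Pure-stand rule: a stratum owning strictly more than 70% of the live
    trees wins; otherwise the plot is unclassified only. (Every plot belongs
    to the unclassified pool in addition to any pure label.)"""
    live = [t for t in trees_in_plot if t.alive]
    if not live:
        raise StratificationError("cannot stratify a plot with no live trees")
    n = len(live)
    broad = sum(1 for t in live if t.stratum == BROADLEAF)
    if broad / n > PURE_STAND_FRACTION:
        return BROADLEAF
    if (n - broad) / n > PURE_STAND_FRACTION:
        return CONIFEROUS
    return UNCLASSIFIED


def to_trees_per_ha(count: float, area_m2: float) -> float:
    """count x 10000 / area; e.g. 27 trees / 400 m^2 -> 675 trees/ha."""
    if area_m2 <= 0:
        raise ValueError(f"plot area must be positive, got {area_m2}")
    return count * 10000.0 / area_m2


def build_observation_table(scene: Scene, detect_params: DetectionParams
                            ) -> list[PlotObservation]:
    """Join detection output to plot truth: one observation per plot."""
    points = detect(scene, detect_params)
    return _observations_from_points(scene, points)


def _observations_from_points(scene: Scene, points: LMPointSet) -> list[PlotObservation]:
    return [
        PlotObservation(
            plot_id=p.plot_id,
            stratum=p.stratum,
            nt=p.nt,
            n_prime=count_points_in_plot(points, p.polygon),
            area_m2=p.area_m2,
        )
        for p in scene.plots
    ]


def build_observation_grid(
    scene: Scene,
    bands: tuple[str, ...] = ("PAN", "NIR"),
    window_sizes: tuple[int, ...] = (3, 5, 7, 9, 11),
    thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> dict[tuple[str, int, float], list[PlotObservation]]:
    """Observation tables for every (band, window, threshold) combination.

    Local maxima are extracted once per band/window and re-filtered per
    threshold, which is equivalent to running :func:`detect` per combination.
    """
    ndvi = compute_ndvi(scene.red, scene.nir)
    grid: dict[tuple[str, int, float], list[PlotObservation]] = {}
    for band in bands:
        raster = scene.band(band)
        for w in window_sizes:
            raw = local_maxima(raster, w)
            raw.source_band = band
            annotated = filter_by_ndvi(raw, ndvi, None)
            for t in thresholds:
                kept = LMPointSet(
                    points=[p for p in annotated if p.ndvi >= t],
                    source_band=band,
                    window_size=w,
                    ndvi_threshold_applied=t,
                )
                grid[(band, w, t)] = _observations_from_points(scene, kept)
    return grid


def observations_to_dataframe(obs: list[PlotObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [o.plot_id for o in obs],
            "stratum": [o.stratum for o in obs],
            "nt": [o.nt for o in obs],
            "n_prime": [o.n_prime for o in obs],
            "area_m2": [o.area_m2 for o in obs],
        }
    )
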