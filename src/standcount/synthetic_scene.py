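"""Synthetic forest scene generator.

Produces PAN/red/NIR rasters plus ground-truth stems and sample plots with
a controlled statistical structure: per-plot stem counts from a truncated
normal, stratum-specific crown diameter distributions, conifer crowns
rendered as single symmetric brightness peaks, broadleaf crowns as irregular
multi-lobed blobs, roads and bare soil with low NDVI, and optional standing
dead trees that are bright in PAN but dark in NIR.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .raster import Raster, block_mean

CONIFEROUS = "coniferous"
BROADLEAF = "broadleaf"
UNCLASSIFIED = "unclassified"

# background / road reflectances (shared with tests through the module API)
PAN_BACKGROUND = 0.20
RED_BACKGROUND = 0.18
NIR_BACKGROUND = 0.20
ROAD_PAN = 0.45
ROAD_RED = 0.25
ROAD_NIR = 0.10

# crown rendering amplitudes
PAN_CROWN_AMPLITUDE = 0.50
NIR_CROWN_AMPLITUDE = 1.00
RED_CROWN_DEPRESSION = 0.15


class SceneSizeError(ValueError):
    """The extent cannot hold the requested number of non-overlapping plots."""


@dataclass
class SceneParams:
    """Parameters of a synthetic scene.

    Defaults reproduce the reference survey moments: 400 m^2 plots, per-plot
    stem counts with mean 27, SD 20, range [4, 110]; conifer crown diameters
    mean 2.68 m (N-S) / 2.95 m (E-W), SD 0.96 m, range [1.38, 6.61] m;
    broadleaf crowns mean 3.63 / 3.79 m, SD 1.52 m.
    """

    extent_m: tuple[float, float] = (480.0, 420.0)
    pan_pixel_m: float = 0.6
    ms_pixel_m: float = 2.4
    plot_side_m: float = 20.0
    n_plots: int = 73
    stratum_mix: float = 26 / 73  # fraction of coniferous plots
    density_moments: tuple[float, float, float, float] = (27.0, 20.0, 4.0, 110.0)
    conifer_crown: tuple[float, float, float, float, float] = (2.68, 2.95, 0.96, 1.38, 6.61)
    broadleaf_crown: tuple[float, float, float] = (3.63, 3.79, 1.52)
    noise_sd: float = 0.01
    road_fraction: float = 0.02
    dead_fraction: float = 0.0
    seed: int = 0
    min_separation_m: float = 0.7
    plot_pitch_m: float = 40.0
    margin_m: float = 20.0
    # stems keep this distance from plot edges so a crown-apex pixel centre
    # cannot fall in the neighbouring (half-open) plot or fishnet cell
    edge_buffer_m: float = 1.2

    def __post_init__(self) -> None:
        ratio = self.ms_pixel_m / self.pan_pixel_m
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("pan_pixel_m must divide ms_pixel_m exactly")
        for side in self.extent_m:
            if abs(side / self.ms_pixel_m - round(side / self.ms_pixel_m)) > 1e-9:
                raise ValueError("extent_m must be a whole number of MS pixels")
        mean, sd, lo, hi = self.density_moments
        if not (lo <= mean <= hi):
            raise ValueError("density moments must satisfy min <= mean <= max")
        if lo < 1:
            raise ValueError("per-plot counts must be >= 1")
        if sd < 0:
            raise ValueError("density SD must be non-negative")
        if not 0 <= self.stratum_mix <= 1:
            raise ValueError("stratum_mix must be in [0, 1]")

    @property
    def ms_factor(self) -> int:
        return round(self.ms_pixel_m / self.pan_pixel_m)


@dataclass
class TreeRecord:
    """Ground-truth stem: position, crown diameters, stratum, alive flag."""

    x: float
    y: float
    crown_ns: float
    crown_ew: float
    stratum: str
    alive: bool = True


@dataclass
class PlotTruth:
    """One square sample plot with its true live-stem count."""

    plot_id: str
    polygon: BaseGeometry
    stratum: str
    nt: int

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def area_m2(self) -> float:
        return self.polygon.area


@dataclass
class Scene:
    pan: Raster
    red: Raster
    nir: Raster
    trees: list[TreeRecord]
    plots: list[PlotTruth]

    def band(self, name: str) -> Raster:
        name = name.upper()
        if name == "PAN":
            return self.pan
        if name == "NIR":
            return self.nir
        if name == "RED":
            return self.red
        raise KeyError(f"unknown band {name!r}")


# ---------------------------------------------------------------------------
# forest generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """One draw from N(mean, sd) truncated to [lo, hi] by rejection."""
    if sd == 0:
        return float(mean)
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _plot_anchors(params: SceneParams) -> list[tuple[float, float]]:
    """Candidate lower-x/lower-y corners for plot squares, row-major.

    Anchors are multiples of plot_side_m so the plots tile onto a fishnet of
    the same cell size; a road reserve strip on the left is kept plot-free.
    """
    w, h = params.extent_m
    side = params.plot_side_m
    pitch = params.plot_pitch_m
    road_w = params.road_fraction * w
    x_start = max(params.margin_m, math.ceil(road_w / side) * side)
    anchors = []
    y = params.margin_m
    while y + side <= h - params.margin_m + 1e-9:
        x = x_start
        while x + side <= w - params.margin_m + 1e-9:
            anchors.append((x, y))
            x += pitch
        y += pitch
    return anchors


def _place_stems(rng: np.random.Generator, n: int, bounds, min_sep: float,
                 max_attempts: int = 2000) -> list[tuple[float, float]]:
    """Uniform positions inside the plot with a minimum-separation rejection
    rule; after max_attempts failed draws a position is accepted regardless
    so dense plots always fill."""
    xmin, ymin, xmax, ymax = bounds
    placed: list[tuple[float, float]] = []
    min_sep2 = min_sep * min_sep
    for _ in range(n):
        for attempt in range(max_attempts):
            px = rng.uniform(xmin, xmax)
            py = rng.uniform(ymin, ymax)
            if all((px - qx) ** 2 + (py - qy) ** 2 >= min_sep2 for qx, qy in placed):
                break
        placed.append((px, py))
    return placed


def _draw_crown(rng: np.random.Generator, stratum: str, params: SceneParams
                ) -> tuple[float, float]:
    if stratum == CONIFEROUS:
        mean_ns, mean_ew, sd, lo, hi = params.conifer_crown
        ns = _truncated_normal(rng, mean_ns, sd, lo, hi)
        ew = _truncated_normal(rng, mean_ew, sd, lo, hi)
    else:
        mean_ns, mean_ew, sd = params.broadleaf_crown
        ns = _truncated_normal(rng, mean_ns, sd, 0.5, mean_ns + 6 * sd)
        ew = _truncated_normal(rng, mean_ew, sd, 0.5, mean_ew + 6 * sd)
    return ns, ew


def generate_forest(params: SceneParams) -> tuple[list[TreeRecord], list[PlotTruth]]:
    """Draw sample plots and ground-truth stems.

    Per-plot stem counts come from a truncated normal with the configured
    moments, rounded to integers; stems are uniform within the plot subject
    to a minimum-separation rejection rule; a ``dead_fraction`` of stems is
    flagged dead. Raises :class:`SceneSizeError` when the extent cannot hold
    ``n_plots`` non-overlapping squares.
    """
    if params.n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    rng = np.random.default_rng([0, params.seed])
    anchors = _plot_anchors(params)
    if len(anchors) < params.n_plots:
        raise SceneSizeError(
            f"extent {params.extent_m} holds only {len(anchors)} plots of side "
            f"{params.plot_side_m} m at pitch {params.plot_pitch_m} m; "
            f"{params.n_plots} requested"
        )
    anchors = anchors[: params.n_plots]

    n_conifer = round(params.stratum_mix * params.n_plots)
    strata = [CONIFEROUS] * n_conifer + [BROADLEAF] * (params.n_plots - n_conifer)
    strata = list(np.array(strata, dtype=object)[rng.permutation(params.n_plots)])

    mean, sd, lo, hi = params.density_moments
    trees: list[TreeRecord] = []
    plots: list[PlotTruth] = []
    for i, ((ax, ay), stratum) in enumerate(zip(anchors, strata)):
        side = params.plot_side_m
        polygon = box(ax, ay, ax + side, ay + side)
        count = int(round(_truncated_normal(rng, mean, sd, lo, hi)))
        buf = min(params.edge_buffer_m, side / 4)
        inner = (ax + buf, ay + buf, ax + side - buf, ay + side - buf)
        positions = _place_stems(rng, count, inner, params.min_separation_m)
        n_live = 0
        for px, py in positions:
            ns, ew = _draw_crown(rng, stratum, params)
            alive = bool(rng.random() >= params.dead_fraction)
            n_live += alive
            trees.append(TreeRecord(px, py, ns, ew, stratum, alive))
        plot_stratum = stratum if n_live > 0 else UNCLASSIFIED
        plots.append(PlotTruth(f"P{i:03d}", polygon, plot_stratum, n_live))
    return trees, plots


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _crown_footprint(tree: TreeRecord, pixel: float, nx: int, ny: int):
    """Pixel-centre coordinate grids over the crown bounding box."""
    rx = tree.crown_ew / 2.0
    ry = tree.crown_ns / 2.0
    c0 = max(0, int(np.floor((tree.x - rx) / pixel)))
    c1 = min(nx - 1, int(np.floor((tree.x + rx) / pixel)))
    r0 = max(0, int(np.floor((tree.y - ry) / pixel)))
    r1 = min(ny - 1, int(np.floor((tree.y + ry) / pixel)))
    if c1 < c0 or r1 < r0:
        return None
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xs = (cols + 0.5) * pixel
    ys = (rows + 0.5) * pixel
    dx = (xs[None, :] - tree.x) / rx
    dy = (ys[:, None] - tree.y) / ry
    return (slice(r0, r1 + 1), slice(c0, c1 + 1)), dx, dy


def _conifer_profile(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Radially symmetric cosine-tapered peak with a single strict maximum."""
    rn = np.sqrt(dx ** 2 + dy ** 2)
    prof = np.where(rn < 1.0, np.cos(0.5 * np.pi * np.minimum(rn, 1.0)) ** 2, 0.0)
    return prof


def _broadleaf_profile(rng: np.random.Generator, dx: np.ndarray, dy: np.ndarray
                       ) -> np.ndarray:
    """Irregular crown: 1-3 offset Gaussian lobes with amplitude jitter, so a
    single crown may carry more than one local brightness peak."""
    n_lobes = int(rng.integers(1, 4))
    prof = np.zeros(np.broadcast_shapes(dx.shape, dy.shape))
    for _ in range(n_lobes):
        ox, oy = rng.uniform(-0.55, 0.55, size=2)
        sigma = rng.uniform(0.15, 0.30)
        amp = rng.uniform(0.55, 1.0)
        prof += amp * np.exp(-(((dx - ox) ** 2 + (dy - oy) ** 2) / (2 * sigma ** 2)))
    prof /= max(prof.max(), 1e-12)
    # confine to the crown ellipse with a soft edge
    rn = np.sqrt(dx ** 2 + dy ** 2)
    prof = prof * np.clip(1.5 * (1.0 - rn), 0.0, 1.0)
    return prof


def render_scene(trees: list[TreeRecord], plots: list[PlotTruth],
                 params: SceneParams) -> Scene:
    """Rasterize stems to PAN/red/NIR.

    Conifers get a radially symmetric peak (one strict PAN maximum at the
    apex), broadleaves a multi-lobed blob. Live crowns raise NIR and depress
    red; dead crowns are bright in PAN only. Background and road strips have
    NDVI < 0.1. MS bands are block means over the latent PAN-resolution grid.
    """
    rng = np.random.default_rng([1, params.seed])
    w, h = params.extent_m
    pixel = params.pan_pixel_m
    nx = round(w / pixel)
    ny = round(h / pixel)

    pan = np.full((ny, nx), PAN_BACKGROUND, dtype=np.float64)
    red = np.full((ny, nx), RED_BACKGROUND, dtype=np.float64)
    nir = np.full((ny, nx), NIR_BACKGROUND, dtype=np.float64)

    # road strip along the left edge, bright in PAN, dark in NIR
    road_w = params.road_fraction * w
    road_cols = int(round(road_w / pixel))
    if road_cols > 0:
        pan[:, :road_cols] = ROAD_PAN
        red[:, :road_cols] = ROAD_RED
        nir[:, :road_cols] = ROAD_NIR
        # a few brighter patches so the road produces pseudo maxima
        for _ in range(max(1, ny // 200)):
            rr = int(rng.integers(2, ny - 2))
            cc = int(rng.integers(0, max(1, road_cols)))
            rows = np.arange(max(0, rr - 3), min(ny, rr + 4))
            cols = np.arange(0, road_cols)
            dyy = (rows[:, None] - rr) / 3.0
            dxx = (cols[None, :] - cc) / 3.0
            pan[np.ix_(rows, cols)] += 0.15 * np.exp(-(dxx ** 2 + dyy ** 2))

    live_veg = np.zeros_like(pan)
    for tree in trees:
        fp = _crown_footprint(tree, pixel, nx, ny)
        if fp is None:
            continue
        window, dx, dy = fp
        if tree.stratum == CONIFEROUS:
            prof = _conifer_profile(dx, dy)
        else:
            prof = _broadleaf_profile(rng, dx, dy)
        amp_pan = PAN_CROWN_AMPLITUDE * rng.uniform(0.8, 1.2)
        pan[window] += amp_pan * prof
        if tree.alive:
            amp_nir = NIR_CROWN_AMPLITUDE * rng.uniform(0.8, 1.2)
            nir[window] += amp_nir * prof
            live_veg[window] += prof
    red -= RED_CROWN_DEPRESSION * np.clip(live_veg, 0.0, 1.0)

    if params.noise_sd > 0:
        pan += rng.normal(0.0, params.noise_sd, pan.shape)
        red += rng.normal(0.0, params.noise_sd, red.shape)
        nir += rng.normal(0.0, params.noise_sd, nir.shape)

    factor = params.ms_factor
    pan_r = Raster(pan.astype(np.float32), origin=(0.0, 0.0), pixel_size=pixel)
    red_r = Raster(block_mean(red, factor).astype(np.float32), origin=(0.0, 0.0),
                   pixel_size=params.ms_pixel_m)
    nir_r = Raster(block_mean(nir, factor).astype(np.float32), origin=(0.0, 0.0),
                   pixel_size=params.ms_pixel_m)
    return Scene(pan=pan_r, red=red_r, nir=nir_r, trees=list(trees), plots=list(plots))


def generate_scene(params: SceneParams) -> Scene:
    """Convenience: :func:`generate_forest` followed by :func:`render_scene`."""
    trees, plots = generate_forest(params)
    return render_scene(trees, plots, params)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_scene(scene: Scene, directory) -> dict[str, Path]:
    """Write rasters as GeoTIFF, trees/plots as GeoJSON, plot table as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pan": directory / "pan.tif",
        "red": directory / "red.tif",
        "nir": directory / "nir.tif",
        "trees": directory / "trees.geojson",
        "plots": directory / "plots.geojson",
        "plot_table": directory / "plots.csv",
    }
    scene.pan.write_geotiff(paths["pan"])
    scene.red.write_geotiff(paths["red"])
    scene.nir.write_geotiff(paths["nir"])

    tree_features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [t.x, t.y]},
            "properties": {
                "stratum": t.stratum,
                "alive": t.alive,
                "crown_ns": t.crown_ns,
                "crown_ew": t.crown_ew,
            },
        }
        for t in scene.trees
    ]
    paths["trees"].write_text(json.dumps(
        {"type": "FeatureCollection", "features": tree_features}))

    plot_features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"plot_id": p.plot_id, "stratum": p.stratum, "nt": p.nt},
        }
        for p in scene.plots
    ]
    paths["plots"].write_text(json.dumps(
        {"type": "FeatureCollection", "features": plot_features}))

    with open(paths["plot_table"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plot_id", "stratum", "nt"])
        for p in scene.plots:
            writer.writerow([p.plot_id, p.stratum, p.nt])
    return paths


def read_scene(directory) -> Scene:
    """Read a scene written by :func:`write_scene` (lossless round trip)."""
    directory = Path(directory)
    pan = Raster.read_geotiff(directory / "pan.tif")
    red = Raster.read_geotiff(directory / "red.tif")
    nir = Raster.read_geotiff(directory / "nir.tif")

    tree_fc = json.loads((directory / "trees.geojson").read_text())
    trees = [
        TreeRecord(
            x=f["geometry"]["coordinates"][0],
            y=f["geometry"]["coordinates"][1],
            crown_ns=f["properties"]["crown_ns"],
            crown_ew=f["properties"]["crown_ew"],
            stratum=f["properties"]["stratum"],
            alive=f["properties"]["alive"],
        )
        for f in tree_fc["features"]
    ]
    plot_fc = json.loads((directory / "plots.geojson").read_text())
    plots = [
        PlotTruth(
            plot_id=f["properties"]["plot_id"],
            polygon=shape(f["geometry"]),
            stratum=f["properties"]["stratum"],
            nt=f["properties"]["nt"],
        )
        for f in plot_fc["features"]
    ]
    return Scene(pan=pan, red=red, nir=nir, trees=trees, plots=plots)
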