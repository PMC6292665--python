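import numpy as np
import pytest

import standcount as sc


@pytest.fixture(scope="session")
def default_scene() -> sc.Scene:
    """Full default scene (73 plots) shared across read-only tests."""
    return sc.generate_scene(sc.SceneParams(seed=1))


@pytest.fixture(scope="session")
def small_scene_params() -> sc.SceneParams:
    """Scaled-down scene for fast multi-seed loops."""
    return sc.SceneParams(
        seed=0,
        n_plots=16,
        stratum_mix=0.5,
        extent_m=(240.0, 240.0),
        density_moments=(15.0, 8.0, 4.0, 40.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_observations(n_prime, nt, stratum="unclassified"):
    """Build a PlotObservation list from parallel count sequences."""
    return [
        sc.PlotObservation(plot_id=f"P{i:03d}", stratum=stratum,
                           nt=int(t), n_prime=int(p))
        for i, (p, t) in enumerate(zip(n_prime, nt))
    ]


def brute_force_local_maxima(data: np.ndarray, window: int) -> set[tuple[int, int]]:
    """Exhaustive per-pixel clipped-window maximum scan (independent oracle)."""
    half = window // 2
    nrows, ncols = data.shape
    out = set()
    for r in range(nrows):
        for c in range(ncols):
            win = data[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1]
            if data[r, c] == win.max():
                out.add((r, c))
    return out


def points_to_pixels(points: sc.LMPointSet, raster: sc.Raster) -> set[tuple[int, int]]:
    return {raster.pixel_of(p.x, p.y) for p in points}


@pytest.fixture
def separated_conifer_params():
    """Noise-free conifer-only scene whose crowns are pairwise separated by
    more than one crown diameter (low density + strong minimum separation)."""
    def factory(seed: int) -> sc.SceneParams:
        return sc.SceneParams(
            seed=seed,
            n_plots=12,
            stratum_mix=1.0,
            noise_sd=0.0,
            density_moments=(3.0, 1.0, 2.0, 4.0),
            min_separation_m=8.0,
            extent_m=(240.0, 240.0),
        )
    return factory


def crowns_separated(trees) -> bool:
    """True when every stem pair is farther apart than the larger of the two
    crowns' biggest diameter."""
    for i, a in enumerate(trees):
        for b in trees[i + 1:]:
            d = np.hypot(a.x - b.x, a.y - b.y)
            if d <= max(a.crown_ns, a.crown_ew, b.crown_ns, b.crown_ew):
                return False
    return True
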