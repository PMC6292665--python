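# standcount

Stand-density estimation from high-resolution imagery using spectral
local-maxima filtering. The pipeline:

1. **synthetic_scene** — generates test scenes: PAN (0.6 m) plus red/NIR
   (2.4 m) rasters, ground-truth stems and 400 m² sample plots. Conifer
   crowns render as single symmetric brightness peaks, broadleaf crowns as
   irregular multi-lobed blobs; roads, bare soil and standing dead trees
   have low NDVI.
2. **detection** — moving-window maximum filtering (windows 3–11 px,
   clipped at borders, plateaus collapsed to one centroid point) plus NDVI
   thresholding to remove pseudo crown points.
3. **plot_analysis** — half-open point-in-plot counting, 70 % pure-stand
   stratification, trees/plot ↔ trees/ha conversion.
4. **calibration** — Pearson-correlation grid search over band × window ×
   NDVI threshold per stratum, then linear and quadratic OLS models of true
   count on detected count with leave-one-out cross-validation.
5. **mapping** — 20 m fishnet point counts and per-cell density prediction
   with per-stratum models (ragged edge cells area-normalized, negative
   predictions floored at 0).

## CLI

```sh
standcount simulate  --config cfg.yaml [--seed N] [--out DIR]
standcount detect    --scene-dir DIR --band PAN --window 3 --threshold 0.3 [--out DIR]
standcount calibrate --scene-dir DIR [--config cfg.yaml] [--out DIR]
standcount map       --scene-dir DIR --models DIR/models.json [--out DIR]
```

`simulate` writes `pan.tif`/`red.tif`/`nir.tif` (GeoTIFF), `trees.geojson`,
`plots.geojson`, `plots.csv` and a `config.json` snapshot. `calibrate`
writes the full grid-search table (`grid_search.csv`, one row per band ×
window × threshold × stratum) and `models.json` with the best combination
and fitted models per stratum. `map` writes `density_per_ha.tif` (20 m
cells), `fishnet.geojson` and `fishnet.csv`.

Example config (YAML; all fields optional):

```yaml
scene:
  n_plots: 73
  stratum_mix: 0.356     # fraction of coniferous plots
  extent_m: [480, 420]
  seed: 1
bands: [PAN, NIR]
window_sizes: [3, 5, 7, 9, 11]
ndvi_thresholds: [0.1, 0.2, 0.3, 0.4, 0.5]
out_dir: out
```

## Python API

```python
import standcount as sc

scene = sc.generate_scene(sc.SceneParams(seed=1))
points = sc.detect(scene, sc.DetectionParams("NIR", 3, 0.3))
tables = sc.build_observation_grid(scene)
cells, best, models = sc.calibrate_models(tables)
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (detector-oracle
equivalence, monotonicity, separated-crown exactness, regression/LOOCV
oracles, parameter recovery, end-to-end conservation, workflow
reproduction). The acceptance report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
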