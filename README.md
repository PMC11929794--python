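# insularity

Island-biogeographic predictors and diversity models for **edaphic
habitat-island archipelagos** — natural island-like patches (such as
quartz-gravel fields) embedded in a contrasting terrestrial matrix.

The package is aimed at spatial ecologists who have island polygons, a
DEM, red/NIR imagery and floristic inventories, and want the standard
habitat-island inference chain as tested, scriptable code:

1. **Five spatial predictors** per island:
   - island **area** A (m²),
   - **habitat diversity index** `HDI = TP / (2·√(π·A))`, where TP is the
     island perimeter plus all internal habitat-boundary lengths from a
     rule-based topographic classification (ridge/slope/plain/valley/
     drainage) of the DEM,
   - **nearest-neighbour distance** (edge to edge, all islands),
   - **target effect** `log10(DMI/√A)`, with DMI the distance to the
     archipelago's largest island (the "mainland equivalent"),
   - **matrix contrast**: NDVI classified into 5 Jenks natural-breaks
     units, class values summed over a 50 m buffer ring and divided by
     the ring area.
2. **Responses** from the island × species incidence matrix and a
   specialist trait flag: generalist richness (GR), specialist richness
   (QS) and specialist percentage (QS%).
3. **Inference**: the species–area power model `S = c·Aᶻ` fitted
   log–log with a 95% CI on z; negative-binomial (GR, QS) and binomial
   (QS%) GLMs — normality screen with log10(x+0.01) transforms,
   z-standardisation, single-predictor linear/quadratic scans, exhaustive
   AICc all-subsets selection respecting marginality, backward pruning of
   non-significant (p ≥ 0.05) and collinear (VIF > 5) terms, and the
   deviance pseudo-R² = (null − residual)/null deviance.
4. A **synthetic archipelago generator** (polygons, terrain, imagery,
   communities with known effect sizes) so the whole chain is testable
   end to end without any data download.

Vector geometry uses shapely; rasters are plain-text ESRI ASCII grids
(`.asc`) behind a small georeferenced-grid container; statistics build
on statsmodels/scipy, with the NB dispersion profiled by maximum
likelihood and the Jenks partition computed by an exact dynamic
programme.

## Worked example

Simulate a small archipelago and run the full chain (the `simulate`
block accepts any generator knob; with real data you pass file paths —
GeoJSON polygons with `id`/`sampled` properties, `.asc` rasters, CSV
community and trait tables — instead):

```python
from insularity.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo_out", seed=42,
    simulate=dict(n_islands=12, n_unsampled=4, area_range=(2.5e3, 4e5),
                  extent=6000, cell_size=10, min_gap=60),
)
res = run_pipeline(cfg)
print(res["sar_fits"][["response", "z", "r2", "z_ci_lo", "z_ci_hi", "n"]]
      .round(3).to_string(index=False))
print(res["glm_final"][["response", "term", "coef", "p_value", "pseudo_r2"]]
      .round(4).to_string(index=False))
```

prints

```
response     z    r2  z_ci_lo  z_ci_hi  n
      gr 0.244 0.338    0.003    0.484 12
      qs 0.320 0.616    0.129    0.511 11

response              term    coef  p_value  pseudo_r2
      gr             const  3.5436   0.0000     0.3823
      gr           area_m2  0.4195   0.0038     0.3823
      qs             const  2.5356   0.0000     0.9486
      qs     target_effect -0.2664   0.3002     0.9486
      qs   matrix_contrast  0.4499   0.0007     0.9486
      qs   target_effect^2 -2.0481   0.0001     0.9486
  qs_pct             const -2.3094   0.0000     0.7937
  qs_pct     target_effect  0.8245   0.0014     0.7937
  qs_pct   matrix_contrast  0.2586   0.0543     0.7937
  qs_pct matrix_contrast^2  0.6201   0.0000     0.7937
```

Reading this: the generalist SAR exponent is z = 0.244 (CI [0.003,
0.484] — wide, as expected at n = 12); the final generalist model keeps
log-area only (coefficients are on z-standardised predictors, so 0.42 is
the change in log richness per SD of log area); specialist richness
shows the planted hump-shaped target-effect response (negative squared
term), and one QS island with zero richness was dropped from its SAR
fit. `demo_out/` receives `predictors.csv`, `diversity.csv`,
`sar_fits.csv`, `glm_single.csv`, `glm_selection.csv`, `glm_final.csv`
and `run.log`.

The same stages are available as a CLI:

```sh
insularity simulate --seed 1 --out scene/
insularity compute-predictors --polygons scene/islands.geojson \
    --dem scene/dem.asc --red scene/red.asc --nir scene/nir.asc \
    --out predictors.csv
insularity fit-sar --predictors predictors.csv --diversity diversity.csv --out sar.csv
insularity run-all --config pipeline.yaml
```

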