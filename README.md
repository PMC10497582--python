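# riverscape

Reach-scale stream-network extraction from digital elevation models, and
presence-background habitat modelling on the extracted network — a toolkit
for mapping potential habitat of freshwater species (and the overlap between
a native species and introduced competitors) in regions where field data are
sparse but elevation and climate rasters are free.

The workflow, end to end:

1. **Hydrology.** A projected DEM is depression-filled (boundary-seeded
   priority-flood), routed with single-direction D8 pointers, and
   flow-accumulated. Stream cells are those whose contributing area
   `A = count × cellsize²` exceeds a headwater threshold (2.0 km² by
   default).
2. **Network.** Stream cells are traced into vector polylines, split at
   confluences, subdivided into reaches of a chosen grain (1.0 km by
   default), and Strahler-ordered. The reach is the modelling unit.
3. **Attributes.** Each reach gets channel descriptors (gradient in % slope,
   sinuosity) and catchment-supported summaries (contributing area,
   confluence and stream density, mean upstream slope in degrees×100, and
   upstream means of any co-registered environmental raster), computed for
   all reaches in one topological pass. Collinear predictors are removed by
   a greedy Pearson filter (|r| < 0.7 retained).
4. **Models.** Presence records are cleaned (positional uncertainty ≤ 100 m,
   per-cell deduplication), background reaches are sampled inside a buffer
   around occurrences, and an L1-penalized maximum-entropy (Gibbs) model

   `q(x) ∝ exp(βᵀ f(x))`, fitted by maximizing
   `(1/n) Σᵢ βᵀf(xᵢ) − log Z − m Σⱼ λⱼ |βⱼ|`

   is estimated by coordinate descent over feature expansions of the
   predictors (linear, quadratic, product, hinge, threshold). Candidate
   models over a (regularization multiplier × feature classes) grid are
   scored by partial-ROC AUC ratios, omission rate and AICc, and the best
   one selected kuenm-style. Suitability is reported on the cloglog scale
   `1 − exp(−e^H · raw)`.
5. **Overlap.** Suitability is binarized with the minimum-training-presence
   (MTP) or 10th-percentile (P10) threshold; suitable stream length and the
   share of a native species' suitable reaches also suitable for invaders
   are reported, with rank tests (Kruskal–Wallis, Mann–Whitney) on the
   elevation distributions of the suitable reach sets.

A seeded synthetic module (drainable terrains, smooth environmental fields,
virtual species with known suitability) makes every stage testable with no
downloads.

## Worked example

```bash
riverscape make-fixtures --kind dendritic_fractal --size 256 --seed 9 --out fx
riverscape run --config fx/config.yaml
```

The first command writes a synthetic DEM, temperature and precipitation
rasters, and occurrence tables for two virtual species, plus a pipeline
config; the second runs extraction → attribution → candidate fitting and
selection → transfer → overlap, printing:

```
extract: ok
attribute: ok
fit:invader: ok
fit:native: ok
receiving: ok
transfer: ok
overlap: ok
```

`fx/run/overlap.json` then holds the study's summary numbers, e.g. (seed 9):

```json
"pairs": {"native|invader": {"native_suitable_km": 266.7, "invader_suitable_km": 203.4,
                             "shared_km": 191.3, "percent_overlap": 71.5, ...}}
```

meaning 71.5% of the reaches suitable for the native species are also suitable
for the invader, with the shared habitat totalling ~191 km of channel; the
accompanying `elevation_tests` entry reports whether the two species'
suitable reaches sit at different elevations. Re-running with the same
config reuses cached stages; `--force` recomputes and reproduces the outputs
byte for byte for a fixed seed.

The same CLI exposes the individual stages (`extract`, `attribute`, `fit`,
`evaluate`, `transfer`, `overlap`) for use on real rasters and occurrence
CSVs (columns `species,x,y,uncertainty_m`).

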