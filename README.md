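# streetcover

Desk-scale pipeline for auditing street-level imagery coverage across
cities and estimating how coverage relates to subcity socioeconomic
conditions.

The pipeline:

1. **Sampling** (`streetcover.spatial`) — projects each city into a planar
   meter frame (azimuthal equidistant, centered on the boundary centroid),
   lays a 500-m point lattice over the boundary, measures road length
   inside a 100-m buffer around every point with exact circle–segment
   clipping, discards points with no road, and assigns points to subcity
   units.
2. **Audit** (`streetcover.providers`) — queries an imagery-metadata
   provider for every eligible point (closest panorama within 100 m; ties
   broken by most recent capture date). A deterministic synthetic provider
   backed by a panorama store replaces the real web service; a thin HTTP
   adapter with the same interface is included. Error responses are
   reported and excluded from analysis (complete case).
3. **Coverage metrics** (`streetcover.coverage`) — availability
   percentage, mean image age in months before April 2019, and the
   standard deviation of image age, at subcity / city / country levels.
4. **SES index** (`streetcover.ses`) — combined socioeconomic indices as
   unweighted sums of Z-scored subcity covariates, with and without the
   above-poverty share.
5. **Models** (`streetcover.models`, `streetcover.glmm`) — point-level
   mixed-effects logistic regression for availability (city-grouped random
   intercept plus random slopes on per-city standardized X/Y coordinates,
   fitted by a Laplace approximation implemented in `glmm.py`) and
   subcity-level linear mixed models (REML, city random intercept) for
   image age and image-age variance. One exposure per model; controls for
   road length (availability only), country (Central America pooled), and
   unit area; effects reported per SD of the exposure.
6. **Synthetic cities** (`streetcover.simulate`) — square cities with grid
   road networks, vertical-strip subcity units, covariates driven by one
   latent factor, and panoramas whose retention and capture dates follow
   known logistic / linear models, so parameter recovery is testable end
   to end.

## CLI

```sh
streetcover simulate --out-dir run --seed 1 --n-cities 8   # synthetic inputs
streetcover all      --out-dir run --seed 1                # sample -> audit -> aggregate -> index -> model
```

Stages can also be run individually (`sample`, `audit`, `aggregate`,
`index`, `model`). Each stage writes flat CSV/GeoJSON artifacts plus a
manifest with input hashes; reruns with identical inputs, config, and seed
are byte-identical. Key options: `--config cfg.yaml`, `--spacing-m`,
`--radius-m`, `--ref-date YYYY-MM`, `--strata per-country`. To run on real
data, point the config at your own `boundaries`/`units`/`roads` GeoJSON
and `panoramas`/`covariates` CSV files (schemas in `streetcover/io.py`).

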