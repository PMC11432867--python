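# pollimap

Pollinator habitat-suitability modelling on categorical land-use rasters,
built to study how **model choice** and **input-data detail** change the
resulting suitability maps.

Wild bees need two things from a landscape: somewhere to nest and flowers
within flight range. Two families of GIS models operationalize this on
land-use/land-cover (LULC) grids, and they disagree in instructive ways:

- **Distance-decay model** (ESTIMAP-style). A local score
  `L = w_f·FA + (1−w_f)·NA` from per-class floral availability (FA) and
  nesting availability (NA) is smoothed with the foraging kernel, then
  boosted by the exponential influence of nearby *favorable* structures
  (hedgerows, semi-natural vegetation, forest edges) and reduced near
  roads:

  `HS = (S + λ·I·(1−S))·R`,  with `I = exp(−D_fav/α)` and
  `R = 1 − p_road·exp(−D_road/β)`.

- **Nesting-anchored model** (InVEST/Lonsdorf-style). Supply is the
  product of a cell's nesting suitability and the kernel-weighted floral
  resources reachable from it:

  `PS(x) = HN(x) · Σ_y w(d(x,y))·FR(y) / Σ_y w(d(x,y))`,
  `w(d) = exp(−d/α)`.

Both share the exponential foraging kernel with decay length `α` equal to
the reference species' mean flight distance (680 m — a composite of many
real wild-bee species; honey bees and bumblebees are out of scope).
Because nesting multiplies rather than diffuses, the second model draws
hard borders between classes where the first grades smoothly — and it is
far less sensitive to small landscape structures.

The package includes the preprocessing the models expect (15 m forest-edge
bands, riparian zones along water), a cell-wise map-similarity index
`S = 1 − |a − b|`, zonal median/std summaries, a seeded synthetic-landscape
generator producing paired detailed/generalized datasets (the real
counterparts of such comparisons are licensed or non-public), and a
2-models × 2-datasets experiment driver.

## Worked example

`python examples/05_full_experiment.py` generates a 200×200 (2 km × 2 km,
10 m cells) detailed landscape and its generalized counterpart, runs both
models on both, and prints:

```
map-wide medians (row 'all' of each zonal summary):
  estimap_a      median=0.45  std=0.09
  estimap_b      median=0.32  std=0.08
  invest_a       median=0.06  std=0.05
  invest_b       median=0.06  std=0.02
  sim_models_a   median=0.62  std=0.09
  sim_models_b   median=0.74  std=0.08
agricultural-matrix median, estimap: detailed 0.462 -> generalized 0.330 (drop 0.132)
agricultural-matrix median, invest: detailed 0.062 -> generalized 0.058 (drop 0.005)
small-structure sensitivity ratio (distance-decay / nesting-anchored): 29.0x
```

The distance-decay model rates habitat higher overall and loses far more
of its rating when hedgerows and small semi-natural patches are
generalized away — the nesting-anchored model barely notices, because a
field's nesting value is unchanged by a removed hedgerow 100 m away.
The other examples each demonstrate one capability (similarity index,
reference species and scalar layers, edge/riparian preprocessing, the
hard-border vs smooth-gradient contrast).

A thin CLI wraps the same library:

```
pollimap pipeline examples/pipeline_config.yaml
pollimap simulate --seed 7 --out-dir sim/
pollimap run-estimap sim/lulc.asc sim/classes.csv sim/biophysical.csv --out hs.asc
pollimap compare hs.asc ps.asc --out similarity.asc
```

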