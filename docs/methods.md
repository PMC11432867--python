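# Methods

## Setting

Wild-bee habitat suitability is modelled on categorical land-use/land-cover
(LULC) rasters. Each class carries four biophysical indices in [0, 1]:
nesting suitability for cavity nesters and for ground nesters, and floral
availability in spring and in summer. A single *reference species* — a
composite wild bee — collapses these to two scalar layers: nesting
availability `NA = max(cavity·pref_cavity, ground·pref_ground)` and floral
availability `FA = (a_spring·floral_spring + a_summer·floral_summer) /
(a_spring + a_summer)`. The defaults (`pref = 1` for both substrates,
`a = 1` for both seasons) describe a generalist that uses everything; the
mean flight distance, 680 m by default, is the only trait that shapes the
spatial behaviour. Honey bees (hive-dependent) and bumblebees (much longer
flight ranges) are outside the model's scope.

## The foraging kernel

Both models use the isotropic exponential kernel `w(d) = exp(−d/α)` with
`α` = flight distance. Two interpretations of "mean flight distance" are
possible — the e-folding length of the kernel, or the mean of the induced
2-D displacement distribution; this implementation adopts the e-folding
reading (`K(d) = exp(−d/680 m)` directly) and exposes `α` as
configuration, so the other reading is a parameter change away.

The kernel is truncated where the weight falls below 1% of the center
weight (radius `α·ln 100 ≈ 4.6 α`, about 3.13 km at 680 m). This is a
compute/accuracy compromise; the fraction is configurable.

Smoothing is a *normalized* weighted mean, `G = Σ wF / Σ w` over valid
in-bounds cells, implemented by two FFT convolutions (values and validity
mask) and a ratio. Renormalization at map borders and around nodata holes
avoids the artificial suitability depression that zero-padding would
introduce; a constant field is an exact fixed point. Residual FFT ripple
(~1e−13) is clipped back into the observed value range so range
preservation holds exactly. Distance transforms are exact Euclidean
(`scipy.ndimage.distance_transform_edt`), not chamfer approximations.

## Distance-decay suitability (ESTIMAP-style)

The source framework is described in its documentation only at the level
of mechanisms — a smoothed expert-based score, an "exponential buffer"
from favorable areas, a negative influence of roads. The concrete
functional form used here is this package's own realization of those three
mechanisms:

```
L  = w_f·FA + (1−w_f)·NA              local score, w_f = 0.5
S  = kernel-smooth(L)
I  = exp(−D_fav / α)                  favorable influence (0 if no favorable cell)
R  = 1 − p_road·exp(−D_road / β)      road penalty, p_road = 0.5, β = 100 m
HS = clip((S + λ·I·(1−S))·R, 0, 1)    λ = 0.5
```

`D_fav` is the distance to the nearest favorable cell — a literal buffer,
chosen over summed kernel mass because it keeps a closed-form, testable
gradient (HS decreases strictly with distance from an isolated favorable
cell out to the kernel truncation). The `I·(1−S)` form lifts the smoothed
score toward 1 without ever exceeding it, so favorable cells are rated at
least as high as their smoothed score wherever roads permit. Excluded
classes (always including water) are masked to exactly 0 *after* all
other terms — open water must read 0.00 regardless of how attractive its
shores are. Setting `p_road = 0` disables the road mechanism entirely.
All four parameters are exposed; the defaults are midpoints of their
admissible ranges, not fitted values.

## Nesting-anchored supply (InVEST/Lonsdorf-style)

```
HN = max(cavity·pref_cavity, ground·pref_ground)
FR = activity-weighted seasonal floral mean
PS = HN · kernel-smooth(FR)
PA = clip(kernel-smooth(PS) · relative_abundance, 0, 1)
```

Seasonal floral values are aggregated *before* the single kernel pass
(one suitability map per model/dataset, not per season). The multi-species
weighted sum of the source model collapses to one term under the single
reference species with relative abundance 1. The headline map is `PS`
(supply): it behaves like a nesting×floral product, which matches the
near-zero urban values such models report; `PA` (abundance) is available
via `output_kind`.

Two structural consequences follow from the product form and are used as
test oracles: on a uniform landscape with all indices `c`, `HS = c` while
`PS = c²` (so the distance-decay model rates any 0 < c < 1 landscape
strictly higher), and `PS` jumps discontinuously across class borders
where `HS` grades smoothly.

## Preprocessing

Forest edges are pollinator-favorable and must exist as their own class
before modelling. Every forest cell whose center lies within 15 m
(default) of a cell of a *different* class — other forest types included —
is relabeled to a per-forest-type edge class (`code + 1000`), flagged
favorable. The band lies inside the forest, so forest+edge area is
conserved. A type's own derived edge class does not count as "different",
which makes the operation idempotent. Riparian zones relabel non-water
cells within the buffer width of water; when the width (4 m default) is
below the cell size the band is still one cell wide — a deliberate
coarsening, since meter-scale buffers would otherwise vanish at any
realistic raster resolution. Contact uses 8-connectivity; distances are
true center-to-center Euclidean.

## Map comparison

Similarity is cell-wise: `S = 1 − |a − b|`, symmetric, in [0, 1]. Zonal
summaries report the median, mean and standard deviation of the
*cell values* within each class or thematic group — never statistics of
statistics. This matters: a zone where the two models agree closely cell
by cell can still have very different zonal medians if the maps rank the
zone's cells differently, so "median similarity" must be the median of
the similarity raster, not `1 − |median(a) − median(b)|`. The standard
deviation uses the population formula (divisor *n*) by default with
`ddof=1` available. The whole-map row includes excluded classes at their
masked value of 0, so map-wide medians reflect the full study area.
Both median and mean are emitted so either reading of "average" can be
checked. Empty zones are omitted with a warning.

## Synthetic landscapes

The paired-dataset experiment needs a *detailed* landscape rich in small
linear semi-natural structures and a *generalized* version of the same
grid. The generator paints, on a 200×200 grid of 10 m cells by default:
an agricultural matrix; a density-graded urban block (sealing 90/65/20/5%)
covering 10% of the area; four forest blobs of two types (radii 10–18
cells); eight small heath/ruderal patches (radii 2–4 cells); hedgerow
segments (3 per 1000 cells, lengths 5–20 cells, one cell wide); a road
grid every 50 cells; one lake and one meandering river. Forest edges and
riparian zones are then derived exactly as for real data. All randomness
flows from one `numpy` Generator seed; identical seeds give bit-identical
landscapes.

Generalization emulates a coarse minimum-mapping-unit product: connected
components smaller than `min_patch_cells` (default 250 cells = 2.5 ha;
real coarse products have far larger MMUs, which would erase everything
at toy extents) and all one-cell-wide linear features are absorbed into
the modal surrounding class (ties to the smallest code). Major roads are
retained, as coarse datasets do map high-traffic roads. Absorption runs
in deterministic passes so that a field fragmented by hedgerows reunites
with the surrounding matrix rather than being swallowed by the road line
bounding it; slivers bordered *only* by roads merge into the road class,
mirroring "roads and associated land" aggregation. The generalized raster
is re-run through edge/riparian derivation, since the emulated coarse
datasets also had forest edges constructed during preparation.

Biophysical tables come in two modes mirroring the two parameterization
routes such studies use. `literature` mode assigns fixed per-group
archetype (NA, FA) pairs whose *rank order* — heath/rough grassland and
ruderal vegetation > forest edge > forest ≥ pasture > arable > urban >
road ≥ bare ground, water = 0 — encodes the established relative
suitability of these cover types; absolute levels are configuration, set
on the 0.1 grid so that `expert` mode (integer 0–10 ratings per class and
expert, archetype ×10 plus Gaussian noise of σ = 1 rating point, rounded
and clamped, averaged across 10 experts and rescaled) reproduces the
archetypes exactly at σ = 0. Urban classes take fixed density-bracket
values (denser sealing → lower suitability); the piecewise-linear
interpolation against built density is available for user-supplied anchor
classes. The expert survey rates two scalars per class, so its biophysical
table sets both substrates to NA and both seasons to FA.

What the synthetic landscapes do **not** emulate: realistic class
proportions of any particular region, georeferenced coordinates,
vector-based preprocessing, or the thematic richness of real biotope
mappings (84 classes in the kind of dataset emulated here vs 13 + derived
classes). Passing tests therefore demonstrate the *mechanisms* — that the
distance-decay model responds strongly to small structures and the
nesting-anchored model does not, that exclusion masking, similarity and
zonal statistics behave as specified — not that any absolute suitability
value would be reproduced on real data, whose published per-region values
depend on non-public inputs.

## Numerical and design choices

- Rasters in one experiment must share an identical grid; there is no
  resampling. ESRI ASCII (.asc) is the interchange format; nodata default
  −9999; row 0 is the northernmost row.
- Distance comparisons in edge/riparian banding use a 1e−9 m tolerance so
  cells exactly at the threshold are included regardless of float noise.
- Degenerate inputs: an all-false favorable mask gives influence 0
  everywhere (not 1); a smoothing window with no valid cell yields nodata;
  empty zones are omitted; empty species tables, zero-rating classes and
  out-of-range parameters raise validation errors naming the offender.
- The experiment at 200×200 with the 680 m kernel (truncation 313 cells)
  runs in under a second per model run via FFT convolution; the default
  problem sizes throughout (16×16 to 64×64 for oracle-checked fixtures,
  200×200 × 5 seeds for the structure-sensitivity experiment) were chosen
  as the smallest grids on which the spatial mechanisms are unambiguous.

## Known limitations

- The distance-decay composition is one defensible realization of the
  mechanism description; published applications built in GIS software may
  weight the same mechanisms differently, so only relative/structural
  statements transfer.
- A single reference species averages away inter-species differences in
  flight range and nesting needs; eco-profiles for guilds would need
  per-guild kernels and tables.
- Suitability is relative to the best class in the study area, making
  cross-region comparison of absolute values meaningless.
- The riparian minimum-one-cell rule widens sub-cell buffers to a full
  cell (10 m for a 4 m buffer at default resolution).
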