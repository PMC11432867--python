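"""The full 2-models x 2-datasets experiment on synthetic landscapes.

A detailed landscape (hedgerows, small semi-natural patches, forest
edges) is generalized into a coarse counterpart, both are run through
both suitability models, and the four maps are cross-compared. The
headline effect: removing small structures drops the distance-decay
model's rating of the agricultural matrix far more than the
nesting-anchored model's, because only the former lets favorable
structures radiate value into their surroundings.
"""

import numpy as np

from pollimap import (
    Dataset,
    LandscapeConfig,
    SpeciesTraits,
    generate_biophysical,
    paired_landscapes,
    run_comparison_experiment,
)
from pollimap.synthetic import CODES

cfg = LandscapeConfig(seed=1)  # 200 x 200 cells at 10 m
(lulc_a, table_a), (lulc_b, table_b) = paired_landscapes(cfg)
dataset_a = Dataset(lulc_a, table_a, generate_biophysical(table_a, mode="literature"), "detailed")
dataset_b = Dataset(lulc_b, table_b, generate_biophysical(table_b, mode="literature"), "generalized")

bundle = run_comparison_experiment(dataset_a, dataset_b, SpeciesTraits())

print("map-wide medians (row 'all' of each zonal summary):")
for name in ("estimap_a", "estimap_b", "invest_a", "invest_b",
             "sim_models_a", "sim_models_b"):
    df = bundle.summaries[name]
    row = df[df.zone == "all"].iloc[0]
    print(f"  {name:14s} median={row['median']:.2f}  std={row['std']:.2f}")

matrix = lulc_a.values == CODES["arable"]
drops = {}
for model in ("estimap", "invest"):
    med_a = np.median(bundle.rasters[f"{model}_a"].values[matrix])
    med_b = np.median(bundle.rasters[f"{model}_b"].values[matrix])
    drops[model] = med_a - med_b
    print(f"agricultural-matrix median, {model}: detailed {med_a:.3f} -> generalized {med_b:.3f} "
          f"(drop {drops[model]:.3f})")
print(f"small-structure sensitivity ratio (distance-decay / nesting-anchored): "
      f"{drops['estimap'] / drops['invest']:.1f}x")
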