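"""Cell-wise map similarity: S = 1 - |a - b|.

Two suitability maps are compared cell by cell; 1 means identical, 0
maximally different. The open-water case is the canonical worked example:
both models exclude water (suitability 0.00), so its similarity is 1.00 —
two maps that agree a place is worthless agree perfectly.
"""

import numpy as np

from pollimap import GridSpec, Raster, similarity_map

spec = GridSpec(n_rows=1, n_cols=3, cell_size=10.0)
model_a = Raster(spec, np.array([[0.00, 0.90, 0.35]]))
model_b = Raster(spec, np.array([[0.00, 0.20, 0.03]]))

s = similarity_map(model_a, model_b)
for label, a, b, v in zip(
    ("open water", "meadow", "built-up"), model_a.values[0], model_b.values[0], s.values[0]
):
    print(f"{label:10s}  a={a:.2f}  b={b:.2f}  similarity={v:.2f}")

# open water: identical zeros -> 1.00; meadow: the models disagree by 0.7,
# similarity 0.30; built-up: 0.32 apart, similarity 0.68
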