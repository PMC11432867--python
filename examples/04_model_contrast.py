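"""Why the two models disagree: smooth gradients vs hard borders.

On a half-forest / half-field landscape the distance-decay model grades
suitability smoothly across the boundary (the smoothing kernel and the
favorable-area influence both spread value), while the nesting-anchored
model multiplies each cell's nesting value into the result, so the
forest/field contrast appears as an abrupt jump. On a uniform landscape
with every biophysical value c, the distance-decay index is exactly c and
supply is c^2 — the former always rates habitat higher.
"""

import numpy as np
import pandas as pd

from pollimap import EstimapParams, SpeciesTraits, estimap_suitability, pollinator_supply
from pollimap.biophysical import BiophysicalTable
from pollimap.grids import ClassTable, GridSpec, Raster

species = SpeciesTraits()  # 680 m flight distance

n = 40
vals = np.full((n, n), 1, dtype=np.int64)
vals[:, n // 2 :] = 2
lulc = Raster(GridSpec(n, n, 10.0), vals)
table = ClassTable(
    pd.DataFrame(
        [
            {"code": 1, "name": "forest", "group": "forests"},
            {"code": 2, "name": "field", "group": "arable and horticultural"},
        ]
    )
)
bio = BiophysicalTable(
    pd.DataFrame(
        {
            "code": [1, 2],
            "nest_cavity": [1.0, 0.1],
            "nest_ground": [1.0, 0.1],
            "floral_spring": [0.8, 0.2],
            "floral_summer": [0.8, 0.2],
        }
    )
)

hs = estimap_suitability(lulc, table, bio, species, EstimapParams())
ps = pollinator_supply(lulc, bio, species, table=table)


def max_jump(r):
    return max(np.abs(np.diff(r.values, axis=0)).max(), np.abs(np.diff(r.values, axis=1)).max())


print(f"largest adjacent-cell jump, distance-decay model: {max_jump(hs):.4f}")
print(f"largest adjacent-cell jump, nesting-anchored model: {max_jump(ps):.4f}")

c = 0.5
uni = Raster(GridSpec(12, 12, 10.0), np.full((12, 12), 1, dtype=np.int64))
t1 = ClassTable(pd.DataFrame([{"code": 1, "name": "m", "group": "g"}]))
b1 = BiophysicalTable(
    pd.DataFrame([{"code": 1, "nest_cavity": c, "nest_ground": c, "floral_spring": c, "floral_summer": c}])
)
hs_u = estimap_suitability(uni, t1, b1, species)
ps_u = pollinator_supply(uni, b1, species, table=t1)
print(f"uniform landscape c={c}: distance-decay index {hs_u.values[0,0]:.2f}, supply {ps_u.values[0,0]:.2f}")
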