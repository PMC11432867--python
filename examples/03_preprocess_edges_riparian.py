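"""Forest-edge bands and riparian zones.

Forest edges are strongly favorable for wild bees, so each forest patch's
outer 15 m is relabeled to a per-forest-type edge class before modelling;
land bordering water becomes a riparian zone (at least one cell wide even
when the buffer is narrower than a cell). Only labels change — the total
forest area is conserved.
"""

import numpy as np
import pandas as pd

from pollimap import derive_forest_edges, derive_riparian_zones
from pollimap.grids import ClassTable, GridSpec, Raster

vals = np.full((9, 9), 1, dtype=np.int64)
vals[2:7, 2:7] = 5   # a 5x5 forest block
vals[:, 8] = 7       # a river along the east edge
lulc = Raster(GridSpec(9, 9, 10.0), vals)
table = ClassTable(
    pd.DataFrame(
        [
            {"code": 1, "name": "arable", "group": "arable and horticultural"},
            {"code": 5, "name": "oak forest", "group": "forests", "is_forest": True},
            {"code": 7, "name": "river", "group": "inland waters", "is_water": True},
        ]
    )
)

lulc, table = derive_forest_edges(lulc, table, edge_width_m=15.0)
lulc, table = derive_riparian_zones(lulc, table, width_m=4.0)

forest = (lulc.values == 5).sum()
edge = (lulc.values == 1005).sum()
riparian = (lulc.values == table.df.index.max()).sum()
print(f"forest interior cells: {forest}, edge cells: {edge} (total {forest+edge} = original 25)")
print(f"riparian cells along the river: {riparian}")
print(lulc.values)
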