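"""Build a composite reference bee and collapse a biophysical table to
scalar nesting/floral layers.

The reference species averages the flight distances of real wild-bee
species and assumes full use of both nesting substrates and both seasons.
Its traits turn the substrate/season-resolved class table into the two
scalar rasters (FA, NA) the models consume.
"""

import numpy as np
import pandas as pd

from pollimap import build_reference_species, derive_scalar_layers
from pollimap.biophysical import BiophysicalTable
from pollimap.grids import GridSpec, Raster

species_table = pd.DataFrame(
    {
        "species": ["Andrena flavipes", "Lasioglossum calceatum", "Osmia bicornis"],
        "flight_distance_m": [600.0, 680.0, 760.0],
    }
)
bee = build_reference_species(species_table)
print(f"reference species flight distance: {bee.flight_distance_m:.0f} m")

bio = BiophysicalTable(
    pd.DataFrame(
        {
            "code": [1, 2],
            "nest_cavity": [0.2, 0.8],
            "nest_ground": [0.6, 0.5],
            "floral_spring": [0.3, 0.9],
            "floral_summer": [0.5, 0.7],
        }
    )
)
lulc = Raster(GridSpec(1, 2, 10.0), np.array([[1, 2]]))
fa, na = derive_scalar_layers(lulc, bio, bee)
print(f"class 1: NA={na.values[0,0]:.2f} (max of substrates), FA={fa.values[0,0]:.2f} (season mean)")
print(f"class 2: NA={na.values[0,1]:.2f}, FA={fa.values[0,1]:.2f}")
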