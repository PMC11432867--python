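import numpy as np
import pandas as pd
import pytest

from pollimap.biophysical import BiophysicalTable, SpeciesTraits
from pollimap.grids import ClassTable, GridSpec, Raster


@pytest.fixture
def species():
    return SpeciesTraits()


@pytest.fixture
def two_class_table():
    return ClassTable(
        pd.DataFrame(
            [
                {"code": 1, "name": "arable", "group": "arable"},
                {"code": 2, "name": "meadow", "group": "meadow", "is_favorable": True},
            ]
        )
    )


def make_raster(values, cell_size=10.0, nodata=-9999):
    values = np.asarray(values)
    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        cell_size=cell_size,
        nodata=nodata,
    )
    return Raster(spec, values)


def uniform_bio(codes, c):
    """Biophysical table with every field equal to c for the given codes."""
    return BiophysicalTable(
        pd.DataFrame(
            [
                {
                    "code": k,
                    "nest_cavity": c,
                    "nest_ground": c,
                    "floral_spring": c,
                    "floral_summer": c,
                }
                for k in codes
            ]
        )
    )


@pytest.fixture
def homogeneous(two_class_table):
    """20x20 single-class landscape with all biophysical values 0.6."""
    lulc = make_raster(np.full((20, 20), 1, dtype=np.int64))
    bio = uniform_bio([1, 2], 0.6)
    return lulc, two_class_table, bio


def brute_force_smooth(values, valid, cell_size, alpha, trunc_fraction=0.01):
    """Independent O(n^2) normalized-kernel smoothing."""
    import math

    trunc = alpha * math.log(1 / trunc_fraction)
    n_rows, n_cols = values.shape
    out = np.full(values.shape, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            num = den = 0.0
            for r2 in range(n_rows):
                for c2 in range(n_cols):
                    if not valid[r2, c2]:
                        continue
                    d = cell_size * math.hypot(r - r2, c - c2)
                    if d > trunc:
                        continue
                    w = math.exp(-d / alpha)
                    num += w * values[r2, c2]
                    den += w
            if den > 0:
                out[r, c] = num / den
    return out


def brute_force_distance(mask, cell_size):
    """Independent all-pairs Euclidean distance to nearest True cell."""
    import math

    n_rows, n_cols = mask.shape
    pts = np.argwhere(mask)
    out = np.full(mask.shape, np.inf)
    for r in range(n_rows):
        for c in range(n_cols):
            for r2, c2 in pts:
                d = cell_size * math.hypot(r - r2, c - c2)
                if d < out[r, c]:
                    out[r, c] = d
    return out
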