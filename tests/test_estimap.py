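import math

import numpy as np
import pandas as pd
import pytest

from pollimap.biophysical import derive_scalar_layers
from pollimap.estimap import (
    EstimapParams,
    estimap_suitability,
    favorable_influence,
    local_score,
    road_penalty,
)
from pollimap.grids import ClassTable, ValidationError
from pollimap.kernels import build_exponential_kernel, smooth_weighted_mean

from conftest import make_raster, uniform_bio


def mixed_fixture(seed=13):
    """16x16 three-class landscape: matrix, favorable meadow, road."""
    rng = np.random.default_rng(seed)
    vals = rng.choice([1, 2, 3], size=(16, 16), p=[0.7, 0.2, 0.1]).astype(np.int64)
    lulc = make_raster(vals)
    table = ClassTable(
        pd.DataFrame(
            [
                {"code": 1, "name": "arable", "group": "arable"},
                {"code": 2, "name": "meadow", "group": "meadow", "is_favorable": True},
                {"code": 3, "name": "road", "group": "roads", "is_road": True},
            ]
        )
    )
    bio = pd.DataFrame(
        {
            "code": [1, 2, 3],
            "nest_cavity": [0.2, 0.8, 0.0],
            "nest_ground": [0.3, 0.9, 0.1],
            "floral_spring": [0.3, 0.9, 0.0],
            "floral_summer": [0.2, 0.7, 0.0],
        }
    )
    from pollimap.biophysical import BiophysicalTable

    return lulc, table, BiophysicalTable(bio)


class TestLocalScore:
    def test_equal_layers_invariant_in_weight(self):
        fa = make_raster(np.full((4, 4), 0.4))
        na = make_raster(np.full((4, 4), 0.4))
        for w in (0.0, 0.3, 1.0):
            assert np.allclose(local_score(fa, na, w).values, 0.4)

    def test_weighting(self):
        fa = make_raster(np.ones((2, 2)))
        na = make_raster(np.zeros((2, 2)))
        assert np.allclose(local_score(fa, na, 0.5).values, 0.5)
        assert np.allclose(local_score(fa, na, 1.0).values, 1.0)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValidationError):
            local_score(make_raster(np.zeros((2, 2))), make_raster(np.zeros((3, 3))), 0.5)


class TestFavorableInfluence:
    def test_favorable_cell_reads_one_and_decays(self, species):
        vals = np.full((1, 9), 1, dtype=np.int64)
        vals[0, 0] = 2
        lulc = make_raster(vals, cell_size=680.0)  # one cell = one flight distance
        table = ClassTable(
            pd.DataFrame(
                [
                    {"code": 1, "name": "a", "group": "g"},
                    {"code": 2, "name": "fav", "group": "g", "is_favorable": True},
                ]
            )
        )
        inf = favorable_influence(lulc, table, species)
        assert inf.values[0, 0] == pytest.approx(1.0)
        assert inf.values[0, 1] == pytest.approx(math.exp(-1))

    def test_no_favorable_class_gives_zero(self, species):
        lulc = make_raster(np.full((3, 3), 1, dtype=np.int64))
        table = ClassTable(pd.DataFrame([{"code": 1, "name": "a", "group": "g"}]))
        assert np.allclose(favorable_influence(lulc, table, species).values, 0.0)


class TestRoadPenalty:
    def test_on_road_and_asymptote(self):
        lulc, table, _ = mixed_fixture()
        params = EstimapParams(p_road=0.4, beta_road_m=50)
        r = road_penalty(lulc, table, params)
        roads = lulc.values == 3
        assert np.allclose(r.values[roads], 0.6)
        assert r.values.max() <= 1.0
        assert r.values.min() >= 0.6

    def test_zero_penalty_is_identity(self):
        lulc, table, _ = mixed_fixture()
        r = road_penalty(lulc, table, EstimapParams(p_road=0.0))
        assert np.allclose(r.values, 1.0)


class TestSuitability:
    def test_homogeneous_closed_form(self, homogeneous, species):
        lulc, table, bio = homogeneous
        hs = estimap_suitability(lulc, table, bio, species)
        # no favorable cells, no roads: HS = smoothed constant = c
        assert np.allclose(hs.values, 0.6, atol=1e-9)

    def test_excluded_water_is_exactly_zero(self, species):
        vals = np.array([[1, 9], [1, 1]], dtype=np.int64)
        table = ClassTable(
            pd.DataFrame(
                [
                    {"code": 1, "name": "meadow", "group": "g", "is_favorable": True},
                    {"code": 9, "name": "lake", "group": "water", "is_water": True},
                ]
            )
        )
        bio = uniform_bio([1], 0.8)
        bio.df.loc[9] = [9, 0.0, 0.0, 0.0, 0.0]
        hs = estimap_suitability(make_raster(vals), table, bio, species)
        assert hs.values[0, 1] == 0.0
        assert hs.values[0, 0] > 0

    def test_composition_of_component_operations(self, species):
        lulc, table, bio = mixed_fixture()
        params = EstimapParams()
        hs = estimap_suitability(lulc, table, bio, species, params)

        kernel = build_exponential_kernel(
            species.flight_distance_m, 10.0, params.trunc_weight_fraction
        )
        fa, na = derive_scalar_layers(lulc, bio, species)
        s = smooth_weighted_mean(local_score(fa, na, params.w_f), kernel).values
        i = favorable_influence(lulc, table, species).values
        r = road_penalty(lulc, table, params).values
        expected = np.clip((s + params.lam * i * (1 - s)) * r, 0, 1)
        assert np.allclose(hs.values, expected, atol=1e-12)

    def test_bounded_and_monotone_in_biophysical(self, species):
        lulc, table, bio = mixed_fixture()
        hs0 = estimap_suitability(lulc, table, bio, species)
        assert hs0.values.min() >= 0 and hs0.values.max() <= 1
        bumped = bio.df.copy().reset_index(drop=True)
        bumped.loc[bumped["code"] == 1, "floral_summer"] = 0.9
        from pollimap.biophysical import BiophysicalTable

        hs1 = estimap_suitability(lulc, table, BiophysicalTable(bumped), species)
        assert (hs1.values >= hs0.values - 1e-12).all()

    def test_favorable_cells_rated_at_least_smoothed_score(self, species):
        lulc, table, bio = mixed_fixture()
        params = EstimapParams(p_road=0.0)  # roads permitting
        hs = estimap_suitability(lulc, table, bio, species, params)
        kernel = build_exponential_kernel(species.flight_distance_m, 10.0)
        fa, na = derive_scalar_layers(lulc, bio, species)
        s = smooth_weighted_mean(local_score(fa, na, params.w_f), kernel).values
        fav = lulc.values == 2
        assert (hs.values[fav] >= s[fav] - 1e-12).all()
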