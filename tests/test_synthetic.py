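import numpy as np
import pytest

from pollimap.biophysical import aggregate_expert_survey
from pollimap.grids import ValidationError, validate_lulc
from pollimap.synthetic import (
    CODES,
    GROUP_ARCHETYPES,
    LandscapeConfig,
    generalize_landscape,
    generate_biophysical,
    generate_landscape,
    paired_landscapes,
)

SMALL = dict(
    n_rows=64, n_cols=64, n_forest_patches=2, patch_radius_range=(6, 9),
    n_seminatural_patches=4, road_spacing=24, lake_radius_range=(4, 6),
)


class TestGenerate:
    def test_deterministic_per_seed(self):
        a, _ = generate_landscape(LandscapeConfig(**SMALL, seed=7))
        b, _ = generate_landscape(LandscapeConfig(**SMALL, seed=7))
        c, _ = generate_landscape(LandscapeConfig(**SMALL, seed=8))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_zero_hedgerow_density(self):
        lulc, _ = generate_landscape(LandscapeConfig(**SMALL, hedgerow_density=0.0, seed=1))
        assert (lulc.values == CODES["hedgerow"]).sum() == 0

    def test_every_code_covered_by_class_table(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=3))
        assert validate_lulc(lulc, table) == []

    def test_expected_structures_present(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=42))
        present = set(np.unique(lulc.values))
        for key in ("arable", "road_major", "hedgerow", "river"):
            assert CODES[key] in present
        # preprocessing ran: at least one forest-edge class exists
        assert table.df["is_forest_edge"].any()

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValidationError, match="80%"):
            generate_landscape(
                LandscapeConfig(n_rows=20, n_cols=20, n_forest_patches=50,
                                patch_radius_range=(10, 10))
            )


class TestGeneralize:
    def test_identity_settings(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=5))
        out = generalize_landscape(lulc, table, min_patch_cells=1, drop_linear=False)
        assert np.array_equal(out.values, lulc.values)

    def test_small_linear_feature_absorbed_into_matrix(self):
        lulc, table = generate_landscape(
            LandscapeConfig(**SMALL, seed=5, hedgerow_density=2.0)
        )
        assert (lulc.values == CODES["hedgerow"]).sum() > 0
        out = generalize_landscape(lulc, table, min_patch_cells=10)
        assert (out.values == CODES["hedgerow"]).sum() == 0

    def test_major_roads_retained(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=5))
        out = generalize_landscape(lulc, table, min_patch_cells=40)
        roads = lulc.values == CODES["road_major"]
        assert (out.values[roads] == CODES["road_major"]).all()

    def test_cell_count_conserved(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=6))
        out = generalize_landscape(lulc, table, min_patch_cells=40)
        assert out.values.shape == lulc.values.shape
        assert out.values.size == lulc.values.size

    def test_strictly_fewer_favorable_cells(self):
        lulc, table = generate_landscape(LandscapeConfig(**SMALL, seed=9))
        out = generalize_landscape(lulc, table, min_patch_cells=40)
        before = table.mask_where(lulc, "is_favorable").sum()
        after = table.mask_where(out, "is_favorable").sum()
        assert after < before

    def test_paired_landscapes_share_grid_and_edges(self):
        (la, ta), (lb, tb) = paired_landscapes(
            LandscapeConfig(**SMALL, seed=11), min_patch_cells=40
        )
        assert la.spec == lb.spec
        assert tb.df["is_forest_edge"].any()
        assert validate_lulc(lb, tb) == []


class TestBiophysical:
    def test_water_all_zero_in_both_modes(self):
        _, table = generate_landscape(LandscapeConfig(**SMALL, seed=1))
        lit = generate_biophysical(table, mode="literature")
        exp, _survey = generate_biophysical(table, mode="expert", seed=1)
        for bio in (lit, exp):
            row = bio.df.loc[CODES["lake"]]
            assert row[["nest_cavity", "nest_ground", "floral_spring", "floral_summer"]].sum() == 0

    def test_sigma_zero_expert_equals_archetype(self):
        _, table = generate_landscape(LandscapeConfig(**SMALL, seed=1))
        lit = generate_biophysical(table, mode="literature")
        exp, survey = generate_biophysical(table, mode="expert", seed=1, sigma=0.0)
        assert np.allclose(exp.df[lit.df.columns[1:]].to_numpy(),
                           lit.df[lit.df.columns[1:]].to_numpy())
        agg = aggregate_expert_survey(survey)
        assert ((agg >= 0) & (agg <= 1)).all().all()

    def test_archetype_ordering(self):
        def level(group):
            na, fa = GROUP_ARCHETYPES[group]
            return (na + fa) / 2

        semi = min(
            level("heathland and rough grassland"),
            level("herbaceous and ruderal vegetation"),
        )
        assert semi > level("forest edge")
        assert level("forest edge") > level("forests")
        assert level("forests") >= level("pastureland")
        assert level("pastureland") > level("arable and horticultural")
        assert level("arable and horticultural") > level("roads")
        assert level("roads") >= level("rock, stone and open ground")
        assert level("inland waters") == 0.0

    def test_literature_values_follow_ordering_in_generated_table(self):
        _, table = generate_landscape(LandscapeConfig(**SMALL, seed=2))
        bio = generate_biophysical(table, mode="literature")
        heath = bio.df.loc[CODES["heath"]]
        arable = bio.df.loc[CODES["arable"]]
        assert (heath[1:] >= arable[1:]).all()

    def test_unknown_group_rejected(self):
        from pollimap.grids import ClassTable
        import pandas as pd

        t = ClassTable(pd.DataFrame([{"code": 1, "name": "x", "group": "moonbase"}]))
        with pytest.raises(ValidationError, match="moonbase"):
            generate_biophysical(t, mode="literature")

    def test_expert_mode_deterministic_per_seed(self):
        _, table = generate_landscape(LandscapeConfig(**SMALL, seed=1))
        a, sa = generate_biophysical(table, mode="expert", seed=5)
        b, sb = generate_biophysical(table, mode="expert", seed=5)
        assert a.df.equals(b.df)
        assert sa.df.equals(sb.df)
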