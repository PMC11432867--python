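import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from pollimap.compare import (
    Dataset,
    run_comparison_experiment,
    similarity_map,
    zonal_summary,
)
from pollimap.grids import ClassTable, ValidationError
from pollimap.synthetic import LandscapeConfig, generate_biophysical, paired_landscapes

from conftest import make_raster


class TestSimilarity:
    def test_identical_maps_give_one(self):
        a = make_raster(np.random.default_rng(0).random((6, 6)))
        assert np.allclose(similarity_map(a, a).values, 1.0)

    def test_paired_zero_values_give_one(self):
        # open water scores 0.00 under both models; the similarity of the
        # pair (0.00, 0.00) is exactly 1.00
        a = make_raster(np.array([[0.00]]))
        b = make_raster(np.array([[0.00]]))
        assert similarity_map(a, b).values[0, 0] == pytest.approx(1.00)

    def test_arithmetic(self):
        a = make_raster(np.array([[0.9]]))
        b = make_raster(np.array([[0.2]]))
        assert similarity_map(a, b).values[0, 0] == pytest.approx(0.3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=hnp.arrays(np.float64, (4, 4), elements=st.floats(0, 1)),
        b=hnp.arrays(np.float64, (4, 4), elements=st.floats(0, 1)),
    )
    def test_symmetric_and_bounded(self, a, b):
        ra, rb = make_raster(a), make_raster(b)
        s1, s2 = similarity_map(ra, rb), similarity_map(rb, ra)
        assert np.array_equal(s1.values, s2.values)
        assert s1.values.min() >= 0 and s1.values.max() <= 1

    def test_nodata_propagates(self):
        a = make_raster(np.array([[0.5, -9999.0]]))
        b = make_raster(np.array([[0.5, 0.5]]))
        s = similarity_map(a, b)
        assert s.nodata_mask[0, 1]

    def test_misaligned_rejected(self):
        with pytest.raises(ValidationError):
            similarity_map(make_raster(np.zeros((2, 2))), make_raster(np.zeros((3, 3))))


class TestZonalSummary:
    def make_table(self):
        return ClassTable(
            pd.DataFrame(
                [
                    {"code": 1, "name": "a", "group": "g1"},
                    {"code": 2, "name": "b", "group": "g1"},
                    {"code": 3, "name": "c", "group": "g2"},
                ]
            )
        )

    def test_constant_zone(self):
        lulc = make_raster(np.full((4, 4), 1, dtype=np.int64))
        vals = make_raster(np.full((4, 4), 0.7))
        df = zonal_summary(vals, lulc, self.make_table(), by="class")
        row = df[df.zone == "1"].iloc[0]
        assert row["median"] == pytest.approx(0.7)
        assert row["std"] == 0.0
        assert row["n_cells"] == 16

    def test_median_is_order_statistic(self):
        lulc = make_raster(np.array([[1, 1, 1]], dtype=np.int64))
        vals = make_raster(np.array([[0.1, 0.2, 0.9]]))
        df = zonal_summary(vals, lulc, self.make_table(), by="class")
        assert df[df.zone == "1"].iloc[0]["median"] == pytest.approx(0.2)

    def test_group_medians_match_brute_force_sort(self):
        rng = np.random.default_rng(30)
        lulc = make_raster(rng.integers(1, 4, size=(30, 30)).astype(np.int64))
        vals = make_raster(rng.random((30, 30)))
        df = zonal_summary(vals, lulc, self.make_table(), by="group").set_index("zone")
        for group, codes in (("g1", [1, 2]), ("g2", [3])):
            pool = np.sort(vals.values[np.isin(lulc.values, codes)])
            n = len(pool)
            med = pool[n // 2] if n % 2 else 0.5 * (pool[n // 2 - 1] + pool[n // 2])
            assert df.loc[group, "median"] == pytest.approx(med, abs=1e-12)
            assert df.loc[group, "n_cells"] == n

    def test_population_std_default_and_sample_option(self):
        lulc = make_raster(np.array([[1, 1]], dtype=np.int64))
        vals = make_raster(np.array([[0.0, 1.0]]))
        t = self.make_table()
        assert zonal_summary(vals, lulc, t, by="class").iloc[0]["std"] == pytest.approx(0.5)
        assert zonal_summary(vals, lulc, t, by="class", ddof=1).iloc[0]["std"] == pytest.approx(
            np.sqrt(0.5)
        )

    def test_cellwise_median_differs_from_median_similarity_fallacy(self):
        # zones where the two maps disagree on *which* cells are good can
        # pair very different medians with high cell-wise similarity
        lulc = make_raster(np.full((1, 4), 1, dtype=np.int64))
        a = make_raster(np.array([[0.9, 0.1, 0.9, 0.1]]))
        b = make_raster(np.array([[0.8, 0.2, 0.8, 0.2]]))
        s = similarity_map(a, b)
        df = zonal_summary(s, lulc, self.make_table(), by="class")
        cellwise = df.iloc[0]["median"]
        assert cellwise == pytest.approx(0.9)
        fallacy = 1 - abs(np.median(a.values) - np.median(b.values))
        assert fallacy == pytest.approx(1.0)
        assert cellwise != fallacy

    def test_empty_zone_omitted(self):
        lulc = make_raster(np.full((2, 2), 1, dtype=np.int64))
        vals = make_raster(np.full((2, 2), 0.5))
        df = zonal_summary(vals, lulc, self.make_table(), by="group")
        assert "g2" not in set(df.zone)
        assert "all" in set(df.zone)


def small_experiment(seed=42):
    cfg = LandscapeConfig(
        n_rows=48, n_cols=48, n_forest_patches=2, patch_radius_range=(5, 7),
        n_seminatural_patches=3, road_spacing=20, lake_radius_range=(3, 4),
        seed=seed,
    )
    (la, ta), (lb, tb) = paired_landscapes(cfg, min_patch_cells=25)
    return (
        Dataset(la, ta, generate_biophysical(ta, mode="literature"), "detailed"),
        Dataset(lb, tb, generate_biophysical(tb, mode="literature"), "generalized"),
    )


class TestExperiment:
    def test_bundle_contract(self, species):
        a, b = small_experiment()
        bundle = run_comparison_experiment(a, b, species)
        assert len(bundle.rasters) == 8
        assert len(bundle.summaries) == 9
        assert "combined" in bundle.summaries
        assert bundle.manifest["species"]["flight_distance_m"] == 680.0

    def test_identical_datasets_give_similarity_one(self, species):
        a, _ = small_experiment()
        bundle = run_comparison_experiment(a, a, species)
        for key in ("sim_datasets_estimap", "sim_datasets_invest"):
            s = bundle.rasters[key]
            assert np.allclose(s.valid_values(), 1.0)

    def test_repeat_runs_bit_identical(self, species):
        a1, b1 = small_experiment()
        a2, b2 = small_experiment()
        r1 = run_comparison_experiment(a1, b1, species)
        r2 = run_comparison_experiment(a2, b2, species)
        for key in r1.rasters:
            assert np.array_equal(r1.rasters[key].values, r2.rasters[key].values)

    def test_bundle_saves_to_disk(self, tmp_path, species):
        a, b = small_experiment()
        bundle = run_comparison_experiment(a, b, species)
        out = bundle.save(tmp_path / "bundle")
        assert len(list(out.glob("*.asc"))) == 8
        assert len(list(out.glob("summary_*.csv"))) == 9
        assert (out / "manifest.json").exists()
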