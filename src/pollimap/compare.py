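"""Map comparison: cell-wise similarity index, zonal summaries, and the
two-models-by-two-datasets experiment driver.

The similarity index follows the cell-by-cell numerical comparison of the
Map Comparison Kit: ``S = 1 - |a - b|`` per cell, so 1 means identical and
0 maximally different. Zonal medians of similarity are medians of the
cell-wise similarity raster — never the similarity of zonal medians, which
is a different (and misleading) number: a zone can pair very different
medians with high cell-wise similarity when the maps disagree about
*which* cells are good.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biophysical import BiophysicalTable, SpeciesTraits
from .estimap import EstimapParams, estimap_suitability
from .grids import ClassTable, Raster, ValidationError, _require_aligned, save_raster
from .invest import InvestParams, pollinator_abundance, pollinator_supply
from .kernels import build_exponential_kernel

import logging

log = logging.getLogger(__name__)

__all__ = [
    "similarity_map",
    "zonal_summary",
    "Dataset",
    "ExperimentBundle",
    "run_comparison_experiment",
]


def similarity_map(a: Raster, b: Raster) -> Raster:
    """Cell-wise similarity ``S = 1 - |a - b|`` for maps valued in [0, 1].

    Symmetric, bounded in [0, 1], S(a, a) = 1; nodata wherever either
    input is nodata.
    """
    _require_aligned(a, b)
    valid = a.valid_mask & b.valid_mask
    for r in (a, b):
        v = r.values[r.valid_mask]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValidationError("similarity inputs must be in [0,1]")
    out = np.full(a.spec.shape, float(a.spec.nodata))
    out[valid] = 1.0 - np.abs(a.values[valid] - b.values[valid])
    return Raster(a.spec, out)


def zonal_summary(
    values: Raster,
    lulc: Raster,
    table: ClassTable,
    by: str = "group",
    ddof: int = 0,
) -> pd.DataFrame:
    """Median, mean and standard deviation of a value raster per zone.

    Zones are class codes (``by="class"``) or thematic groups
    (``by="group"``). Statistics are taken over the individual non-nodata
    cells of each zone — statistics of cell values, never statistics of
    per-class statistics. The standard deviation is the population formula
    (divisor n) by default; pass ``ddof=1`` for the sample formula. A
    whole-map row labeled ``"all"`` covers every valid cell, excluded
    classes included (their zeros are part of the map-wide median). Empty
    zones are omitted with a logged warning.
    """
    if by not in ("class", "group"):
        raise ValueError(f"by must be 'class' or 'group', got {by!r}")
    _require_aligned(values, lulc)
    valid = values.valid_mask & lulc.valid_mask
    rows = []
    if by == "class":
        zones = [(str(int(c)), np.asarray([c])) for c in table.codes]
    else:
        zones = [
            (g, table.df.loc[table.df["group"] == g, "code"].to_numpy())
            for g in table.groups()
        ]
    for label, codes in zones:
        m = valid & np.isin(lulc.values, codes)
        v = values.values[m]
        if v.size == 0:
            log.warning("zonal_summary: zone %r is empty, omitted", label)
            continue
        rows.append(_stats_row(label, v, ddof))
    rows.append(_stats_row("all", values.values[valid], ddof))
    return pd.DataFrame(rows, columns=["zone", "median", "mean", "std", "n_cells"])


def _stats_row(label: str, v: np.ndarray, ddof: int) -> dict:
    return {
        "zone": label,
        "median": float(np.median(v)),
        "mean": float(np.mean(v)),
        "std": float(np.std(v, ddof=ddof)),
        "n_cells": int(v.size),
    }


@dataclass
class Dataset:
    """One land-use dataset ready for modelling: raster + class table +
    biophysical table."""

    lulc: Raster
    table: ClassTable
    bio: BiophysicalTable
    name: str = "dataset"


@dataclass
class ExperimentBundle:
    """Everything the 2-models x 2-datasets experiment produces.

    ``rasters`` holds 8 maps: a suitability map per model/dataset pair,
    a model-vs-model similarity map per dataset, and a dataset-vs-dataset
    similarity map per model. ``summaries`` holds one zonal table per map
    plus a combined long-format table under ``"combined"``.
    """

    rasters: dict[str, Raster]
    summaries: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, r in self.rasters.items():
            save_raster(r, out / f"{name}.asc")
        for name, df in self.summaries.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def run_comparison_experiment(
    dataset_a: Dataset,
    dataset_b: Dataset,
    species: SpeciesTraits,
    estimap_params: EstimapParams | None = None,
    invest_params: InvestParams | None = None,
) -> ExperimentBundle:
    """Run both models on both datasets and compare every pair.

    All four rasters must share one grid (no resampling). The zonal
    grouping of dataset-vs-dataset similarity maps follows dataset A's
    class table (the detailed dataset in the paired-landscape setting).
    """
    estimap_params = estimap_params or EstimapParams()
    invest_params = invest_params or InvestParams()
    _require_aligned(dataset_a.lulc, dataset_b.lulc)

    kernel = build_exponential_kernel(
        species.flight_distance_m,
        dataset_a.lulc.spec.cell_size,
        estimap_params.trunc_weight_fraction,
    )

    rasters: dict[str, Raster] = {}
    for ds, tag in ((dataset_a, "a"), (dataset_b, "b")):
        rasters[f"estimap_{tag}"] = estimap_suitability(
            ds.lulc, ds.table, ds.bio, species, estimap_params, kernel=kernel
        )
        supply = pollinator_supply(
            ds.lulc, ds.bio, species, kernel=kernel, table=ds.table
        )
        if invest_params.output_kind == "abundance":
            rasters[f"invest_{tag}"] = pollinator_abundance(
                supply, species, kernel=kernel
            )
        else:
            rasters[f"invest_{tag}"] = supply

    rasters["sim_models_a"] = similarity_map(rasters["estimap_a"], rasters["invest_a"])
    rasters["sim_models_b"] = similarity_map(rasters["estimap_b"], rasters["invest_b"])
    rasters["sim_datasets_estimap"] = similarity_map(
        rasters["estimap_a"], rasters["estimap_b"]
    )
    rasters["sim_datasets_invest"] = similarity_map(
        rasters["invest_a"], rasters["invest_b"]
    )

    zone_source = {
        "estimap_a": dataset_a,
        "invest_a": dataset_a,
        "sim_models_a": dataset_a,
        "estimap_b": dataset_b,
        "invest_b": dataset_b,
        "sim_models_b": dataset_b,
        "sim_datasets_estimap": dataset_a,
        "sim_datasets_invest": dataset_a,
    }
    summaries: dict[str, pd.DataFrame] = {}
    combined = []
    for name, ds in zone_source.items():
        df = zonal_summary(rasters[name], ds.lulc, ds.table, by="group")
        summaries[name] = df
        combined.append(df.assign(map=name))
    summaries["combined"] = pd.concat(combined, ignore_index=True)

    manifest = {
        "datasets": {"a": dataset_a.name, "b": dataset_b.name},
        "species": {
            "flight_distance_m": species.flight_distance_m,
            "nest_pref_cavity": species.nest_pref_cavity,
            "nest_pref_ground": species.nest_pref_ground,
            "activity_spring": species.activity_spring,
            "activity_summer": species.activity_summer,
            "relative_abundance": species.relative_abundance,
        },
        "estimap_params": {
            k: getattr(estimap_params, k) for k in estimap_params.__dataclass_fields__
        },
        "invest_params": {
            k: getattr(invest_params, k) for k in invest_params.__dataclass_fields__
        },
        "grid": {
            "n_rows": dataset_a.lulc.spec.n_rows,
            "n_cols": dataset_a.lulc.spec.n_cols,
            "cell_size_m": dataset_a.lulc.spec.cell_size,
        },
        "kernel_truncation_m": kernel.truncation_radius_m,
    }
    return ExperimentBundle(rasters=rasters, summaries=summaries, manifest=manifest)
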