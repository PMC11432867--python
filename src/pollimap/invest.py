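"""Nesting-by-floral pollinator supply (InVEST/Lonsdorf-style).

Supply at a cell is the product of its nesting suitability and the
kernel-weighted floral resources reachable from it:

    PS(x) = HN(x) * sum_y w(d(x,y)) FR(y) / sum_y w(d(x,y))

with the same exponential foraging kernel as the distance-decay model.
Because nesting multiplies rather than diffuses, class boundaries appear
as hard value jumps — a cell of an unsuitable class scores 0 however rich
its neighborhood. Pollinator abundance additionally smooths the supply
(bees forage away from the nest) and scales by relative abundance.

The single reference species collapses the source model's multi-species
weighted sum to one term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophysical import BiophysicalTable, SpeciesTraits
from .grids import ClassTable, Raster, ValidationError
from .kernels import Kernel, build_exponential_kernel, smooth_weighted_mean

__all__ = [
    "InvestParams",
    "habitat_nesting",
    "seasonal_floral",
    "pollinator_supply",
    "pollinator_abundance",
]


@dataclass(frozen=True)
class InvestParams:
    """Which map the model reports: nest-anchored ``supply`` (default,
    the headline suitability map) or foraging-smoothed ``abundance``."""

    output_kind: str = "supply"
    trunc_weight_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.output_kind not in ("supply", "abundance"):
            raise ValidationError(
                f"output_kind must be 'supply' or 'abundance', got {self.output_kind!r}"
            )
        if not (0 < self.trunc_weight_fraction < 1):
            raise ValidationError("trunc_weight_fraction must be in (0,1)")


def habitat_nesting(
    lulc: Raster, bio: BiophysicalTable, species: SpeciesTraits
) -> Raster:
    """HN(x) = max(cavity value x cavity pref, ground value x ground pref)."""
    nodata = lulc.spec.nodata
    cav = bio.lookup("nest_cavity", lulc.values, nodata)
    grd = bio.lookup("nest_ground", lulc.values, nodata)
    valid = lulc.valid_mask
    out = np.full(lulc.spec.shape, float(nodata))
    out[valid] = np.maximum(
        cav[valid] * species.nest_pref_cavity,
        grd[valid] * species.nest_pref_ground,
    )
    return Raster(lulc.spec, out)


def seasonal_floral(
    lulc: Raster, bio: BiophysicalTable, species: SpeciesTraits
) -> Raster:
    """Activity-weighted mean of spring and summer floral values."""
    total = species.activity_spring + species.activity_summer
    if total <= 0:
        raise ValidationError("total seasonal activity must be > 0")
    nodata = lulc.spec.nodata
    spr = bio.lookup("floral_spring", lulc.values, nodata)
    smr = bio.lookup("floral_summer", lulc.values, nodata)
    valid = lulc.valid_mask
    out = np.full(lulc.spec.shape, float(nodata))
    out[valid] = (
        species.activity_spring * spr[valid] + species.activity_summer * smr[valid]
    ) / total
    return Raster(lulc.spec, out)


def pollinator_supply(
    lulc: Raster,
    bio: BiophysicalTable,
    species: SpeciesTraits,
    kernel: Kernel | None = None,
    table: ClassTable | None = None,
) -> Raster:
    """PS = HN x smoothed FR, the nest-anchored suitability map in [0, 1].

    Seasonal floral values are aggregated before the single kernel pass.
    Supply is exactly 0 wherever nesting is 0 (the model's hard borders).
    """
    if table is not None:
        bio.check_against(table)
    hn = habitat_nesting(lulc, bio, species)
    fr = seasonal_floral(lulc, bio, species)
    if kernel is None:
        kernel = build_exponential_kernel(
            species.flight_distance_m, lulc.spec.cell_size
        )
    fr_smooth = smooth_weighted_mean(fr, kernel)
    valid = lulc.valid_mask & fr_smooth.valid_mask
    out = np.full(lulc.spec.shape, float(lulc.spec.nodata))
    out[valid] = np.clip(hn.values[valid] * fr_smooth.values[valid], 0.0, 1.0)
    return Raster(lulc.spec, out)


def pollinator_abundance(
    supply: Raster, species: SpeciesTraits, kernel: Kernel | None = None
) -> Raster:
    """PA = smoothed supply x relative abundance, clamped to [0, 1]."""
    if kernel is None:
        kernel = build_exponential_kernel(
            species.flight_distance_m, supply.spec.cell_size
        )
    sm = smooth_weighted_mean(supply, kernel)
    valid = sm.valid_mask
    out = np.full(supply.spec.shape, float(supply.spec.nodata))
    out[valid] = np.clip(sm.values[valid] * species.relative_abundance, 0.0, 1.0)
    return Raster(supply.spec, out)
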