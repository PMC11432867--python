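"""Distance-decay pollinator habitat suitability (ESTIMAP-style).

The model composes four mechanisms:

1. a local score ``L = w_f*FA + (1-w_f)*NA`` from the per-class floral and
   nesting indices;
2. kernel smoothing of L with the reference species' foraging kernel;
3. a positive exponential influence ``I = exp(-D_fav / alpha)`` radiating
   from favorable classes (semi-natural vegetation, hedgerows, forest
   edges), where ``D_fav`` is the Euclidean distance to the nearest
   favorable cell and ``alpha`` the mean flight distance;
4. a multiplicative road penalty ``R = 1 - p_road * exp(-D_road / beta)``.

The habitat-suitability index is ``HS = (S + lambda*I*(1-S)) * R`` clamped
to [0, 1], with excluded classes (water and other masked classes) forced
to exactly 0 afterwards so that e.g. open water reads 0.00 regardless of
its surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophysical import BiophysicalTable, SpeciesTraits, derive_scalar_layers
from .grids import ClassTable, Raster, ValidationError, _require_aligned
from .kernels import Kernel, build_exponential_kernel, distance_to_nearest, smooth_weighted_mean

__all__ = [
    "EstimapParams",
    "local_score",
    "favorable_influence",
    "road_penalty",
    "estimap_suitability",
]


@dataclass(frozen=True)
class EstimapParams:
    """Tunable weights of the distance-decay model.

    w_f
        Floral weight in the local score (0..1); nesting gets ``1 - w_f``.
    lam
        Strength of the favorable-area influence (0..1).
    p_road
        Depth of the road penalty at the road itself (0..1; 0 disables).
    beta_road_m
        Decay length of the road penalty, meters.
    trunc_weight_fraction
        Kernel truncation as a fraction of the center weight.
    """

    w_f: float = 0.5
    lam: float = 0.5
    p_road: float = 0.5
    beta_road_m: float = 100.0
    trunc_weight_fraction: float = 0.01

    def __post_init__(self) -> None:
        for name in ("w_f", "lam", "p_road"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.beta_road_m <= 0:
            raise ValidationError("beta_road_m must be > 0")
        if not (0 < self.trunc_weight_fraction < 1):
            raise ValidationError("trunc_weight_fraction must be in (0,1)")


def local_score(fa: Raster, na: Raster, w_f: float = 0.5) -> Raster:
    """Convex combination ``L = w_f*FA + (1-w_f)*NA`` of the scalar layers."""
    _require_aligned(fa, na)
    if not (0 <= w_f <= 1):
        raise ValidationError(f"w_f must be in [0,1], got {w_f}")
    valid = fa.valid_mask & na.valid_mask
    out = np.full(fa.spec.shape, float(fa.spec.nodata))
    out[valid] = w_f * fa.values[valid] + (1 - w_f) * na.values[valid]
    return Raster(fa.spec, out)


def favorable_influence(
    lulc: Raster, table: ClassTable, species: SpeciesTraits
) -> Raster:
    """Exponential influence of the nearest favorable cell.

    ``I(x) = exp(-D_fav(x) / flight_distance)``; favorable cells read 1.
    When the raster contains no favorable cell the influence is 0
    everywhere.
    """
    fav = table.mask_where(lulc, "is_favorable") & lulc.valid_mask
    out = np.full(lulc.spec.shape, float(lulc.spec.nodata))
    valid = lulc.valid_mask
    if not fav.any():
        out[valid] = 0.0
        return Raster(lulc.spec, out)
    d = distance_to_nearest(fav, lulc.spec.cell_size)
    out[valid] = np.exp(-d[valid] / species.flight_distance_m)
    return Raster(lulc.spec, out)


def road_penalty(lulc: Raster, table: ClassTable, params: EstimapParams) -> Raster:
    """Multiplier ``R = 1 - p_road*exp(-D_road/beta)`` in [1-p_road, 1].

    On-road cells carry the full penalty; the effect decays exponentially
    with distance and vanishes without roads (R = 1 everywhere).
    """
    out = np.full(lulc.spec.shape, float(lulc.spec.nodata))
    valid = lulc.valid_mask
    roads = table.mask_where(lulc, "is_road") & valid
    if params.p_road == 0 or not roads.any():
        out[valid] = 1.0
        return Raster(lulc.spec, out)
    d = distance_to_nearest(roads, lulc.spec.cell_size)
    out[valid] = 1.0 - params.p_road * np.exp(-d[valid] / params.beta_road_m)
    return Raster(lulc.spec, out)


def estimap_suitability(
    lulc: Raster,
    table: ClassTable,
    bio: BiophysicalTable,
    species: SpeciesTraits,
    params: EstimapParams | None = None,
    kernel: Kernel | None = None,
) -> Raster:
    """Full habitat-suitability index in [0, 1].

    ``HS = (S + lam*I*(1-S)) * R`` where S is the kernel-smoothed local
    score; excluded classes are masked to 0 after everything else, and
    nodata propagates.
    """
    params = params or EstimapParams()
    fa, na = derive_scalar_layers(lulc, bio, species, table=table)
    L = local_score(fa, na, params.w_f)
    if kernel is None:
        kernel = build_exponential_kernel(
            species.flight_distance_m,
            lulc.spec.cell_size,
            params.trunc_weight_fraction,
        )
    S = smooth_weighted_mean(L, kernel)
    I = favorable_influence(lulc, table, species)
    R = road_penalty(lulc, table, params)

    valid = lulc.valid_mask & S.valid_mask
    hs = np.full(lulc.spec.shape, float(lulc.spec.nodata))
    s = S.values[valid]
    hs[valid] = (s + params.lam * I.values[valid] * (1.0 - s)) * R.values[valid]
    hs[valid] = np.clip(hs[valid], 0.0, 1.0)
    excluded = table.mask_where(lulc, "is_excluded") & valid
    hs[excluded] = 0.0
    return Raster(lulc.spec, hs)
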