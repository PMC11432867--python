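"""Seeded synthetic landscapes emulating a detailed vs generalized
land-cover dataset pair.

Real comparisons of this kind hinge on data that are licensed or
non-public, so every pipeline stage here is exercised on generated
landscapes instead: an agricultural matrix seeded with forest blobs,
semi-natural patches, a density-graded urban block, one-cell roads and
hedgerows, a lake and a river, then run through the forest-edge and
riparian preprocessing. :func:`generalize_landscape` produces the coarse
counterpart by absorbing small patches and linear features into their
surroundings — the way a coarse-minimum-mapping-unit product loses
hedgerows and field-margin structures while keeping major roads.

Biophysical tables come in two flavours mirroring the two
parameterization routes: ``literature`` mode assigns fixed per-group
archetype values, ``expert`` mode simulates a panel of integer 0-10
ratings around those archetypes and aggregates them.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .biophysical import (
    BiophysicalTable,
    ExpertSurvey,
    aggregate_expert_survey,
)
from .grids import ClassTable, GridSpec, Raster, ValidationError
from .preprocess import derive_forest_edges, derive_riparian_zones

__all__ = [
    "LandscapeConfig",
    "CODES",
    "generate_landscape",
    "generalize_landscape",
    "generate_biophysical",
    "paired_landscapes",
    "GROUP_ARCHETYPES",
]

# class codes used by the generator
CODES = {
    "arable": 10,
    "heath": 20,
    "ruderal": 21,
    "forest_deciduous": 30,
    "forest_coniferous": 31,
    "urban_continuous": 40,
    "urban_dense": 41,
    "urban_discontinuous": 42,
    "urban_low": 43,
    "road_major": 50,
    "hedgerow": 60,
    "lake": 70,
    "river": 71,
}

_URBAN_DENSITIES = {40: 0.90, 41: 0.65, 42: 0.20, 43: 0.05}

# archetype (NA, FA) per thematic group, on the 0.1 grid of the 0-10
# questionnaire scale; ranked semi-natural > forest edge > forest >=
# pasture > arable > urban > road >= bare ground, water 0
GROUP_ARCHETYPES: dict[str, tuple[float, float]] = {
    "heathland and rough grassland": (0.9, 0.9),
    "herbaceous and ruderal vegetation": (0.8, 0.9),
    "shrubs and woody plants": (0.8, 0.7),
    "forest edge": (0.7, 0.7),
    "forests": (0.6, 0.4),
    "pastureland": (0.5, 0.4),
    "arable and horticultural": (0.2, 0.3),
    "building, traffic and industrial areas": (0.2, 0.2),
    "roads": (0.1, 0.0),
    "rock, stone and open ground": (0.1, 0.0),
    "inland waters": (0.0, 0.0),
}

# urban classes get fixed density-bracket values instead of the group
# archetype: denser sealing, lower suitability
_URBAN_ARCHETYPES = {0.90: (0.0, 0.1), 0.65: (0.1, 0.1), 0.20: (0.2, 0.2), 0.05: (0.3, 0.3)}


@dataclass(frozen=True)
class LandscapeConfig:
    """Composition knobs for the generator; defaults draw a hedgerow-rich
    mixed agricultural landscape on a 2 km x 2 km grid at 10 m cells."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size_m: float = 10.0
    n_forest_patches: int = 4
    patch_radius_range: tuple[int, int] = (10, 18)
    n_seminatural_patches: int = 8
    seminatural_radius_range: tuple[int, int] = (2, 4)
    hedgerow_density: float = 3.0  # segments per 1000 cells
    road_spacing: int = 50  # cells between road lines
    urban_fraction: float = 0.10
    lake_radius_range: tuple[int, int] = (6, 10)
    forest_edge_m: float = 15.0
    riparian_m: float = 4.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size_m <= 0:
            raise ValidationError("grid dimensions and cell size must be positive")
        if self.hedgerow_density < 0 or self.urban_fraction < 0 or self.urban_fraction >= 1:
            raise ValidationError("densities must be >= 0 and urban_fraction in [0,1)")


def _base_class_table() -> ClassTable:
    rows = [
        (10, "arable field", "arable and horticultural", {}),
        (20, "heathland", "heathland and rough grassland", {"is_favorable": True}),
        (21, "ruderal vegetation", "herbaceous and ruderal vegetation", {"is_favorable": True}),
        (30, "deciduous forest", "forests", {"is_forest": True}),
        (31, "coniferous forest", "forests", {"is_forest": True}),
        (40, "continuous urban fabric", "building, traffic and industrial areas", {"built_density": 0.90}),
        (41, "dense discontinuous urban fabric", "building, traffic and industrial areas", {"built_density": 0.65}),
        (42, "discontinuous urban fabric", "building, traffic and industrial areas", {"built_density": 0.20}),
        (43, "low-density urban fabric", "building, traffic and industrial areas", {"built_density": 0.05}),
        (50, "major road", "roads", {"is_road": True}),
        (60, "hedgerow", "shrubs and woody plants", {"is_favorable": True}),
        (70, "lake", "inland waters", {"is_water": True, "is_excluded": True}),
        (71, "river", "inland waters", {"is_water": True, "is_excluded": True}),
    ]
    recs = []
    for code, name, group, extra in rows:
        rec = {"code": code, "name": name, "group": group}
        rec.update(extra)
        recs.append(rec)
    return ClassTable(pd.DataFrame(recs))


def _disk(values: np.ndarray, r0: int, c0: int, radius: int, code: int, paint_over: np.ndarray) -> None:
    n_rows, n_cols = values.shape
    rr, cc = np.ogrid[:n_rows, :n_cols]
    disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    values[disk & paint_over] = code


def generate_landscape(config: LandscapeConfig) -> tuple[Raster, ClassTable]:
    """Draw the detailed landscape and run it through preprocessing.

    Returns the LULC raster (forest edges and riparian zones already
    derived) and its class table. Deterministic per ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.n_rows, config.n_cols
    n_cells = n_rows * n_cols

    r_forest_max = config.patch_radius_range[1]
    requested = (
        config.n_forest_patches * np.pi * r_forest_max**2
        + config.n_seminatural_patches * np.pi * config.seminatural_radius_range[1] ** 2
        + np.pi * config.lake_radius_range[1] ** 2
        + config.urban_fraction * n_cells
    )
    if requested > 0.8 * n_cells:
        raise ValidationError(
            f"requested patches cover ~{requested:.0f} cells, more than 80% "
            f"of the {n_cells}-cell grid"
        )

    values = np.full((n_rows, n_cols), CODES["arable"], dtype=np.int64)

    # urban block in the top-left corner, density graded outward
    if config.urban_fraction > 0:
        side = int(round(np.sqrt(config.urban_fraction * n_cells)))
        side = min(side, n_rows, n_cols)
        if side > 0:
            rr, cc = np.ogrid[:side, :side]
            d = np.maximum(rr, cc).astype(float) / max(side - 1, 1)
            ring = np.digitize(d, [0.25, 0.5, 0.75])  # 0..3 inner to outer
            urban_codes = np.array([40, 41, 42, 43])[ring]
            values[:side, :side] = urban_codes

    arable = values == CODES["arable"]

    # forest blobs
    for _ in range(config.n_forest_patches):
        radius = int(rng.integers(config.patch_radius_range[0], config.patch_radius_range[1] + 1))
        r0 = int(rng.integers(0, n_rows))
        c0 = int(rng.integers(0, n_cols))
        code = int(rng.choice([CODES["forest_deciduous"], CODES["forest_coniferous"]]))
        _disk(values, r0, c0, radius, code, arable)
        arable = values == CODES["arable"]

    # semi-natural patches (heath / ruderal alternating)
    for i in range(config.n_seminatural_patches):
        radius = int(
            rng.integers(
                config.seminatural_radius_range[0],
                config.seminatural_radius_range[1] + 1,
            )
        )
        r0 = int(rng.integers(0, n_rows))
        c0 = int(rng.integers(0, n_cols))
        code = CODES["heath"] if i % 2 == 0 else CODES["ruderal"]
        _disk(values, r0, c0, radius, code, arable)
        arable = values == CODES["arable"]

    # lake and a meandering one-cell river from top to bottom
    radius = int(rng.integers(config.lake_radius_range[0], config.lake_radius_range[1] + 1))
    r0 = int(rng.integers(n_rows // 4, 3 * n_rows // 4))
    c0 = int(rng.integers(n_cols // 4, 3 * n_cols // 4))
    _disk(values, r0, c0, radius, CODES["lake"], np.ones_like(values, dtype=bool))
    col = int(rng.integers(n_cols // 4, 3 * n_cols // 4))
    for r in range(n_rows):
        values[r, col] = CODES["river"]
        col = int(np.clip(col + rng.integers(-1, 2), 0, n_cols - 1))

    # hedgerows: short one-cell segments over arable only
    n_hedges = int(round(config.hedgerow_density * n_cells / 1000.0))
    arable = values == CODES["arable"]
    for _ in range(n_hedges):
        length = int(rng.integers(5, 21))
        horizontal = bool(rng.integers(0, 2))
        r0 = int(rng.integers(0, n_rows))
        c0 = int(rng.integers(0, n_cols))
        for k in range(length):
            r, c = (r0, c0 + k) if horizontal else (r0 + k, c0)
            if 0 <= r < n_rows and 0 <= c < n_cols and arable[r, c]:
                values[r, c] = CODES["hedgerow"]

    # road grid over everything but water
    water = np.isin(values, [CODES["lake"], CODES["river"]])
    if config.road_spacing > 0:
        for r in range(config.road_spacing // 2, n_rows, config.road_spacing):
            values[r, ~water[r]] = CODES["road_major"]
        for c in range(config.road_spacing // 2, n_cols, config.road_spacing):
            col_mask = ~water[:, c]
            values[col_mask, c] = CODES["road_major"]

    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=config.cell_size_m)
    raster = Raster(spec, values)
    table = _base_class_table()
    raster, table = derive_forest_edges(raster, table, config.forest_edge_m)
    raster, table = derive_riparian_zones(raster, table, config.riparian_m)
    return raster, table


def _linear_component(comp: np.ndarray) -> bool:
    """A component is 'linear' when no cell has more than two 4-neighbors
    inside it (one-cell-wide strings: hedgerows, small roads, rivers)."""
    neigh = ndimage.convolve(
        comp.astype(np.int8),
        np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8),
        mode="constant",
    )
    return bool((neigh[comp] <= 2).all())


def generalize_landscape(
    lulc: Raster,
    table: ClassTable,
    min_patch_cells: int = 250,
    drop_linear: bool = True,
    keep_codes: list[int] | None = None,
) -> Raster:
    """Absorb small patches and linear features into their surroundings.

    Connected components (8-connectivity) smaller than ``min_patch_cells``
    — and every one-cell-wide linear feature when ``drop_linear`` — are
    replaced by the modal surrounding class (ties break to the smallest
    code). ``keep_codes`` defaults to the road classes: coarse datasets
    still map major roads. The default threshold of 250 cells is 2.5 ha at
    10 m resolution, a deliberately mild stand-in for coarse-product
    minimum mapping units that would erase everything at toy extents.
    Cell count is conserved; only labels change.
    """
    if min_patch_cells < 1:
        raise ValidationError("min_patch_cells must be >= 1")
    if keep_codes is None:
        keep_codes = [int(c) for c in table.codes_where("is_road")]
    keep = set(keep_codes)

    values = lulc.values.copy()
    valid = lulc.valid_mask
    structure = np.ones((3, 3), dtype=bool)
    removals: list[tuple[int, int, np.ndarray]] = []  # (size, code, mask)
    for code in sorted(int(c) for c in np.unique(values[valid])):
        if code in keep:
            continue
        labeled, n = ndimage.label(values == code, structure=structure)
        for comp_id in range(1, n + 1):
            comp = labeled == comp_id
            size = int(comp.sum())
            small = size < min_patch_cells
            linear = drop_linear and _linear_component(comp)
            if small or linear:
                removals.append((size, code, comp))

    removal_mask = np.zeros_like(valid)
    for _, _, comp in removals:
        removal_mask |= comp

    kept_lines = np.isin(values, sorted(keep))

    def fill(comp: np.ndarray, donors: np.ndarray) -> None:
        donor_vals = values[donors]
        codes_, counts = np.unique(donor_vals, return_counts=True)
        values[comp] = int(codes_[counts == counts.max()].min())

    # Absorb in passes: a component merges only once it borders a settled
    # areal neighbor, so a field sliced up by hedgerows reunites with the
    # surrounding matrix instead of being swallowed by the road line that
    # bounds it. Deterministic: pending order is (size, code, discovery).
    pending = sorted(removals, key=lambda t: (t[0], t[1]))
    while pending:
        deferred = []
        for size, code, comp in pending:
            ring = ndimage.binary_dilation(comp, structure=structure) & ~comp & valid
            donors = ring & ~removal_mask & ~kept_lines
            if donors.any():
                fill(comp, donors)
                removal_mask &= ~comp
            else:
                deferred.append((size, code, comp))
        if len(deferred) == len(pending):
            # nothing settled this pass: remaining components see only
            # kept lines (or nothing); let those donate after all
            for size, code, comp in deferred:
                ring = ndimage.binary_dilation(comp, structure=structure) & ~comp & valid
                donors = ring & ~removal_mask
                if not donors.any():
                    donors = ring
                if donors.any():
                    fill(comp, donors)
                removal_mask &= ~comp
            break
        pending = deferred
    return Raster(lulc.spec, values)


def paired_landscapes(
    config: LandscapeConfig, min_patch_cells: int = 250
) -> tuple[tuple[Raster, ClassTable], tuple[Raster, ClassTable]]:
    """Generate the detailed landscape and its generalized counterpart.

    The generalized raster is re-run through forest-edge and riparian
    derivation afterwards, because the generalization may absorb the thin
    edge bands while the coarse products being emulated did have edges
    (re)constructed during their preparation.
    """
    detailed, table = generate_landscape(config)
    coarse = generalize_landscape(detailed, table, min_patch_cells=min_patch_cells)
    coarse, table_b = derive_forest_edges(coarse, table, config.forest_edge_m)
    coarse, table_b = derive_riparian_zones(coarse, table_b, config.riparian_m)
    return (detailed, table), (coarse, table_b)


def _archetype_for(row: pd.Series) -> tuple[float, float]:
    group = str(row["group"])
    bd = row["built_density"]
    if not pd.isna(bd):
        key = min(_URBAN_ARCHETYPES, key=lambda k: abs(k - float(bd)))
        return _URBAN_ARCHETYPES[key]
    if group not in GROUP_ARCHETYPES:
        raise ValidationError(f"no archetype for group {group!r}")
    return GROUP_ARCHETYPES[group]


def generate_biophysical(
    table: ClassTable,
    mode: str = "literature",
    seed: int = 0,
    n_experts: int = 10,
    sigma: float = 1.0,
) -> BiophysicalTable | tuple[BiophysicalTable, ExpertSurvey]:
    """Build a biophysical table from the per-group archetypes.

    ``literature`` mode assigns the archetype (NA, FA) directly;
    ``expert`` mode simulates ``n_experts`` integer 0-10 ratings per class
    (archetype x 10 plus N(0, sigma) noise, rounded and clamped),
    aggregates them, and returns the survey alongside the table. Excluded
    classes are always all-zero.
    """
    if mode not in ("literature", "expert"):
        raise ValueError(f"mode must be 'literature' or 'expert', got {mode!r}")
    rows = []
    for code in table.codes:
        row = table.row(int(code))
        na, fa = (0.0, 0.0) if row["is_excluded"] else _archetype_for(row)
        rows.append({"code": int(code), "na": na, "fa": fa})
    arch = pd.DataFrame(rows).set_index("code")

    if mode == "literature":
        return _to_bio_table(arch)

    rng = np.random.default_rng(seed)
    recs = []
    for code, r in arch.iterrows():
        for e in range(n_experts):
            na_rating = int(np.clip(round(10 * r["na"] + rng.normal(0, sigma)), 0, 10))
            fa_rating = int(np.clip(round(10 * r["fa"] + rng.normal(0, sigma)), 0, 10))
            recs.append(
                {"code": int(code), "expert_id": e, "na_rating": na_rating, "fa_rating": fa_rating}
            )
    survey = ExpertSurvey(pd.DataFrame(recs))
    agg = aggregate_expert_survey(survey)
    excluded = set(int(c) for c in table.codes_where("is_excluded"))
    agg.loc[agg.index.isin(excluded), :] = 0.0
    return _to_bio_table(agg), survey


def _to_bio_table(na_fa: pd.DataFrame) -> BiophysicalTable:
    df = pd.DataFrame(
        {
            "code": na_fa.index.astype(int),
            "nest_cavity": na_fa["na"].to_numpy(),
            "nest_ground": na_fa["na"].to_numpy(),
            "floral_spring": na_fa["fa"].to_numpy(),
            "floral_summer": na_fa["fa"].to_numpy(),
        }
    )
    return BiophysicalTable(df)
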