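"""Per-class biophysical values, expert-survey aggregation, and the
reference species.

Both models consume two per-class quantities: nesting availability (NA)
and floral availability (FA), each an index in [0, 1]. The biophysical
table resolves these by substrate (cavity vs ground nesting) and season
(spring vs summer flowering); the reference species' preferences and
activities collapse them to the scalar NA/FA layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ClassTable, Raster, ValidationError, validate_lulc

__all__ = [
    "BiophysicalTable",
    "ExpertSurvey",
    "SpeciesTraits",
    "aggregate_expert_survey",
    "interpolate_urban_values",
    "build_reference_species",
    "derive_scalar_layers",
    "load_biophysical_table",
    "load_species_table",
]

BIOPHYSICAL_COLUMNS = [
    "code",
    "nest_cavity",
    "nest_ground",
    "floral_spring",
    "floral_summer",
]
_VALUE_COLUMNS = BIOPHYSICAL_COLUMNS[1:]


@dataclass
class BiophysicalTable:
    """Nesting suitability (cavity/ground) and floral availability
    (spring/summer) per land-cover class, each in [0, 1]."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = set(BIOPHYSICAL_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"biophysical table missing columns {sorted(missing)}")
        df["code"] = df["code"].astype(int)
        if df["code"].duplicated().any():
            raise ValidationError("duplicate codes in biophysical table")
        for col in _VALUE_COLUMNS:
            v = df[col].astype(float)
            if ((v < 0) | (v > 1)).any() or v.isna().any():
                raise ValidationError(f"{col} values must be in [0,1]")
            df[col] = v
        self.df = df.set_index("code", drop=False)[BIOPHYSICAL_COLUMNS]

    def check_against(self, table: ClassTable) -> None:
        """Enforce cross-table invariants: every code known to the class
        table, and excluded classes carrying all-zero values."""
        unknown = [c for c in self.df["code"] if not table.has_code(c)]
        if unknown:
            raise ValidationError(
                f"biophysical codes absent from class table: {unknown}"
            )
        excluded = set(table.codes_where("is_excluded").tolist())
        rows = self.df.loc[self.df["code"].isin(excluded), _VALUE_COLUMNS]
        if (rows.to_numpy() != 0).any():
            bad = rows.index[(rows != 0).any(axis=1)].tolist()
            raise ValidationError(
                f"excluded classes must have all-zero biophysical values: {bad}"
            )

    def lookup(self, column: str, codes: np.ndarray, nodata: float) -> np.ndarray:
        """Vectorized per-cell lookup of one value column; nodata passes
        through, unknown codes raise."""
        mapping = self.df[column]
        out = np.full(codes.shape, float(nodata), dtype=np.float64)
        valid = codes != nodata
        present = np.unique(codes[valid])
        missing = [int(c) for c in present if int(c) not in mapping.index]
        if missing:
            raise ValidationError(f"codes missing from biophysical table: {missing}")
        lut = {int(c): float(mapping.loc[int(c)]) for c in present}
        flat = codes[valid].astype(int)
        out[valid] = np.vectorize(lut.__getitem__, otypes=[np.float64])(flat)
        return out

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.reset_index(drop=True).to_csv(path, index=False)
        return path


@dataclass
class ExpertSurvey:
    """Raw questionnaire ratings: per class, each expert scores nesting
    availability and floral availability on an integer 0-10 scale."""

    df: pd.DataFrame = field(repr=False)  # columns: code, expert_id, na_rating, fa_rating

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"code", "expert_id", "na_rating", "fa_rating"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"survey missing columns {sorted(missing)}")
        for col in ("na_rating", "fa_rating"):
            v = df[col]
            if not np.array_equal(v, v.astype(int)):
                raise ValidationError(f"{col} must be integers 0-10")
            v = v.astype(int)
            if ((v < 0) | (v > 10)).any():
                raise ValidationError(f"{col} must be in [0, 10]")
            df[col] = v
        df["code"] = df["code"].astype(int)
        self.df = df


@dataclass(frozen=True)
class SpeciesTraits:
    """Reference-species parameters.

    The defaults describe a composite wild bee averaged over many real
    species: it nests in both cavities and the ground at full preference,
    is active in spring and summer alike, and forages out to a mean flight
    distance that sets the kernel decay length.
    """

    flight_distance_m: float = 680.0
    nest_pref_cavity: float = 1.0
    nest_pref_ground: float = 1.0
    activity_spring: float = 1.0
    activity_summer: float = 1.0
    relative_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.flight_distance_m <= 0:
            raise ValidationError("flight_distance_m must be > 0")
        if self.activity_spring + self.activity_summer <= 0:
            raise ValidationError("total seasonal activity must be > 0")
        if max(self.nest_pref_cavity, self.nest_pref_ground) <= 0:
            raise ValidationError("at least one nesting preference must be > 0")
        if self.relative_abundance <= 0:
            raise ValidationError("relative_abundance must be > 0")


def aggregate_expert_survey(
    survey: ExpertSurvey, statistic: str = "mean"
) -> pd.DataFrame:
    """Collapse ratings to per-class (NA, FA) indices in [0, 1].

    Ratings on the 0-10 questionnaire scale are averaged across experts
    (arithmetic mean by default, median optional) and divided by 10.
    Returns a frame indexed by code with columns ``na`` and ``fa``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    df = survey.df
    counts = df.groupby("code").size()
    empty = counts[counts == 0].index.tolist()
    if empty:
        raise ValidationError(f"classes with no ratings: {empty}")
    agg = df.groupby("code")[["na_rating", "fa_rating"]].agg(statistic) / 10.0
    agg.columns = ["na", "fa"]
    return agg


def interpolate_urban_values(
    anchors: list[tuple[float, float]], query_density: float
) -> float:
    """Piecewise-linear interpolation of a biophysical value against built
    density.

    Urban land-cover classes are defined by sealing-density brackets;
    classes without a literature value receive one interpolated between the
    anchored classes. No extrapolation: the query must lie within the
    anchor range.
    """
    if len(anchors) < 2:
        raise ValidationError("need at least 2 anchors")
    pts = sorted(anchors)
    dens = [p[0] for p in pts]
    if len(set(dens)) != len(dens):
        raise ValidationError("anchor densities must be distinct")
    if not (dens[0] <= query_density <= dens[-1]):
        raise ValidationError(
            f"query density {query_density} outside anchor range "
            f"[{dens[0]}, {dens[-1]}]"
        )
    vals = [p[1] for p in pts]
    return float(np.interp(query_density, dens, vals))


def build_reference_species(
    species_table: pd.DataFrame, **overrides
) -> SpeciesTraits:
    """Average a per-species trait table into one reference species.

    The flight distance is the arithmetic mean of the per-species flight
    distances; nesting preferences and seasonal activities default to 1
    (the composite bee uses every substrate and both seasons).
    """
    if "flight_distance_m" not in species_table.columns:
        raise ValidationError("species table needs a flight_distance_m column")
    d = species_table["flight_distance_m"].astype(float)
    if len(d) == 0:
        raise ValidationError("species table is empty")
    if (d <= 0).any():
        raise ValidationError("flight distances must be > 0")
    return SpeciesTraits(flight_distance_m=float(d.mean()), **overrides)


def derive_scalar_layers(
    lulc: Raster,
    bio: BiophysicalTable,
    species: SpeciesTraits,
    table: ClassTable | None = None,
) -> tuple[Raster, Raster]:
    """Collapse the substrate/season-resolved table to scalar (FA, NA)
    rasters for the reference species.

    NA(x) = max over substrates of nesting value x preference;
    FA(x) = activity-weighted mean of seasonal floral values.
    Nodata propagates. Returns ``(FA, NA)``.
    """
    if table is not None:
        missing = validate_lulc(lulc, table)
        if missing:
            raise ValidationError(f"raster codes missing from class table: {missing}")
        bio.check_against(table)
    nodata = lulc.spec.nodata
    codes = lulc.values
    cav = bio.lookup("nest_cavity", codes, nodata)
    grd = bio.lookup("nest_ground", codes, nodata)
    spr = bio.lookup("floral_spring", codes, nodata)
    smr = bio.lookup("floral_summer", codes, nodata)

    valid = lulc.valid_mask
    na = np.full(codes.shape, float(nodata))
    fa = np.full(codes.shape, float(nodata))
    na[valid] = np.maximum(
        cav[valid] * species.nest_pref_cavity,
        grd[valid] * species.nest_pref_ground,
    )
    a_s, a_m = species.activity_spring, species.activity_summer
    fa[valid] = (a_s * spr[valid] + a_m * smr[valid]) / (a_s + a_m)
    float_spec = lulc.spec if isinstance(nodata, float) else lulc.spec
    return Raster(float_spec, fa), Raster(float_spec, na)


def load_biophysical_table(path: str | Path) -> BiophysicalTable:
    return BiophysicalTable(pd.read_csv(path))


def load_species_table(path: str | Path) -> pd.DataFrame:
    """Species CSV with columns ``species,flight_distance_m``."""
    return pd.read_csv(path)
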