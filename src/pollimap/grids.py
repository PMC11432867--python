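"""Raster and class-table containers plus ESRI ASCII Grid I/O.

All model stages operate on square-celled, axis-aligned lattices. A raster
is a :class:`GridSpec` (geometry + nodata sentinel) plus a 2-D numpy array;
row 0 is the northernmost row and the origin is the lower-left corner, the
ESRI ASCII convention. Rasters that enter one experiment must share an
identical GridSpec — no resampling is offered, because the cell-by-cell
similarity index presupposes aligned grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999

__all__ = [
    "GridSpec",
    "Raster",
    "ClassTable",
    "RasterParseError",
    "ValidationError",
    "load_raster",
    "save_raster",
    "load_class_table",
    "validate_lulc",
    "DEFAULT_NODATA",
]


class RasterParseError(ValueError):
    """Malformed ESRI ASCII grid (bad header, ragged row, non-numeric cell)."""


class ValidationError(ValueError):
    """A table or raster violates one of its declared invariants."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled grid.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions (>= 1).
    cell_size
        Cell edge length in meters (> 0); cells are square.
    origin_x, origin_y
        Lower-left corner coordinates in meters.
    nodata
        Sentinel for missing cells, distinct from every valid value.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class Raster:
    """A GridSpec plus its value lattice (integer class codes or floats)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValidationError(
                f"value array shape {self.values.shape} does not match "
                f"grid spec {self.spec.shape}"
            )

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values)

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())

    def same_grid(self, other: "Raster") -> bool:
        return self.spec == other.spec


def _require_aligned(*rasters: Raster) -> None:
    first = rasters[0].spec
    for r in rasters[1:]:
        if r.spec != first:
            raise ValidationError(
                f"rasters are not aligned: {r.spec} differs from {first}"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII Grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def load_raster(path: str | Path, kind: str = "integer") -> Raster:
    """Read an ESRI ASCII grid (.asc).

    ``kind`` is ``"integer"`` (class codes) or ``"float"`` (continuous
    field). Raises :class:`RasterParseError` with the offending line number
    on malformed input.
    """
    if kind not in ("integer", "float"):
        raise ValueError(f"kind must be 'integer' or 'float', got {kind!r}")
    path = Path(path)
    lines = path.read_text().splitlines()

    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise RasterParseError(
                    f"{path}, line {i + 1}: non-numeric header value {parts[1]!r}"
                ) from None
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterParseError(f"{path}: header missing keys {missing}")

    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=int(nodata) if kind == "integer" else nodata,
    )

    data_lines = [ln for ln in lines[i:] if ln.strip()]
    if len(data_lines) != n_rows:
        raise RasterParseError(
            f"{path}: header declares {n_rows} rows, found {len(data_lines)}"
        )
    dtype = np.int64 if kind == "integer" else np.float64
    values = np.empty((n_rows, n_cols), dtype=dtype)
    for r, ln in enumerate(data_lines):
        parts = ln.split()
        if len(parts) != n_cols:
            raise RasterParseError(
                f"{path}, line {i + 1 + r}: expected {n_cols} columns, "
                f"found {len(parts)}"
            )
        try:
            row = [float(p) for p in parts]
        except ValueError:
            bad = next(p for p in parts if not _is_number(p))
            raise RasterParseError(
                f"{path}, line {i + 1 + r}: non-numeric cell {bad!r}"
            ) from None
        values[r] = np.asarray(row, dtype=np.float64).astype(dtype)
    return Raster(spec, values)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def save_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid.

    Integer rasters round-trip exactly; floats are written with 12
    significant digits (round trip within 1e-9 relative).
    """
    path = Path(path)
    spec = raster.spec
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x:.6f}\n"
        f"yllcorner {spec.origin_y:.6f}\n"
        f"cellsize {spec.cell_size:.6f}\n"
        f"NODATA_value {spec.nodata:g}\n"
    )
    if raster.is_integer:
        body = "\n".join(" ".join(str(v) for v in row) for row in raster.values)
    else:
        body = "\n".join(
            " ".join(f"{v:.12g}" for v in row) for row in raster.values
        )
    path.write_text(header + body + "\n")
    return path


# ---------------------------------------------------------------------------
# Class table
# ---------------------------------------------------------------------------

CLASS_TABLE_COLUMNS = [
    "code",
    "name",
    "group",
    "is_forest",
    "is_forest_edge",
    "is_water",
    "is_road",
    "is_favorable",
    "is_excluded",
    "built_density",
]

_FLAG_COLUMNS = [c for c in CLASS_TABLE_COLUMNS if c.startswith("is_")]


@dataclass
class ClassTable:
    """Per-class metadata and role flags for a categorical LULC raster.

    One row per class code. Role flags drive the models: ``is_favorable``
    classes seed the distance-decay influence, ``is_excluded`` classes
    (always including water) are masked to suitability 0, ``is_road``
    classes carry the road penalty, and ``is_forest`` marks classes whose
    perimeter receives a forest-edge band during preprocessing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in CLASS_TABLE_COLUMNS:
            if col not in df.columns:
                if col == "built_density":
                    df[col] = np.nan
                elif col in _FLAG_COLUMNS:
                    df[col] = False
                else:
                    raise ValidationError(f"class table missing column {col!r}")
        df["code"] = df["code"].astype(int)
        if df["code"].duplicated().any():
            dupes = sorted(df.loc[df["code"].duplicated(), "code"].unique())
            raise ValidationError(f"duplicate class codes: {dupes}")
        for col in _FLAG_COLUMNS:
            df[col] = _coerce_flags(df[col], col)
        # invariant: water implies excluded
        fix = df["is_water"] & ~df["is_excluded"]
        if fix.any():
            log.info(
                "class table: forcing is_excluded=True for water classes %s",
                sorted(df.loc[fix, "code"]),
            )
            df.loc[fix, "is_excluded"] = True
        # invariant: forest edges count as favorable
        fix = df["is_forest_edge"] & ~df["is_favorable"]
        if fix.any():
            log.info(
                "class table: forcing is_favorable=True for forest-edge "
                "classes %s",
                sorted(df.loc[fix, "code"]),
            )
            df.loc[fix, "is_favorable"] = True
        bd = df["built_density"].astype(float)
        bad = bd.notna() & ((bd < 0) | (bd > 1))
        if bad.any():
            raise ValidationError(
                f"built_density outside [0,1] for codes "
                f"{sorted(df.loc[bad, 'code'])}"
            )
        df["built_density"] = bd
        self.df = df.set_index("code", drop=False)[CLASS_TABLE_COLUMNS]

    # -- accessors ---------------------------------------------------------

    @property
    def codes(self) -> np.ndarray:
        return self.df["code"].to_numpy()

    def codes_where(self, flag: str) -> np.ndarray:
        """Codes whose boolean column ``flag`` is true."""
        return self.df.loc[self.df[flag].astype(bool), "code"].to_numpy()

    def mask_where(self, lulc: Raster, flag: str) -> np.ndarray:
        """Boolean lattice: cells belonging to classes with ``flag`` set."""
        return np.isin(lulc.values, self.codes_where(flag))

    def group_of(self, code: int) -> str:
        return str(self.df.at[code, "group"])

    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    def has_code(self, code: int) -> bool:
        return int(code) in self.df.index

    def row(self, code: int) -> pd.Series:
        return self.df.loc[int(code)]

    def append_class(self, **fields) -> "ClassTable":
        """Return a new table with one extra class row (used by preprocess)."""
        row = {c: fields.get(c) for c in CLASS_TABLE_COLUMNS}
        for col in _FLAG_COLUMNS:
            row[col] = bool(fields.get(col, False))
        row["built_density"] = fields.get("built_density", np.nan)
        new = pd.concat(
            [self.df.reset_index(drop=True), pd.DataFrame([row])],
            ignore_index=True,
        )
        return ClassTable(new)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.df.reset_index(drop=True).copy()
        for col in _FLAG_COLUMNS:
            out[col] = out[col].astype(int)
        out.to_csv(path, index=False)
        return path


def _coerce_flags(series: pd.Series, name: str) -> pd.Series:
    """Accept 0/1, booleans, or true/false strings; reject anything else."""

    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if pd.isna(v) or v == "":
            return False
        if isinstance(v, str):
            s = v.strip().lower()
            if s in ("1", "true", "yes"):
                return True
            if s in ("0", "false", "no"):
                return False
            raise ValidationError(f"unknown {name} flag value {v!r}")
        if v in (0, 1):
            return bool(v)
        raise ValidationError(f"unknown {name} flag value {v!r}")

    return series.map(one)


def load_class_table(path: str | Path) -> ClassTable:
    """Read a class-table CSV (columns: code,name,group,flags,built_density)."""
    df = pd.read_csv(path)
    required = {"code", "name", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: class table missing columns {sorted(missing)}")
    return ClassTable(df)


def validate_lulc(raster: Raster, table: ClassTable) -> list[int]:
    """Report class codes present in the raster but absent from the table.

    An empty list means every cell of every model run on this pair can be
    resolved. Report-only: never raises.
    """
    present = np.unique(raster.valid_values())
    return sorted(int(c) for c in present if not table.has_code(int(c)))
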