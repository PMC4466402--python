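"""Gridded climate layers, occurrence tables, and the spatial conventions they share.

Everything downstream — filtering, model fitting, projection, range-stability
maps — works in the coordinate frame defined here: a regular latitude/longitude
grid (WGS84 degrees assumed, no reprojection), row 0 at the northern edge,
square cells. Cell membership uses half-open intervals, ``[west, east)`` in
longitude and ``(south, north]`` in latitude, so every point belongs to exactly
one cell and points on the far eastern/southern outer edge fall outside the
grid.

Values are stored as double precision in whatever units the input layers carry
(WorldClim-style integer-coded temperatures are *not* rescaled: environmental
filter widths are specified in raw layer units).

Supported on-disk formats: ESRI ASCII grid and single-band GeoTIFF for rasters,
comma- or tab-delimited text for occurrence tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "Raster",
    "EnvStack",
    "Occurrence",
    "OccurrenceSet",
    "EnvSample",
    "Extraction",
    "RejectedPoint",
    "GridFormatError",
    "UnsupportedGeometryError",
    "EmptyOccurrenceError",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "extract_values",
]


class GridFormatError(ValueError):
    """A raster file violates its declared format (names the offending field)."""


class UnsupportedGeometryError(ValueError):
    """Raster geometry outside the supported model (e.g. non-square cells)."""


class EmptyOccurrenceError(ValueError):
    """An occurrence table yielded no valid records."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    ``x_origin`` is the western edge, ``y_origin`` the northern edge;
    ``cell_size`` is in decimal degrees and applies to both axes.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def aligned_with(self, other: "GridSpec") -> bool:
        """True iff the five geometry fields agree exactly (an equivalence)."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.x_origin == other.x_origin
            and self.y_origin == other.y_origin
            and self.cell_size == other.cell_size
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell (row, col) containing the point, or None if out of bounds.

        Membership convention: [west, east) x (south, north].
        """
        col = math.floor((lon - self.x_origin) / self.cell_size)
        # floor((y_origin - lat)/cell) implements the (south, north] rule: a
        # point on an interior row boundary is that boundary's north-edge
        # point for the cell below, so it lands in the lower row; the grid's
        # own north edge maps to row 0 and the south outer edge to n_rows
        # (out of bounds).
        row = math.floor((self.y_origin - lat) / self.cell_size)
        if row < 0 or row >= self.n_rows or col < 0 or col >= self.n_cols:
            return None
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat


@dataclass
class Raster:
    """A single gridded layer: values on a :class:`GridSpec` lattice.

    Row 0 is the northernmost row. Cells equal to ``spec.nodata_value`` (or
    NaN) form the mask and never enter any statistic.
    """

    spec: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.spec.nodata_value))

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(self.spec, values, self.name if name is None else name)

    def masked_like(self, other: "Raster") -> "Raster":
        """Copy with this raster's mask intersected with ``other``'s."""
        out = self.values.copy()
        out[~other.valid_mask] = self.spec.nodata_value
        return Raster(self.spec, out, self.name)


@dataclass
class EnvStack:
    """An ordered collection of aligned layers for one climate scenario.

    At construction the masks of all layers are intersected, so a cell masked
    in any layer is masked in every layer. Layer names must be unique.
    """

    layers: list[Raster]
    scenario_name: str = "current"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        spec = self.layers[0].spec
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        for lyr in self.layers[1:]:
            if not lyr.spec.aligned_with(spec):
                raise ValueError(
                    f"layer {lyr.name!r} is not aligned with {self.layers[0].name!r}"
                )
        common = np.ones((spec.n_rows, spec.n_cols), dtype=bool)
        for lyr in self.layers:
            common &= lyr.valid_mask
        new_layers = []
        for lyr in self.layers:
            vals = lyr.values.copy()
            vals[~common] = lyr.spec.nodata_value
            new_layers.append(Raster(lyr.spec, vals, lyr.name))
        self.layers = new_layers
        self._mask = common

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def layer_names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        return self._mask

    def __len__(self) -> int:
        return len(self.layers)

    def get(self, name: str) -> Raster:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"no layer named {name!r}; have {self.layer_names}")

    def matrix_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_cells, n_layers) matrix of layer values at the given cells."""
        return np.column_stack([lyr.values[rows, cols] for lyr in self.layers])

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column indices of all unmasked cells."""
        rows, cols = np.nonzero(self._mask)
        return rows, cols


class Occurrence(NamedTuple):
    longitude: float
    latitude: float
    source: str = ""


@dataclass
class OccurrenceSet:
    """Presence-only records for one species.

    ``role`` records provenance within the workflow: ``raw`` as ingested,
    ``calibration``/``testing`` after environmental filtering.
    """

    species: str
    records: list[Occurrence]
    role: str = "raw"

    _ROLES = ("raw", "calibration", "testing")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        self.records = [Occurrence(*r) for r in self.records]
        for i, rec in enumerate(self.records):
            if not (-180.0 <= rec.longitude <= 180.0):
                raise ValueError(f"record {i}: longitude {rec.longitude} out of range")
            if not (-90.0 <= rec.latitude <= 90.0):
                raise ValueError(f"record {i}: latitude {rec.latitude} out of range")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def longitudes(self) -> np.ndarray:
        return np.array([r.longitude for r in self.records], dtype=np.float64)

    @property
    def latitudes(self) -> np.ndarray:
        return np.array([r.latitude for r in self.records], dtype=np.float64)

    def subset(self, indices: Sequence[int], role: str | None = None) -> "OccurrenceSet":
        return OccurrenceSet(
            self.species,
            [self.records[i] for i in indices],
            self.role if role is None else role,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "longitude": self.longitudes,
                "latitude": self.latitudes,
                "source": [r.source for r in self.records],
            }
        )


@dataclass
class EnvSample:
    """Environment matrix for a set of points (points x variables).

    Column order matches the :class:`EnvStack` layer order it was extracted
    from; the matrix never contains nodata.
    """

    point_ids: list
    matrix: np.ndarray
    variable_names: list[str]
    cell_rows: np.ndarray | None = None
    cell_cols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (points x variables)")
        if self.matrix.shape[1] != len(self.variable_names):
            raise ValueError("matrix width must equal number of variable names")
        if len(self.point_ids) != self.matrix.shape[0]:
            raise ValueError("one point id per matrix row required")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}; have {self.variable_names}")
        return self.matrix[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.variable_names, index=self.point_ids)


class RejectedPoint(NamedTuple):
    index: int
    longitude: float
    latitude: float
    reason: str  # "masked_cell" or "out_of_bounds"


class Extraction(NamedTuple):
    """Result of sampling a stack at occurrence points."""

    sample: EnvSample
    rejected: list[RejectedPoint]
    kept_indices: list[int]


def extract_values(stack: EnvStack, occ: OccurrenceSet) -> Extraction:
    """Sample every layer of ``stack`` at the occurrence points.

    Each point takes the value of the cell containing it ([west, east) x
    (south, north] membership). Points on masked cells or outside the grid are
    excluded from the matrix and listed in the rejection report — never
    silently dropped.
    """
    spec = stack.spec
    rows, cols, kept, rejected = [], [], [], []
    for i, rec in enumerate(occ.records):
        cell = spec.cell_of(rec.longitude, rec.latitude)
        if cell is None:
            rejected.append(RejectedPoint(i, rec.longitude, rec.latitude, "out_of_bounds"))
            continue
        r, c = cell
        if not stack.valid_mask[r, c]:
            rejected.append(RejectedPoint(i, rec.longitude, rec.latitude, "masked_cell"))
            continue
        rows.append(r)
        cols.append(c)
        kept.append(i)
    if rejected:
        logger.info(
            "extract_values: %d of %d points rejected (%s)",
            len(rejected),
            len(occ),
            {p.reason for p in rejected},
        )
    rows_a = np.array(rows, dtype=np.intp)
    cols_a = np.array(cols, dtype=np.intp)
    matrix = (
        stack.matrix_at_cells(rows_a, cols_a)
        if kept
        else np.empty((0, len(stack.layers)))
    )
    sample = EnvSample(
        point_ids=list(kept),
        matrix=matrix,
        variable_names=stack.layer_names,
        cell_rows=rows_a,
        cell_cols=cols_a,
    )
    return Extraction(sample, rejected, kept)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASCII_FIELDS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")

# GeoTIFF tag codes: pixel scale, tiepoint, GDAL's nodata convention.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd"):
        return "esri_ascii"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise GridFormatError(f"cannot infer raster format from suffix {suffix!r}")


def read_raster(path: str | Path, fmt: str | None = None, name: str | None = None) -> Raster:
    """Read a single-band raster (``esri_ascii`` or ``geotiff``).

    The layer name defaults to the file stem.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if name is None:
        name = path.stem
    if fmt == "esri_ascii":
        return _read_esri_ascii(path, name)
    if fmt == "geotiff":
        return _read_geotiff(path, name)
    raise GridFormatError(f"unknown raster format {fmt!r}")


def write_raster(raster: Raster, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "esri_ascii":
        _write_esri_ascii(raster, path)
    elif fmt == "geotiff":
        _write_geotiff(raster, path)
    else:
        raise GridFormatError(f"unknown raster format {fmt!r}")


def _read_esri_ascii(path: Path, name: str) -> Raster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    center_registered = {"x": False, "y": False}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            ):
                if len(parts) != 2:
                    raise GridFormatError(f"malformed header line for field {key!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError:
                    raise GridFormatError(f"non-numeric value for header field {key!r}")
                if key == "xllcenter":
                    center_registered["x"] = True
                    header["xllcorner"] = header.pop("xllcenter")
                if key == "yllcenter":
                    center_registered["y"] = True
                    header["yllcorner"] = header.pop("yllcenter")
            else:
                data_lines.append(line)
    for fld in _ASCII_FIELDS:
        if fld not in header:
            raise GridFormatError(f"missing required header field {fld!r}")
    cell = header["cellsize"]
    if cell <= 0:
        raise GridFormatError("cellsize must be positive")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    xll, yll = header["xllcorner"], header["yllcorner"]
    if center_registered["x"]:
        xll -= cell / 2
    if center_registered["y"]:
        yll -= cell / 2
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.loadtxt(data_lines, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(f"malformed data block: {exc}")
    if values.shape != (n_rows, n_cols):
        raise GridFormatError(
            f"data block shape {values.shape} does not match header "
            f"nrows/ncols ({n_rows}, {n_cols})"
        )
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=xll,
        y_origin=yll + n_rows * cell,
        cell_size=cell,
        nodata_value=nodata,
    )
    return Raster(spec, values, name)


def _write_esri_ascii(raster: Raster, path: Path) -> None:
    spec = raster.spec
    with open(path, "w") as fh:
        fh.write(f"NCOLS {spec.n_cols}\n")
        fh.write(f"NROWS {spec.n_rows}\n")
        fh.write(f"XLLCORNER {float(spec.x_origin)!r}\n")
        fh.write(f"YLLCORNER {float(spec.y_min)!r}\n")
        fh.write(f"CELLSIZE {float(spec.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(spec.nodata_value)!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path, name: str) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if values.ndim != 2:
        raise UnsupportedGeometryError("only single-band rasters are supported")
    if _TAG_PIXEL_SCALE not in tags:
        raise GridFormatError("missing required tag ModelPixelScale")
    if _TAG_TIEPOINT not in tags:
        raise GridFormatError("missing required tag ModelTiepoint")
    sx, sy = float(tags[_TAG_PIXEL_SCALE][0]), float(tags[_TAG_PIXEL_SCALE][1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise UnsupportedGeometryError(f"non-square cells ({sx} x {sy}) not supported")
    tie = tags[_TAG_TIEPOINT]
    # tiepoint maps raster (i, j, k) -> model (x, y, z); we require (0, 0).
    if float(tie[0]) != 0.0 or float(tie[1]) != 0.0:
        raise UnsupportedGeometryError("tiepoint must anchor the (0, 0) pixel corner")
    x_origin, y_origin = float(tie[3]), float(tie[4])
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            raise GridFormatError("non-numeric GDAL nodata tag")
    n_rows, n_cols = values.shape
    spec = GridSpec(n_rows, n_cols, x_origin, y_origin, sx, nodata)
    return Raster(spec, np.asarray(values, dtype=np.float64), name)


def _write_geotiff(raster: Raster, path: Path) -> None:
    import tifffile

    spec = raster.spec
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_origin, spec.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata_value)),
    ]
    tifffile.imwrite(path, raster.values, extratags=extratags)


# ---------------------------------------------------------------------------
# Occurrence I/O
# ---------------------------------------------------------------------------

_LON_ALIASES = ("longitude", "lon", "long", "x")
_LAT_ALIASES = ("latitude", "lat", "y")


def _resolve_column(columns: Iterable[str], aliases: Sequence[str], what: str) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    raise GridFormatError(f"no {what} column found (tried {aliases})")


def read_occurrences(
    path: str | Path, species: str | None = None, role: str = "raw"
) -> OccurrenceSet:
    """Read an occurrence table (CSV or TSV, auto-detected, header-named columns).

    Columns are matched case-insensitively against ``species``,
    ``longitude``/``lon``/``x`` and ``latitude``/``lat``/``y`` in any order.
    Rows with unparseable or out-of-range coordinates are skipped and logged
    with their row number. Exact duplicate coordinates are retained:
    deduplication is the environmental filter's job, not the reader's.
    """
    path = Path(path)
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, _csv.Error):
        raise EmptyOccurrenceError(f"{path} is empty or undelimited")
    if df.empty:
        raise EmptyOccurrenceError(f"{path} has a header but no records")
    lon_col = _resolve_column(df.columns, _LON_ALIASES, "longitude")
    lat_col = _resolve_column(df.columns, _LAT_ALIASES, "latitude")
    sp_col = _resolve_column(df.columns, ("species", "sp", "taxon"), "species")
    src_col = None
    for cand in ("source", "reference", "provenance"):
        if cand in {c.lower().strip() for c in df.columns}:
            src_col = _resolve_column(df.columns, (cand,), "source")
            break

    if species is not None:
        df = df[df[sp_col].str.strip() == species]
        if df.empty:
            raise EmptyOccurrenceError(f"no records for species {species!r} in {path}")
    else:
        names = df[sp_col].str.strip().unique()
        if len(names) > 1:
            raise ValueError(
                f"{path} contains multiple species {list(names)}; pass species= to select one"
            )
        species = str(names[0])

    records: list[Occurrence] = []
    lon_vals = df[lon_col].tolist()
    lat_vals = df[lat_col].tolist()
    src_vals = df[src_col].tolist() if src_col else [""] * len(df)
    for i, (raw_lon, raw_lat, raw_src) in enumerate(zip(lon_vals, lat_vals, src_vals)):
        row_number = i + 2  # 1-based, after the header line
        try:
            lon = float(raw_lon)
            lat = float(raw_lat)
        except (TypeError, ValueError):
            logger.warning("row %d: unparseable coordinate (%r, %r); skipped",
                           row_number, raw_lon, raw_lat)
            continue
        if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
            logger.warning("row %d: coordinate (%s, %s) out of range; skipped",
                           row_number, lon, lat)
            continue
        records.append(Occurrence(lon, lat, str(raw_src) if src_col else ""))
    if not records:
        raise EmptyOccurrenceError(f"{path} yielded no valid records")
    return OccurrenceSet(species=species, records=records, role=role)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_dataframe().to_csv(path, index=False)
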