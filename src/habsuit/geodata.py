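"""Locality tables, environmental rasters and vector/report serialization.

Grid convention: 0-based row/col, cell-centre registration, half-open
extents.  Row 0 is the northernmost row; a point samples the cell whose
centre block contains it (``floor`` on the fractional index).

Rasters are read and written as ESRI ASCII grids (plain text), localities
as delimited text (comma/tab autodetected), vector products as GeoJSON.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping

from .projection import equal_area_to_geographic, geographic_to_equal_area

logger = logging.getLogger(__name__)

PARAMETER_CODES = ("ALT", "TMA", "PMA", "GLC")

#: Global value ranges of the four environmental layers (validation only).
PARAMETER_RANGES = {
    "ALT": (0.0, 3350.0),
    "TMA": (-19.4, 32.0),
    "PMA": (0.0, 11401.0),
    "GLC": (1, 23),
}

#: Land-cover legend: GLC2000-style class codes.
LAND_COVER_LEGEND = {
    1: "Tree cover, broadleaved, evergreen",
    2: "Tree cover, broadleaved, deciduous, closed",
    3: "Tree cover, broadleaved, deciduous, open",
    7: "Tree cover, regularly flooded, fresh water",
    9: "Mosaic: Tree cover / Other natural vegetation",
    11: "Shrub cover, closed-open, evergreen",
    12: "Shrub cover, closed-open, deciduous",
    13: "Herbaceous cover, closed-open",
    14: "Sparse herbaceous or sparse shrub cover",
    15: "Regularly flooded shrub and/or herbaceous cover",
    16: "Cultivated and managed areas",
    17: "Mosaic: Cropland / Tree cover / Other natural vegetation",
    20: "Water bodies",
    22: "Artificial surfaces and associated areas",
}

WATER_CODES = frozenset({20})
ARTIFICIAL_CODES = frozenset({22})

#: Specimen-record counts of the four hermit-spider species with enough
#: georeferenced data to model (the two data-poor island endemics are
#: excluded); totals 751 records.
REFERENCE_SPECIES_COUNTS = {
    "Nephilengys cruentata": 436,
    "Nephilengys livida": 138,
    "Nephilengys malabarensis": 138,
    "Nephilengys papuana": 39,
}


class ConfigurationError(ValueError):
    """A run/file configuration problem (missing column, code mismatch...)."""


class InputError(ValueError):
    """Input data unusable (zero valid rows, all points off-grid...)."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# locality tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalityRecord:
    species: str
    lon: float
    lat: float
    record_id: str = ""


@dataclass
class LocalityTable:
    """Ordered presence records with per-species bookkeeping."""

    frame: pd.DataFrame  # columns: species, lon, lat, record_id

    def __post_init__(self) -> None:
        required = {"species", "lon", "lat"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"locality table missing columns: {sorted(missing)}")
        if "record_id" not in self.frame.columns:
            self.frame = self.frame.assign(
                record_id=[str(i) for i in range(len(self.frame))]
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def counts_by_species(self) -> dict[str, int]:
        return self.frame["species"].value_counts().to_dict()

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def subset(self, species: str) -> "LocalityTable":
        return LocalityTable(self.frame[self.frame["species"] == species].reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Iterable[LocalityRecord]) -> "LocalityTable":
        rows = [(r.species, r.lon, r.lat, r.record_id) for r in records]
        return cls(pd.DataFrame(rows, columns=["species", "lon", "lat", "record_id"]))


@dataclass
class ProjectedPoints:
    """Equal-area metric coordinates of a locality table (row-aligned)."""

    x: np.ndarray
    y: np.ndarray
    source: LocalityTable | None = None

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def read_locality_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> LocalityTable:
    """Read a delimited locality file (header row; comma or tab).

    ``column_map`` maps the logical names ``species``/``lon``/``lat``/``id``
    to the file's column headers.  Rows with unparseable or out-of-range
    coordinates are dropped with a logged warning, mirroring the exclusion
    of ambiguous records from the source data.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    delim = "\t" if sample.count("\t") >= sample.count(",") and "\t" in sample else ","
    df = pd.read_csv(path, sep=delim)

    cmap = dict(column_map or {})
    resolved = {}
    for logical in ("species", "lon", "lat"):
        col = cmap.get(logical, logical)
        if col not in df.columns:
            raise ConfigurationError(
                f"required column {logical!r} (mapped to {col!r}) not in {list(df.columns)}"
            )
        resolved[logical] = col
    id_col = cmap.get("id", "id")

    out = pd.DataFrame(
        {
            "species": df[resolved["species"]].astype(str),
            "lon": pd.to_numeric(df[resolved["lon"]], errors="coerce"),
            "lat": pd.to_numeric(df[resolved["lat"]], errors="coerce"),
        }
    )
    out["record_id"] = (
        df[id_col].astype(str) if id_col in df.columns else [str(i) for i in range(len(df))]
    )
    bad = (
        out["lon"].isna()
        | out["lat"].isna()
        | (out["lon"].abs() > 180)
        | (out["lat"].abs() > 90)
        | (out["species"].str.strip() == "")
    )
    if bad.any():
        logger.warning(
            "%s: dropped %d row(s) with missing/invalid coordinates or species",
            path.name,
            int(bad.sum()),
        )
    out = out[~bad].reset_index(drop=True)
    if len(out) == 0:
        raise InputError(f"{path}: no valid locality rows")
    return LocalityTable(out)


def project_points(table: LocalityTable) -> ProjectedPoints:
    """Project a locality table to equal-area metres (the analysis space)."""
    x, y = geographic_to_equal_area(
        table.frame["lon"].to_numpy(), table.frame["lat"].to_numpy()
    )
    return ProjectedPoints(x=np.atleast_1d(x), y=np.atleast_1d(y), source=table)


def unproject_points(points: ProjectedPoints) -> tuple[np.ndarray, np.ndarray]:
    return equal_area_to_geographic(points.x, points.y)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class EnvRaster:
    """Single-band georeferenced grid in geographic coordinates.

    ``west``/``north`` are the outer edges of the top-left cell;
    ``cell_size`` is in decimal degrees (square cells).
    """

    code: str
    grid: np.ndarray
    west: float
    north: float
    cell_size: float
    nodata: float = -9999.0
    categorical: bool = False

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise FormatError("cell size must be positive")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise FormatError("raster grid must be 2-D (single band)")
        if self.code == "GLC":
            self.categorical = True
            vals = np.unique(self.grid[self.grid != self.nodata])
            outside = [v for v in vals if not (1 <= v <= 23 and float(v).is_integer())]
            if outside:
                logger.warning("GLC raster contains codes outside the 1-23 legend: %s", outside)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell_size

    def same_geometry(self, other: "EnvRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices containing each point (half-open cell blocks)."""
        col = np.floor((np.asarray(lon, float) - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - np.asarray(lat, float)) / self.cell_size).astype(int)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell centre."""
        nrow, ncol = self.shape
        lon = self.west + (np.arange(ncol) + 0.5) * self.cell_size
        lat = self.north - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata


def read_env_raster(path: str | Path, code: str) -> EnvRaster:
    """Read a single-band ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        try:
            grid = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse grid body: {exc}") from exc

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII-grid header field {key!r}")
    if "xllcorner" not in header or "yllcorner" not in header:
        raise FormatError(f"{path}: missing georeference (xllcorner/yllcorner)")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: grid body {grid.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    return EnvRaster(
        code=code,
        grid=grid,
        west=header["xllcorner"],
        north=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
        categorical=(code == "GLC"),
    )


def write_env_raster(raster: EnvRaster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid; integer-valued grids round-trip bit-exactly."""
    path = Path(path)
    nrows, ncols = raster.shape
    is_int = np.all(
        np.mod(raster.grid[raster.grid != raster.nodata], 1) == 0
    ) and float(raster.nodata).is_integer()
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.west!r}\n")
        fh.write(f"yllcorner {raster.south!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        fmt = "%d" if is_int else "%.17g"
        np.savetxt(fh, raster.grid, fmt=fmt)
    return path


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# product writers
# ---------------------------------------------------------------------------

def write_geojson(geometry, path: str | Path, properties: dict | None = None) -> Path:
    """Write a shapely geometry (or list of (geom, props)) as GeoJSON."""
    path = Path(path)
    if isinstance(geometry, list):
        features = [
            {"type": "Feature", "geometry": shapely_mapping(g), "properties": p or {}}
            for g, p in geometry
        ]
    else:
        features = [
            {
                "type": "Feature",
                "geometry": shapely_mapping(geometry),
                "properties": properties or {},
            }
        ]
    payload = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def write_class_table_csv(rows: Iterable[dict], path: str | Path) -> Path:
    """Serialize frequency-class rows (parameter, bin, count, class) to CSV."""
    rows = list(rows)
    path = Path(path)
    fieldnames = list(rows[0].keys()) if rows else [
        "parameter", "bin_low", "bin_high", "category", "count", "rel_freq", "class",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return path


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
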