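"""Extract environmental values at localities and build frequency classes.

The suitability model is frequency-based: values of an environmental layer
observed often at known occurrences are taken as highly suitable, rare
values as marginally suitable, and values never observed as unsuitable
("outliers", mapped to NoData downstream).  Continuous layers are binned on
fixed-width half-open intervals [a, b); land cover is binned by category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    ConfigurationError,
    EnvRaster,
    InputError,
    LocalityTable,
    PARAMETER_CODES,
    PARAMETER_RANGES,
)

logger = logging.getLogger(__name__)

#: Default bin widths for the continuous layers (same units as the layer).
DEFAULT_BIN_WIDTHS = {"ALT": 100.0, "TMA": 1.0, "PMA": 100.0}

HIGH, MODERATE, LOW = 3, 2, 1


def extract_values(
    raster: EnvRaster, points: LocalityTable
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the raster at each locality (cell-centre registration).

    Returns ``(values, ok)`` where ``ok`` is False for points outside the
    raster extent or on NoData cells; those values are NaN.
    """
    lon = points.frame["lon"].to_numpy()
    lat = points.frame["lat"].to_numpy()
    row, col = raster.rowcol(lon, lat)
    nrow, ncol = raster.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    values = np.full(len(points), np.nan)
    ok = inside.copy()
    r, c = row[inside], col[inside]
    sampled = raster.grid[r, c]
    good = sampled != raster.nodata
    vals_inside = np.where(good, sampled, np.nan)
    values[inside] = vals_inside
    ok[np.flatnonzero(inside)[~good]] = False
    if not ok.any():
        raise InputError(f"all {len(points)} points fall outside {raster.code} or on NoData")
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: %d point(s) off-grid or on NoData", raster.code, n_bad)
    return values, ok


def build_attribute_table(
    localities: LocalityTable, rasters: dict[str, EnvRaster]
) -> pd.DataFrame:
    """One row per retained locality with all four layer values attached.

    Rows where any layer is NoData/off-grid are dropped (logged).  Values
    outside the layers' documented global ranges trigger a validation
    warning but are kept.
    """
    codes = list(rasters)
    if sorted(codes) != sorted(set(codes)):
        raise ConfigurationError("duplicate parameter code among rasters")
    unknown = set(codes) - set(PARAMETER_CODES)
    if unknown:
        raise ConfigurationError(f"unknown parameter codes: {sorted(unknown)}")
    if set(codes) != set(PARAMETER_CODES):
        missing = set(PARAMETER_CODES) - set(codes)
        raise ConfigurationError(f"missing rasters for: {sorted(missing)}")

    table = localities.frame[["species", "lon", "lat", "record_id"]].copy()
    keep = np.ones(len(table), dtype=bool)
    for code in PARAMETER_CODES:
        values, ok = extract_values(rasters[code], localities)
        table[code] = values
        keep &= ok
        lo, hi = PARAMETER_RANGES[code]
        valid = values[ok]
        if valid.size and ((valid < lo).any() or (valid > hi).any()):
            logger.warning(
                "%s values outside the documented global range [%s, %s]", code, lo, hi
            )
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("attribute table: dropped %d locality(ies) lacking full attributes", dropped)
    return table[keep].reset_index(drop=True)


@dataclass
class FrequencyTable:
    """Observed-frequency table for one parameter.

    For continuous parameters ``bins`` holds (low, high) edge pairs of the
    occupied fixed-width bins; for GLC it holds the observed category codes.
    """

    code: str
    bins: list[tuple[float, float]] | list[int]
    counts: np.ndarray
    categorical: bool

    @property
    def rel_freq(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class FrequencyClassTable:
    """Bin -> suitability class (high=3 / moderate=2 / low=1) mapping."""

    code: str
    bins: list[tuple[float, float]] | list[int]
    counts: np.ndarray
    classes: np.ndarray  # int, same length as bins
    categorical: bool

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Class for each value; 0 for outliers (never-observed values)."""
        values = np.asarray(values, dtype=float)
        out = np.zeros(values.shape, dtype=int)
        if self.categorical:
            for cat, cls in zip(self.bins, self.classes):
                out[values == cat] = int(cls)
        else:
            for (lo, hi), cls in zip(self.bins, self.classes):
                out[(values >= lo) & (values < hi)] = int(cls)
        return out

    def rows(self) -> list[dict]:
        """Serializable rows (the published-table analogue)."""
        rows = []
        for b, cnt, cls in zip(self.bins, self.counts, self.classes):
            row = {"parameter": self.code}
            if self.categorical:
                row.update(bin_low="", bin_high="", category=int(b))
            else:
                row.update(bin_low=b[0], bin_high=b[1], category="")
            row.update(count=int(cnt), rel_freq=float(cnt / self.counts.sum()),
                       **{"class": int(cls)})
            rows.append(row)
        return rows


def bin_parameter(
    values: np.ndarray, code: str, bin_width: float | None = None
) -> FrequencyTable:
    """Bin observed values: fixed-width [a, b) for continuous, category for GLC.

    Continuous edges are anchored at integer multiples of the width, so a
    value v lands in [width*floor(v/width), width*(floor(v/width)+1)).
    Empty bins are omitted.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise InputError(f"no values to bin for {code}")
    if code == "GLC":
        cats, counts = np.unique(values.astype(int), return_counts=True)
        return FrequencyTable(code, [int(c) for c in cats], counts, categorical=True)
    width = float(bin_width if bin_width is not None else DEFAULT_BIN_WIDTHS[code])
    idx = np.floor(values / width).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    bins = [(width * i, width * (i + 1)) for i in uniq]
    return FrequencyTable(code, bins, counts, categorical=False)


def classify_frequencies(
    freq: FrequencyTable, override: dict | None = None
) -> FrequencyClassTable:
    """Partition occupied bins into high/moderate/low frequency classes.

    Thresholds are the 66.7th and 33.3rd percentiles of the non-zero bin
    counts; a bin whose count ties a threshold is promoted to the higher
    class.  ``override`` (bin -> class) replaces the automatic rule.
    """
    counts = np.asarray(freq.counts)
    if counts.size == 0:
        raise InputError("frequency table has no occupied bins")
    if override is not None:
        classes = np.array([int(override[_key(b)]) for b in freq.bins])
    else:
        t_high = np.percentile(counts, 66.7)
        t_low = np.percentile(counts, 33.3)
        classes = np.where(counts >= t_high, HIGH, np.where(counts >= t_low, MODERATE, LOW))
    return FrequencyClassTable(
        code=freq.code,
        bins=freq.bins,
        counts=counts,
        classes=classes.astype(int),
        categorical=freq.categorical,
    )


def _key(b):
    return b if not isinstance(b, tuple) else b
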