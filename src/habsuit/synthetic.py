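"""Seeded synthetic environmental layers, niche-driven localities and point clouds.

The generators stand in for the global 1-km environmental layers and the
museum locality records: smooth correlated random-field surfaces for
elevation, temperature and precipitation; a categorical land-cover mosaic
with contiguous patches including water; and presence points preferentially
sampled where the environment falls inside a configurable niche window.
Every generator is a pure function of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import EnvRaster, InputError, LocalityTable, PARAMETER_RANGES, ProjectedPoints

#: land-cover codes used in the synthetic mosaic (a subset of the 1-23 legend)
_MOSAIC_CODES = [1, 2, 3, 9, 11, 12, 13, 14, 16, 17, 22]
WATER_CODE = 20

#: default synthetic value ranges (within the documented global ranges)
DEFAULT_SURFACE_RANGES = {
    "ALT": (0.0, 3350.0),
    "TMA": (-5.0, 32.0),
    "PMA": (0.0, 4000.0),
}


@dataclass
class NicheSpec:
    """Preference windows defining a synthetic species' niche.

    ``windows`` maps parameter codes to (low, high) value windows; a point
    is "in niche" when every windowed parameter falls inside its window.
    ``weight`` is the in-niche mixture fraction; the remainder is sampled
    uniformly over land.  ``grade`` tilts within-niche sampling toward the
    niche optimum (warm, low-elevation edge of the tolerance windows) —
    abundance declines toward tolerance limits rather than dropping off a
    cliff; 0 gives a flat window.
    """

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"TMA": (20.0, 32.0), "ALT": (0.0, 1000.0)}
    )
    weight: float = 0.75
    n: int = 300
    grade: float = 1.5
    species: str = "synthetic_sp"

    def __post_init__(self) -> None:
        for code, (lo, hi) in self.windows.items():
            glo, ghi = PARAMETER_RANGES[code]
            if lo < glo or hi > ghi or lo >= hi:
                raise InputError(
                    f"niche window for {code} [{lo}, {hi}] outside the global range"
                )
        if not (0.0 <= self.weight <= 1.0):
            raise InputError("mixture weight must be in [0, 1]")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  corr_cells: float = 10.0) -> np.ndarray:
    """Gaussian random field in [0, 1] via seeded smoothing of white noise."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=corr_cells, mode="reflect")
    f = f - f.min()
    rng_span = f.max() - f.min()
    return f / rng_span if rng_span > 0 else np.zeros(shape)


def gen_env_rasters(
    seed: int,
    shape: tuple[int, int] = (100, 100),
    west: float = 0.0,
    north: float = 25.0,
    cell_size: float = 0.5,
    water_fraction: float = 0.12,
    surface_ranges: dict[str, tuple[float, float]] | None = None,
    corr_cells: float = 4.0,
    corr_cells_fine: float = 1.0,
) -> dict[str, EnvRaster]:
    """Generate the four-layer environmental quartet.

    ALT/TMA/PMA are independent smooth surfaces rescaled into realistic
    sub-ranges of the documented global ranges; GLC is a patch mosaic over
    the remaining codes with ``water_fraction`` of cells set to water
    (code 20).  Elevation and temperature vary at the broad
    ``corr_cells`` scale; precipitation and land cover carry the finer
    ``corr_cells_fine`` texture (orographic rainfall and land-use patches
    vary at much shorter ranges than continental relief).
    """
    if shape[0] < 50 or shape[1] < 50:
        raise InputError("synthetic rasters must be at least 50x50")
    rng = np.random.default_rng(seed)
    ranges = {**DEFAULT_SURFACE_RANGES, **(surface_ranges or {})}

    alt01 = _smooth_field(rng, shape, corr_cells)
    tma01 = _smooth_field(rng, shape, corr_cells)
    pma01 = _smooth_field(rng, shape, corr_cells_fine)

    def scaled(f01, code):
        lo, hi = ranges[code]
        return lo + f01 * (hi - lo)

    water_field = _smooth_field(rng, shape, corr_cells)
    water = water_field <= np.quantile(water_field, water_fraction)
    mosaic_field = _smooth_field(rng, shape, corr_cells_fine)
    edges = np.quantile(mosaic_field, np.linspace(0, 1, len(_MOSAIC_CODES) + 1)[1:-1])
    glc = np.asarray(_MOSAIC_CODES)[np.searchsorted(edges, mosaic_field.ravel())]
    glc = glc.reshape(shape).astype(float)
    glc[water] = WATER_CODE

    common = dict(west=west, north=north, cell_size=cell_size, nodata=-9999.0)
    return {
        "ALT": EnvRaster(code="ALT", grid=scaled(alt01, "ALT"), **common),
        "TMA": EnvRaster(code="TMA", grid=scaled(tma01, "TMA"), **common),
        "PMA": EnvRaster(code="PMA", grid=scaled(pma01, "PMA"), **common),
        "GLC": EnvRaster(code="GLC", grid=glc, categorical=True, **common),
    }


def gen_localities(
    rasters: dict[str, EnvRaster],
    niche: NicheSpec,
    seed: int,
) -> tuple[LocalityTable, dict]:
    """Sample presence localities from the niche-weighted mixture.

    Points are placed at jittered positions inside their source cell (so
    each point samples exactly that cell's value), never on water or
    NoData.  Returns the table and a ground-truth record: which points
    were drawn in-niche and the niche cell mask.
    """
    rng = np.random.default_rng(seed)
    glc = rasters["GLC"]
    land = glc.valid_mask() & (glc.grid != WATER_CODE)
    in_niche = land.copy()
    for code, (lo, hi) in niche.windows.items():
        g = rasters[code].grid
        in_niche &= (g >= lo) & (g <= hi)
    if not in_niche.any():
        raise InputError("niche windows select no land cells on these rasters")

    # graded preference toward the warm/low-elevation optimum: TMA scores
    # upward within its window, every other windowed parameter downward
    score = np.zeros(glc.shape)
    for code, (lo, hi) in niche.windows.items():
        g01 = (rasters[code].grid - lo) / (hi - lo)
        score += g01 if code == "TMA" else (1.0 - g01)
    pref = np.exp(niche.grade * score)[in_niche]
    pref = pref / pref.sum()

    n_in = int(rng.binomial(niche.n, niche.weight))
    n_bg = niche.n - n_in
    niche_cells = np.flatnonzero(in_niche.ravel())
    land_cells = np.flatnonzero(land.ravel())
    chosen = np.concatenate(
        [
            rng.choice(niche_cells, size=n_in, replace=True, p=pref),
            rng.choice(land_cells, size=n_bg, replace=True),
        ]
    )
    labels = np.array([True] * n_in + [False] * n_bg)
    rows, cols = np.unravel_index(chosen, glc.shape)
    # jitter strictly inside the cell so the point samples its source cell
    u = rng.uniform(0.05, 0.95, size=len(chosen))
    v = rng.uniform(0.05, 0.95, size=len(chosen))
    lon = glc.west + (cols + u) * glc.cell_size
    lat = glc.north - (rows + v) * glc.cell_size
    frame = pd.DataFrame(
        {
            "species": niche.species,
            "lon": lon,
            "lat": lat,
            "record_id": [f"{niche.species}_{i}" for i in range(len(chosen))],
        }
    )
    truth = {
        "in_niche_label": labels,
        "n_in_niche": n_in,
        "niche_windows": dict(niche.windows),
        "niche_cell_mask": in_niche,
        "seed": seed,
    }
    return LocalityTable(frame), truth


def gen_gaussian_points(
    seed: int,
    n: int,
    mean: tuple[float, float] = (0.0, 0.0),
    covariance: np.ndarray | list = ((1.0, 0.0), (0.0, 1.0)),
) -> ProjectedPoints:
    """Seeded bivariate-normal point cloud in projected metres."""
    cov = np.asarray(covariance, dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if (eig <= 0).any():
        raise InputError("covariance must be positive definite")
    rng = np.random.default_rng(seed)
    pts = rng.multivariate_normal(mean, cov, size=n)
    return ProjectedPoints(x=pts[:, 0], y=pts[:, 1])


def gen_two_regime_data(
    seed: int,
    n: int = 200,
    slopes: tuple[float, float] = (2.0, -2.0),
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray, ProjectedPoints, np.ndarray]:
    """Spatially varying-slope fixture: two clusters with opposite slopes.

    Returns (X, y, points, cluster labels).  Cluster 0 sits at the origin,
    cluster 1 is offset far enough that adaptive kernels never mix them.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.repeat([0, 1], [half, n - half])
    offset = np.where(labels == 1, 1e6, 0.0)
    x_coord = rng.uniform(0, 1e5, n) + offset
    y_coord = rng.uniform(0, 1e5, n)
    x1 = rng.uniform(-1, 1, n)
    slope = np.where(labels == 0, slopes[0], slopes[1])
    y = 1.0 + slope * x1 + rng.normal(0, noise_sd, n)
    X = pd.DataFrame({"x1": x1})
    return X, y, ProjectedPoints(x=x_coord, y=y_coord), labels
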