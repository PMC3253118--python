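"""Rank rasters, equal-weight combination, focal smoothing, final classes.

Within the masked ellipse each of the two selected parameters is
reclassified through its frequency-class table to a rank raster
(high = 3, moderate = 2, low = 1; values never observed at any locality
are NoData — "outliers").  The two rank rasters are combined with equal
weight (cellwise mean), smoothed with a circular focal mean of radius 9
cells, and cut back into three display classes on equal thirds of the
attainable [1, 3] range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geodata import (
    ConfigurationError,
    EnvRaster,
    InputError,
    LocalityTable,
    project_points,
)
from .gwr import GWRConfig, GWRResult, fit_gwr
from .sampling import (
    FrequencyClassTable,
    bin_parameter,
    build_attribute_table,
    classify_frequencies,
)
from .selection import (
    OLSResult,
    SelectionTrace,
    backward_select,
    fit_ols,
    presence_intensity_response,
)
from .spatial import (
    DirectionalEllipse,
    MoranResult,
    build_weights,
    directional_distribution,
    ellipse_mask,
    morans_i,
)

logger = logging.getLogger(__name__)

NODATA_RANK = 0          # internal NoData sentinel for integer rank grids
FOCAL_RADIUS_DEFAULT = 9
MIN_RECORDS_DEFAULT = 30
R2_GAP_THRESHOLD = 0.15


@dataclass
class RankRaster:
    code: str
    grid: np.ndarray          # int: 3/2/1, NODATA_RANK where undefined
    template: EnvRaster       # geometry donor

    def __post_init__(self) -> None:
        bad = ~np.isin(self.grid, [0, 1, 2, 3])
        if bad.any():
            raise ValueError("rank grid may only hold {3,2,1,NoData}")


def rank_raster(
    raster: EnvRaster, classes: FrequencyClassTable, mask: np.ndarray
) -> RankRaster:
    """Reclassify a layer through its frequency classes inside the mask."""
    if raster.code != classes.code:
        raise ConfigurationError(
            f"class table is for {classes.code!r}, raster is {raster.code!r}"
        )
    ranks = classes.lookup(raster.grid)
    ranks[~mask] = NODATA_RANK
    ranks[~raster.valid_mask()] = NODATA_RANK
    return RankRaster(code=raster.code, grid=ranks.astype(int), template=raster)


def combine_equal_weight(r1: RankRaster, r2: RankRaster) -> np.ndarray:
    """Cellwise mean of two rank grids; NaN where either is NoData."""
    if r1.grid.shape != r2.grid.shape or not r1.template.same_geometry(r2.template):
        raise ConfigurationError("rank rasters have mismatching geometry")
    out = (r1.grid + r2.grid) / 2.0
    out[(r1.grid == NODATA_RANK) | (r2.grid == NODATA_RANK)] = np.nan
    return out


def disk_offsets(radius_cells: float) -> np.ndarray:
    """Footprint of the circular neighbourhood: all cells whose centres lie
    within Euclidean distance ``radius_cells`` (in cell units) of the centre."""
    r = int(np.floor(radius_cells))
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return (di**2 + dj**2) <= radius_cells**2


def focal_smooth(grid: np.ndarray, radius_cells: float = FOCAL_RADIUS_DEFAULT) -> np.ndarray:
    """Circular focal mean ignoring NaN neighbours.

    The neighbourhood is clipped at grid edges; a NaN centre stays NaN
    (smoothing never invents suitability outside the ranked domain).
    """
    if radius_cells < 0:
        raise InputError("radius must be >= 0")
    if radius_cells < 1:
        return grid.copy()
    footprint = disk_offsets(radius_cells).astype(float)
    valid = np.isfinite(grid).astype(float)
    filled = np.where(np.isfinite(grid), grid, 0.0)
    sums = ndimage.convolve(filled, footprint, mode="constant", cval=0.0)
    counts = ndimage.convolve(valid, footprint, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    mean[~np.isfinite(grid)] = np.nan
    return mean


def classify_suitability(smoothed: np.ndarray) -> np.ndarray:
    """Equal-thirds cut of [1, 3] back to {1, 2, 3}; boundaries go upward.

    [1, 5/3) -> low, [5/3, 7/3) -> moderate, [7/3, 3] -> high.
    """
    finite = smoothed[np.isfinite(smoothed)]
    if finite.size and ((finite < 1 - 1e-9) | (finite > 3 + 1e-9)).any():
        raise ValueError("smoothed suitability outside [1, 3]: upstream contract violated")
    out = np.zeros(smoothed.shape, dtype=int)
    ok = np.isfinite(smoothed)
    out[ok & (smoothed < 5.0 / 3.0)] = 1
    out[ok & (smoothed >= 5.0 / 3.0) & (smoothed < 7.0 / 3.0)] = 2
    out[ok & (smoothed >= 7.0 / 3.0)] = 3
    return out


@dataclass
class SuitabilityMap:
    species: str
    classified: np.ndarray        # int {3,2,1}, 0 = NoData
    continuous: np.ndarray        # float, NaN = NoData
    ellipse: DirectionalEllipse
    template: EnvRaster
    legend: dict = field(default_factory=lambda: {3: "high", 2: "moderate", 1: "low"})


@dataclass
class SpeciesModelReport:
    species: str
    n_records: int
    selected_pair: list[str]
    ols: OLSResult | None
    ols_full: OLSResult | None
    trace: SelectionTrace | None
    gwr: GWRResult | None
    moran: MoranResult | None
    skipped: bool = False
    skip_reason: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def r2_gap_flag(self) -> bool:
        """True iff the raw-vs-adjusted R^2 gap of the GWR fit exceeds 0.15
        (a large gap signals overfitting of the local model)."""
        if self.gwr is None:
            return False
        return (self.gwr.r2 - self.gwr.adj_r2) > R2_GAP_THRESHOLD

    def to_dict(self) -> dict:
        out = {
            "species": self.species,
            "n_records": self.n_records,
            "skipped": self.skipped,
            "skip_reason": self.skip_reason,
            "selected_pair": self.selected_pair,
            "r2_gap_flag": self.r2_gap_flag,
            "notes": self.notes,
        }
        if self.ols_full is not None:
            out["ols_all_parameters"] = self.ols_full.summary_dict()
        if self.ols is not None:
            out["ols_selected_pair"] = self.ols.summary_dict()
        if self.trace is not None:
            out["selection"] = self.trace.to_dict()
        if self.gwr is not None:
            out["gwr"] = self.gwr.summary_dict()
        if self.moran is not None:
            out["moran"] = self.moran.to_dict()
        return out


def run_species_model(
    localities: LocalityTable,
    rasters: dict[str, EnvRaster],
    species: str,
    *,
    bin_widths: dict[str, float] | None = None,
    response_radius_km: float = 100.0,
    vif_threshold: float = 7.5,
    k_neighbors: int = 10,
    moran_scheme: str = "inverse_distance",
    n_sd: float = 3.0,
    radius_cells: float = FOCAL_RADIUS_DEFAULT,
    min_records: int = MIN_RECORDS_DEFAULT,
    class_overrides: dict | None = None,
) -> tuple[SpeciesModelReport, SuitabilityMap | None]:
    """The full per-species chain.

    extract -> backward OLS selection -> GWR on the selected pair ->
    Moran's I on GWR residuals -> 3-SD directional ellipse -> frequency
    classes -> rank rasters -> equal-weight combine -> circular focal
    mean -> three-class map.  Deterministic for fixed inputs.
    """
    sub = localities.subset(species)
    if len(sub) < min_records:
        report = SpeciesModelReport(
            species=species,
            n_records=len(sub),
            selected_pair=[],
            ols=None,
            ols_full=None,
            trace=None,
            gwr=None,
            moran=None,
            skipped=True,
            skip_reason=(
                f"only {len(sub)} records (< min_records={min_records}); "
                "too poorly represented to model"
            ),
        )
        logger.info("%s skipped: %s", species, report.skip_reason)
        return report, None

    attr = build_attribute_table(sub, rasters)
    retained = LocalityTable(attr[["species", "lon", "lat", "record_id"]].copy())
    points = project_points(retained)
    y = presence_intensity_response(points, radius_km=response_radius_km)

    X_all = attr[["ALT", "TMA", "PMA", "GLC"]].astype(float)
    trace = backward_select(X_all, y, vif_threshold=vif_threshold)
    pair = trace.selected
    ols_full = None
    try:
        ols_full = fit_ols(X_all, y)
    except Exception as exc:  # full model may be singular; the trace survives
        logger.warning("full OLS model not reportable: %s", exc)
    ols_pair = fit_ols(X_all[pair], y)

    gwr_res = fit_gwr(X_all[pair], y, points, GWRConfig(k_neighbors=k_neighbors))

    # Moran's I on GWR residuals at unique coordinates (mean residual per
    # coordinate) — duplicate localities carry no extra spatial information.
    coords = np.round(points.xy, 6)
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    resid_u = np.zeros(len(uniq))
    np.add.at(resid_u, inv, gwr_res.residuals)
    counts = np.bincount(inv)
    resid_u /= counts
    from .geodata import ProjectedPoints  # local import to avoid cycle noise

    pts_u = ProjectedPoints(x=uniq[:, 0], y=uniq[:, 1])
    moran = morans_i(resid_u, build_weights(pts_u, scheme=moran_scheme))

    ellipse = directional_distribution(points, n_sd=n_sd)
    mask = ellipse_mask(ellipse, rasters["GLC"])

    widths = dict(bin_widths or {})
    rank_maps = []
    for code in pair:
        freq = bin_parameter(attr[code].to_numpy(), code, widths.get(code))
        override = (class_overrides or {}).get(code)
        classes = classify_frequencies(freq, override=override)
        rank_maps.append(rank_raster(rasters[code], classes, mask))
    combined = combine_equal_weight(rank_maps[0], rank_maps[1])
    smoothed = focal_smooth(combined, radius_cells=radius_cells)
    classified = classify_suitability(smoothed)

    cell_km = rasters[pair[0]].cell_size * 111.32  # informational only
    report = SpeciesModelReport(
        species=species,
        n_records=len(attr),
        selected_pair=pair,
        ols=ols_pair,
        ols_full=ols_full,
        trace=trace,
        gwr=gwr_res,
        moran=moran,
        notes=[
            "response variable: ln(1 + conspecific records within "
            f"{response_radius_km} km) — a presence-intensity proxy for habitat "
            "suitability; absolute fit metrics depend on this assumption",
            f"Moran features: {len(uniq)} unique coordinates from {len(attr)} records",
            f"focal radius {radius_cells} cells ~= {radius_cells * cell_km:.2f} km at this resolution",
        ],
    )
    suit = SuitabilityMap(
        species=species,
        classified=classified,
        continuous=smoothed,
        ellipse=ellipse,
        template=rasters["GLC"],
    )
    return report, suit
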