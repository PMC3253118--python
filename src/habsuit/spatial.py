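"""Spatial autocorrelation diagnostics and the directional distribution.

Two independent spatial summaries close the modelling loop:

* **Global Moran's I** on regression residuals, with the analytic
  expectation E[I] = -1/(n-1), the randomization (permutation-moment)
  variance, a normal z-score and a two-sided p-value.  A well behaved
  model leaves residuals indistinguishable from spatial noise.
* **The directional distribution** (standard deviational ellipse): an
  ellipse centred on the mean of the projected localities whose semi-axes
  are three standard deviations along the rotated principal directions.
  For bivariate-normal scatter the 3-SD ellipse covers 1 - exp(-9/2)
  (about 98.9%) of points; the terrestrial cells inside it delimit the
  species' potential target area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .geodata import EnvRaster, InputError, ProjectedPoints, WATER_CODES
from .projection import geographic_to_equal_area

logger = logging.getLogger(__name__)

N_SD_DEFAULT = 3.0
ELLIPSE_VERTICES = 360

PATTERN_LABELS = (
    "random",
    "quasi-random",
    "quasi-clustered",
    "quasi-dispersed",
    "clustered",
    "dispersed",
)


class DegeneracyError(ValueError):
    """Statistic undefined for this input (constant values, collinear points)."""


# ---------------------------------------------------------------------------
# spatial weights + Moran's I
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    w: np.ndarray          # n x n, zero diagonal
    scheme: str

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def build_weights(
    points: ProjectedPoints,
    scheme: str = "inverse_distance",
    k: int = 8,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Spatial weights among localities.

    ``inverse_distance`` (default): w_ij = 1/d_ij.  Coincident pairs would
    give infinite weight; they are capped at the weight of the nearest
    distinct pair.  ``k_nearest``: w_ij = 1 for the k nearest neighbours
    of i.  Optional row standardization scales each row to sum 1.
    """
    n = len(points)
    if n < 4:
        raise InputError(f"need at least 4 points for spatial weights (got {n})")
    d = cdist(points.xy, points.xy)
    if scheme == "inverse_distance":
        off = d[~np.eye(n, dtype=bool)]
        pos = off[off > 0]
        if pos.size == 0:
            raise DegeneracyError("all points coincident")
        if (off == 0).any():
            logger.warning("coincident points: inverse-distance weight capped")
        dmin = pos.min()
        with np.errstate(divide="ignore"):
            w = 1.0 / np.where(d == 0, dmin, d)
        np.fill_diagonal(w, 0.0)
    elif scheme == "k_nearest":
        if not (1 <= k < n):
            raise InputError(f"k_nearest needs 1 <= k < n (k={k}, n={n})")
        w = np.zeros((n, n))
        order = np.argsort(d + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1)
        for i in range(n):
            w[i, order[i, :k]] = 1.0
    else:
        raise InputError(f"unknown weights scheme {scheme!r}")
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeights(w=w, scheme=scheme)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    n: int
    pattern: str = ""

    def to_dict(self) -> dict:
        return {
            "morans_I": self.I,
            "expected_I": self.expected,
            "variance": self.variance,
            "z_score": self.z,
            "p_value": self.p_value,
            "n": self.n,
            "pattern": self.pattern,
        }


def morans_i(values: np.ndarray, W: SpatialWeights, permutations: int = 0,
             rng: np.random.Generator | None = None) -> MoranResult:
    """Global Moran's I with randomization inference.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values.  The variance uses the permutation-moment (randomization)
    assumption; significance is a two-sided normal test.  If
    ``permutations`` > 0 a Monte-Carlo p-value is computed as a
    cross-check and returned in place of the analytic one.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n != W.n:
        raise InputError("values and weights dimensions differ")
    z = z - z.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise DegeneracyError("Moran's I undefined for constant values")
    w = W.w
    s0 = W.s0
    I = (n / s0) * float(z @ w @ z) / m2

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    m4 = float(np.mean(z**4))
    b2 = m4 / (m2 / n) ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var = num / den - e_i**2
    var = max(var, 0.0)
    zscore = (I - e_i) / np.sqrt(var) if var > 0 else np.nan
    p = 2 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan

    if permutations > 0:
        rng = rng or np.random.default_rng(0)
        sims = np.empty(permutations)
        for s in range(permutations):
            zp = rng.permutation(z)
            sims[s] = (n / s0) * float(zp @ w @ zp) / m2
        extreme = np.sum(np.abs(sims - e_i) >= abs(I - e_i))
        p = (extreme + 1) / (permutations + 1)

    result = MoranResult(I=float(I), expected=float(e_i), variance=float(var),
                         z=float(zscore), p_value=float(p), n=n)
    result.pattern = classify_pattern(result)
    return result


def classify_pattern(result: MoranResult) -> str:
    """Label the spatial pattern from significance and the sign of I - E[I].

    p >= 0.10 -> random; 0.05 <= p < 0.10 -> quasi-random;
    0.001 <= p < 0.05 -> quasi-clustered / quasi-dispersed;
    p < 0.001 -> clustered / dispersed.
    """
    p = result.p_value
    positive = (result.I - result.expected) > 0
    if not np.isfinite(p) or p >= 0.10:
        return "random"
    if p >= 0.05:
        return "quasi-random"
    if p >= 0.001:
        return "quasi-clustered" if positive else "quasi-dispersed"
    return "clustered" if positive else "dispersed"


# ---------------------------------------------------------------------------
# directional distribution (standard deviational ellipse)
# ---------------------------------------------------------------------------

@dataclass
class DirectionalEllipse:
    center_x: float
    center_y: float
    theta: float          # radians clockwise from north
    semi_x: float         # n_sd * sigma along the rotated x' axis (metres)
    semi_y: float         # n_sd * sigma along the rotated y' axis (metres)
    n_sd: float

    @property
    def area_m2(self) -> float:
        return float(np.pi * self.semi_x * self.semi_y)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-ellipse test in projected coordinates."""
        dx = np.asarray(x, float) - self.center_x
        dy = np.asarray(y, float) - self.center_y
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = dx * ct - dy * st
        v = dx * st + dy * ct
        return (u / self.semi_x) ** 2 + (v / self.semi_y) ** 2 <= 1.0

    def polygon(self, n_vertices: int = ELLIPSE_VERTICES) -> Polygon:
        """Closed polygon ring approximating the ellipse boundary."""
        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        u = self.semi_x * np.cos(t)
        v = self.semi_y * np.sin(t)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.center_x + u * ct + v * st
        y = self.center_y - u * st + v * ct
        return Polygon(np.column_stack([x, y]))

    def to_dict(self) -> dict:
        return {
            "center_x_m": self.center_x,
            "center_y_m": self.center_y,
            "rotation_deg_cw_from_north": float(np.degrees(self.theta)),
            "semi_axis_x_m": self.semi_x,
            "semi_axis_y_m": self.semi_y,
            "n_sd": self.n_sd,
            "area_km2": self.area_m2 / 1e6,
        }


def directional_distribution(points: ProjectedPoints, n_sd: float = N_SD_DEFAULT) -> DirectionalEllipse:
    """Standard deviational ellipse of a projected point set.

    Centre = coordinate mean.  Rotation theta (clockwise from north)
    satisfies tan(theta) = (A + sqrt(A^2 + 4C^2)) / (2C) with
    A = sum(x'^2) - sum(y'^2), C = sum(x'y') over mean deviations.  The
    standard deviations along the rotated axes are scaled by ``n_sd``
    (default 3) with no small-sample correction, so a bivariate-normal
    cloud is covered at the 1 - exp(-n_sd^2/2) level (~98.9% for 3 SD).
    """
    n = len(points)
    if n < 3:
        raise InputError(f"directional distribution needs >= 3 points (got {n})")
    xbar, ybar = points.x.mean(), points.y.mean()
    dx = points.x - xbar
    dy = points.y - ybar
    a = float(np.sum(dx**2) - np.sum(dy**2))
    c = float(np.sum(dx * dy))
    if c == 0.0:
        theta = 0.0 if np.sum(dy**2) >= np.sum(dx**2) else np.pi / 2
    else:
        theta = np.arctan((a + np.hypot(a, 2 * c)) / (2 * c))
        if theta < 0:
            theta += np.pi
    ct, st = np.cos(theta), np.sin(theta)
    sx = np.sqrt(np.mean((dx * ct - dy * st) ** 2))
    sy = np.sqrt(np.mean((dx * st + dy * ct) ** 2))
    if min(sx, sy) <= 1e-9 * max(sx, sy, 1e-300):
        raise DegeneracyError("collinear points give a degenerate ellipse")
    return DirectionalEllipse(
        center_x=float(xbar),
        center_y=float(ybar),
        theta=float(theta),
        semi_x=float(n_sd * sx),
        semi_y=float(n_sd * sy),
        n_sd=float(n_sd),
    )


def ellipse_mask(ellipse: DirectionalEllipse, glc: EnvRaster) -> np.ndarray:
    """Boolean grid: cell centre inside the ellipse AND terrestrial.

    Water cells (land-cover code 20) and NoData are excluded — the
    potential target area is all terrestrial habitat within the ellipse.
    """
    lon, lat = glc.cell_centers()
    x, y = geographic_to_equal_area(lon.ravel(), lat.ravel())
    inside = ellipse.contains(x, y).reshape(glc.shape)
    land = glc.valid_mask() & ~np.isin(glc.grid, list(WATER_CODES))
    mask = inside & land
    if not mask.any():
        logger.warning("ellipse mask is empty (no terrestrial cells inside the ellipse)")
    return mask
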