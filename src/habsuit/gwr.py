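"""Geographically weighted regression with an adaptive bisquare kernel.

Each locality gets its own weighted least-squares fit: weights decay with
distance under a bisquare kernel whose reach (bandwidth) is the distance to
the k-th nearest neighbour, so the kernel adapts to local point density.
The fit is diagnostic: local coefficients and their spatial variation show
where each environmental parameter matters, and the corrected Akaike
criterion compares the spatially varying model against the global OLS fit.

AICc follows the small-sample geographically-weighted form:

    AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S))

with sigma_hat^2 = RSS/n and S the hat matrix mapping y to fitted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geodata import ConfigurationError, InputError, ProjectedPoints

logger = logging.getLogger(__name__)

K_NEIGHBORS_DEFAULT = 10
_RIDGE = 1e-8


@dataclass
class GWRConfig:
    k_neighbors: int = K_NEIGHBORS_DEFAULT
    kernel: str = "bisquare"   # "boxcar" is a near-flat test hook
    bandwidth_mode: str = "adaptive"


@dataclass
class GWRResult:
    predictors: list[str]
    local_params: pd.DataFrame   # n rows, columns: const + predictors
    fitted: np.ndarray
    residuals: np.ndarray
    bandwidths: np.ndarray       # metres, per locality
    trace_S: float
    sigma_hat: float
    aicc: float | None
    r2: float
    adj_r2: float
    nobs: int

    def coefficient_summary(self) -> dict:
        q = self.local_params.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        return {c: q[c].to_dict() for c in self.local_params.columns}

    def summary_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "AICc": self.aicc,
            "R2": self.r2,
            "adj_R2": self.adj_r2,
            "trace_S": self.trace_S,
            "bandwidth_m": {
                "min": float(self.bandwidths.min()),
                "median": float(np.median(self.bandwidths)),
                "max": float(self.bandwidths.max()),
            },
            "n": self.nobs,
            "local_coefficients": self.coefficient_summary(),
        }


def adaptive_bandwidths(points: ProjectedPoints, k: int = K_NEIGHBORS_DEFAULT) -> np.ndarray:
    """Distance from each point to its k-th nearest neighbour (self excluded).

    Coincident points that would yield a zero bandwidth get the smallest
    positive neighbour distance instead (with a warning).
    """
    n = len(points)
    if n <= k:
        raise InputError(f"adaptive bandwidth needs n > k (n={n}, k={k})")
    d = cdist(points.xy, points.xy)
    d_sorted = np.sort(d, axis=1)       # column 0 is the self-distance 0
    h = d_sorted[:, k]
    if np.any(h <= 0):
        pos = np.where(d_sorted > 0, d_sorted, np.inf).min(axis=1)
        bad = h <= 0
        logger.warning("%d coincident bandwidth(s) replaced by nearest distinct distance", bad.sum())
        h = np.where(bad, pos, h)
    return h


def kernel_weight(d: np.ndarray, h: float, kernel: str = "bisquare") -> np.ndarray:
    """Distance-decay weight.  Bisquare: w = (1 - (d/h)^2)^2 for d < h, else 0."""
    d = np.asarray(d, dtype=float)
    if kernel == "bisquare":
        u = d / h
        w = (1 - u**2) ** 2
        return np.where(d < h, w, 0.0)
    if kernel == "boxcar":
        return np.where(d < h, 1.0, 0.0)
    raise ConfigurationError(f"unknown kernel {kernel!r}")


def fit_gwr(
    X: pd.DataFrame,
    y: np.ndarray,
    points: ProjectedPoints,
    config: GWRConfig | None = None,
) -> GWRResult:
    """Fit a local regression at every locality.

    At locality i, beta_i = (X'W_i X)^-1 X'W_i y with W_i from the adaptive
    kernel centred on i.  A locally singular design is regularized with a
    tiny ridge (1e-8) and a warning.
    """
    config = config or GWRConfig()
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if len(points) != n or len(y) != n:
        raise InputError("X, y and points must be row-aligned")
    h = adaptive_bandwidths(points, config.k_neighbors)
    d = cdist(points.xy, points.xy)

    names = ["const"] + list(X.columns)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p = A.shape[1]
    betas = np.empty((n, p))
    fitted = np.empty(n)
    trace_S = 0.0
    n_singular = 0
    for i in range(n):
        w = kernel_weight(d[i], h[i], config.kernel)
        Aw = A * w[:, None]
        xtwx = A.T @ Aw
        xtwy = Aw.T @ y
        try:
            beta = np.linalg.solve(xtwx, xtwy)
            # hat row element: s_ii = a_i (X'WX)^-1 X'W e_i
            s_row_i = A[i] @ np.linalg.solve(xtwx, Aw.T[:, i])
        except np.linalg.LinAlgError:
            n_singular += 1
            xtwx = xtwx + _RIDGE * np.eye(p)
            beta = np.linalg.solve(xtwx, xtwy)
            s_row_i = A[i] @ np.linalg.solve(xtwx, Aw.T[:, i])
        betas[i] = beta
        fitted[i] = A[i] @ beta
        trace_S += s_row_i
    if n_singular:
        logger.warning(
            "locally singular design at %d/%d localities (duplicate coordinates "
            "or locally constant predictors); ridge 1e-8 applied", n_singular, n
        )

    resid = y - fitted
    rss = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else 0.0
    sigma = np.sqrt(max(rss, 1e-300) / n)
    denom = n - 2.0 - trace_S
    if denom <= 0:
        logger.warning("AICc undefined: n - 2 - tr(S) = %.3f <= 0", denom)
        aicc = None
    else:
        aicc = float(2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + trace_S) / denom)
    # effective parameters = tr(S), by analogy with the linear smoother df
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - trace_S) if n > trace_S else r2
    return GWRResult(
        predictors=list(X.columns),
        local_params=pd.DataFrame(betas, columns=names),
        fitted=fitted,
        residuals=resid,
        bandwidths=h,
        trace_S=float(trace_S),
        sigma_hat=float(sigma),
        aicc=aicc,
        r2=float(r2),
        adj_r2=float(adj_r2),
        nobs=n,
    )


def hat_matrix(
    X: pd.DataFrame, points: ProjectedPoints, config: GWRConfig | None = None
) -> np.ndarray:
    """Explicit n x n smoother matrix S (row i maps y to fitted value i).

    O(n^2 p) memory/time — intended for diagnostics and small n.
    """
    config = config or GWRConfig()
    n = len(points)
    h = adaptive_bandwidths(points, config.k_neighbors)
    d = cdist(points.xy, points.xy)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    S = np.empty((n, n))
    for i in range(n):
        w = kernel_weight(d[i], h[i], config.kernel)
        Aw = A * w[:, None]
        xtwx = A.T @ Aw
        try:
            S[i] = A[i] @ np.linalg.solve(xtwx, Aw.T)
        except np.linalg.LinAlgError:
            S[i] = A[i] @ np.linalg.solve(xtwx + _RIDGE * np.eye(A.shape[1]), Aw.T)
    return S


def coefficient_surface(
    result: GWRResult,
    points: ProjectedPoints,
    predictor: str,
    grid_shape: tuple[int, int] | None = None,
    idw_power: float = 2.0,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Per-locality coefficients for one predictor, optionally IDW-gridded.

    The point export is the model output; the inverse-distance-weighted
    grid is a visualization convenience only.
    """
    if predictor not in result.local_params.columns:
        raise ConfigurationError(
            f"predictor {predictor!r} not in model {list(result.local_params.columns)}"
        )
    table = pd.DataFrame(
        {
            "x": points.x,
            "y": points.y,
            "coefficient": result.local_params[predictor].to_numpy(),
            "residual": result.residuals,
        }
    )
    grid = None
    if grid_shape is not None:
        ny, nx = grid_shape
        gx = np.linspace(points.x.min(), points.x.max(), nx)
        gy = np.linspace(points.y.max(), points.y.min(), ny)
        GX, GY = np.meshgrid(gx, gy)
        pts = np.column_stack([GX.ravel(), GY.ravel()])
        dist = cdist(pts, points.xy)
        dist = np.maximum(dist, 1e-9)
        wts = dist ** (-idw_power)
        vals = (wts @ table["coefficient"].to_numpy()) / wts.sum(axis=1)
        grid = vals.reshape(ny, nx)
    return table, grid
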