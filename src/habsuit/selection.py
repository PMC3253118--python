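"""Global OLS screening with robust probabilities, VIF and backward elimination.

The screening stage regresses a presence-intensity response on the four
candidate environmental parameters, removes collinear predictors (largest
VIF above the threshold first), then drops the least significant predictor
(largest robust probability) until exactly two remain.  The survivors feed
the geographically weighted stage.

The response variable for presence-only data is, by default, the log count
of conspecific records within a configurable radius of each locality —
an observed local presence intensity standing in for habitat suitability.
This choice is recorded in every report: it is an assumption, and absolute
fit metrics depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist

from .geodata import InputError, ProjectedPoints

VIF_THRESHOLD_DEFAULT = 7.5
RESPONSE_RADIUS_KM_DEFAULT = 100.0


class SingularityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class OLSResult:
    predictors: list[str]
    params: pd.Series            # includes "const"
    bse: pd.Series               # classical standard errors
    robust_bse: pd.Series        # HC0 standard errors
    robust_p: pd.Series          # t-based probabilities from HC0 covariance
    r2: float
    adj_r2: float
    aic: float
    vif: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    nobs: int

    def summary_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coefficients": self.params.to_dict(),
            "robust_p": self.robust_p.to_dict(),
            "VIF": self.vif.to_dict(),
            "R2": self.r2,
            "adj_R2": self.adj_r2,
            "AIC": self.aic,
            "n": self.nobs,
        }


@dataclass
class SelectionStep:
    removed: str
    reason: str                  # "VIF" or "robust-p"
    metric: float
    aic_before: float
    aic_after: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    selected: list[str]
    final: OLSResult

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "removed": s.removed,
                    "reason": s.reason,
                    "metric": s.metric,
                    "AIC_before": s.aic_before,
                    "AIC_after": s.aic_after,
                }
                for s in self.steps
            ],
            "selected": self.selected,
        }


def presence_intensity_response(
    points: ProjectedPoints, radius_km: float = RESPONSE_RADIUS_KM_DEFAULT
) -> np.ndarray:
    """y_i = ln(1 + number of other conspecific records within ``radius_km``).

    A smooth, always-defined proxy for local habitat suitability derived
    from the presence records alone.
    """
    d = cdist(points.xy, points.xy)
    within = (d <= radius_km * 1000.0).sum(axis=1) - 1  # exclude self
    return np.log1p(within.astype(float))


def fit_ols(X: pd.DataFrame, y: np.ndarray) -> OLSResult:
    """OLS with classical and heteroskedasticity-consistent (HC0) inference.

    AIC uses the Gaussian likelihood: n*ln(2*pi*SSE/n) + n + 2*(k+1).
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise InputError(f"need n > k+1 observations (n={n}, k={k})")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = _collinear_columns(Xc)
        raise SingularityError(f"design matrix rank deficient; collinear columns: {collinear}")
    fit = sm.OLS(y, Xc).fit()
    robust = fit.get_robustcov_results(cov_type="HC0", use_t=True)
    sse = float(np.sum(fit.resid**2))
    aic = n * np.log(2 * np.pi * max(sse, 1e-300) / n) + n + 2 * (k + 1)
    names = list(Xc.columns)
    rsq = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    return OLSResult(
        predictors=list(X.columns),
        params=pd.Series(fit.params.values, index=names),
        bse=pd.Series(fit.bse.values, index=names),
        robust_bse=pd.Series(np.asarray(robust.bse), index=names),
        robust_p=pd.Series(np.asarray(robust.pvalues), index=names),
        r2=rsq,
        adj_r2=float(1 - (1 - rsq) * (n - 1) / (n - k - 1)),
        aic=float(aic),
        vif=compute_vif(X),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        nobs=n,
    )


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j), R^2_j from regressing column j on the others.

    A single predictor has VIF 1 by definition; perfect collinearity is
    reported as ``inf`` rather than raised.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return pd.Series(1.0, index=cols)
    out = {}
    A = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        yj = A[:, j]
        others = np.delete(A, j, axis=1)
        D = np.column_stack([np.ones(len(yj)), others])
        beta, *_ = np.linalg.lstsq(D, yj, rcond=None)
        resid = yj - D @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def backward_select(
    X: pd.DataFrame,
    y: np.ndarray,
    vif_threshold: float = VIF_THRESHOLD_DEFAULT,
    n_keep: int = 2,
) -> SelectionTrace:
    """Backward elimination to the ``n_keep`` best-fit predictors.

    Phase 1 removes, one at a time, the predictor with the largest VIF
    above ``vif_threshold``.  Phase 2 removes the predictor with the
    largest robust probability until ``n_keep`` remain.  Supplying
    ``n_keep`` or fewer candidates returns them unchanged with an empty
    trace.
    """
    if len(X) < 10:
        raise InputError(f"need at least 10 observations for selection (got {len(X)})")
    current = X.copy()
    steps: list[SelectionStep] = []
    if current.shape[1] <= n_keep:
        return SelectionTrace(steps=[], selected=sorted(current.columns), final=fit_ols(current, y))

    # phase 1: collinearity.  VIF comes from the auxiliary regressions, so a
    # rank-deficient design (e.g. a duplicated column, VIF = inf) is still
    # resolvable here even though a full OLS fit would be singular.
    while current.shape[1] > n_keep:
        vif = compute_vif(current)
        worst = vif.idxmax()
        if not (vif[worst] > vif_threshold):
            break
        aic_before = _safe_aic(current, y)
        nxt = current.drop(columns=[worst])
        steps.append(
            SelectionStep(worst, "VIF", float(vif[worst]), aic_before, _safe_aic(nxt, y))
        )
        current = nxt
    # phase 2: significance
    result = fit_ols(current, y)
    while current.shape[1] > n_keep:
        pvals = result.robust_p.drop(labels=["const"])
        worst = pvals.idxmax()
        nxt = current.drop(columns=[worst])
        nxt_res = fit_ols(nxt, y)
        steps.append(
            SelectionStep(worst, "robust-p", float(pvals[worst]), result.aic, nxt_res.aic)
        )
        current, result = nxt, nxt_res
    return SelectionTrace(steps=steps, selected=sorted(current.columns), final=result)


def _safe_aic(X: pd.DataFrame, y: np.ndarray) -> float:
    try:
        return fit_ols(X, y).aic
    except SingularityError:
        return float("nan")


def _collinear_columns(Xc: pd.DataFrame) -> list[str]:
    """Columns involved in exact linear dependence (via QR pivoting)."""
    A = Xc.to_numpy(dtype=float)
    _, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    return [c for c, d in zip(Xc.columns, diag) if d < tol]
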