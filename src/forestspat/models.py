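"""Maximum-likelihood spatial regression models: SEM, SLX and SDEM.

All three share the linear trend in the standardized log predictors; they
differ in how space enters:

* SLX  adds neighbour-averaged predictors WX with coefficients theta
  (estimated by OLS on the augmented design — the lag terms are ordinary
  regressors);
* SEM  keeps the trend but lets the disturbance follow a spatial
  autoregression u = lambda W u + eps;
* SDEM combines both and nests SEM (theta = 0), SLX (lambda = 0) and OLS
  (both zero).

SEM/SDEM estimation maximizes the concentrated log-likelihood

    l(lambda) = -(n/2)(ln 2 pi + 1) - (n/2) ln sigma2(lambda)
                + ln |I - lambda W|

where beta(lambda) and sigma2(lambda) come from least squares on the
spatially filtered data (I - lambda W) y, (I - lambda W) X.  Because W is
row-standardized from a symmetric adjacency it is similar to a symmetric
matrix, so its eigenvalues are real, the admissible interval is
(1/omega_min, 1), and the log-determinant is a stable sum of
ln(1 - lambda omega_i).  Disconnected blocks (pooled pantropical samples)
need no special casing: eigenvalues and the spatial filter are
block-diagonal-safe.

Impacts in SLX/SDEM: direct = beta_v (own unit), indirect = theta_v
(neighbours), total = beta_v + theta_v with
Var(total) = Var(beta) + Var(theta) + 2 Cov(beta, theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.sparse.linalg import splu

from .regression import OLSFit, global_measures, ols_fit
from .weights import SpatialWeights

#: dense eigenvalue log-determinants up to this size; sparse LU above
DENSE_LOGDET_MAX_N = 2000

LAMBDA_MARGIN = 1e-6


class ConvergenceError(RuntimeError):
    pass


def log_det(weights: SpatialWeights, lam: float,
            method: str | None = None) -> float:
    """ln |I - lambda W| for the row-standardized W.

    ``method`` is "eigen" (sum of ln(1 - lambda omega_i) over the real
    spectrum), "lu" (sparse LU of I - lambda W), or None to pick eigen
    for n <= 2000 and LU above.
    """
    lo, hi = weights.lambda_bounds()
    if not lo < lam < hi:
        raise ValueError(f"lambda {lam} outside admissible ({lo:.6f}, 1)")
    if method is None:
        method = "eigen" if weights.n <= DENSE_LOGDET_MAX_N else "lu"
    if method == "eigen":
        vals = 1.0 - lam * weights.eigenvalues()
        if np.any(vals <= 0.0):
            raise ValueError(f"I - {lam} W is singular")
        return float(np.log(vals).sum())
    if method == "lu":
        n = weights.n
        a = (sp.identity(n, format="csc") - lam * weights.W.tocsc())
        lu = splu(a)
        diag = lu.U.diagonal()
        if np.any(diag == 0.0):
            raise ValueError(f"I - {lam} W is singular")
        return float(np.log(np.abs(diag)).sum())
    raise ValueError(f"unknown log-determinant method {method!r}")


@dataclass
class SpatialFit:
    """A fitted SEM, SLX or SDEM model."""

    kind: str
    variables: list[str]
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame = field(repr=False)
    lam: float | None
    lam_se: float | None
    loglik: float
    nobs: int
    resid: np.ndarray = field(repr=False)  # innovation residuals eps-hat
    u: np.ndarray = field(repr=False)      # spatial residuals y - trend
    trend: np.ndarray = field(repr=False)
    impacts: pd.DataFrame = field(default=None, repr=False)
    measures: dict = field(default_factory=dict)

    @property
    def k_model(self) -> int:
        return len(self.params) + (0 if self.lam is None else 1)

    @property
    def lam_z(self) -> float | None:
        if self.lam is None or not self.lam_se:
            return None
        return self.lam / self.lam_se

    @property
    def lam_p(self) -> float | None:
        z = self.lam_z
        return None if z is None else float(2.0 * stats.norm.sf(abs(z)))

    def coefficient_table(self) -> pd.DataFrame:
        table = pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues,
        })
        if self.lam is not None:
            table.loc["lambda"] = [self.lam, self.lam_se, self.lam_z, self.lam_p]
        return table


def _impact_table(variables, params, cov) -> pd.DataFrame:
    """Direct/indirect/total impact decomposition with delta-method SEs."""
    columns = ["direct", "se_direct", "indirect", "se_indirect",
               "total", "se_total", "z_direct", "p_direct", "z_indirect",
               "p_indirect", "z_total", "p_total"]
    if not variables:
        return pd.DataFrame(columns=columns)
    rows = []
    for v in variables:
        lag = f"lag.{v}"
        direct = params[v]
        d_se = np.sqrt(cov.loc[v, v])
        if lag in params.index:
            indirect = params[lag]
            i_se = np.sqrt(cov.loc[lag, lag])
            total = direct + indirect
            t_var = cov.loc[v, v] + cov.loc[lag, lag] + 2.0 * cov.loc[v, lag]
            t_se = np.sqrt(t_var)
        else:
            indirect, i_se = 0.0, np.nan
            total, t_se = direct, d_se
        row = {"variable": v,
               "direct": direct, "se_direct": d_se,
               "indirect": indirect, "se_indirect": i_se,
               "total": total, "se_total": t_se}
        for name, se in (("direct", d_se), ("indirect", i_se), ("total", t_se)):
            z = row[name] / se if se and np.isfinite(se) and se > 0 else np.nan
            row[f"z_{name}"] = z
            row[f"p_{name}"] = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _augment_with_lags(X: pd.DataFrame, weights: SpatialWeights) -> pd.DataFrame:
    w = weights.W
    lagged = pd.DataFrame(
        w @ X.to_numpy(), index=X.index,
        columns=[f"lag.{c}" for c in X.columns],
    )
    return pd.concat([X, lagged], axis=1)


def slx_fit(X: pd.DataFrame, weights: SpatialWeights, y: np.ndarray) -> SpatialFit:
    """Spatially lagged X model: OLS of y on [1, X, WX]."""
    if weights.n != len(X):
        raise ValueError("weights do not match the design length")
    aug = _augment_with_lags(X, weights)
    base = ols_fit(aug, y)
    cov = pd.DataFrame(
        np.asarray(sm_cov(base)), index=base.params.index, columns=base.params.index
    )
    fit = SpatialFit(
        kind="SLX",
        variables=list(X.columns),
        params=base.params, bse=base.bse,
        zvalues=base.zvalues, pvalues=base.pvalues,
        cov_params=cov,
        lam=None, lam_se=None,
        loglik=base.loglik, nobs=base.nobs,
        resid=base.resid, u=base.resid, trend=base.fitted,
        impacts=_impact_table(list(X.columns), base.params, cov),
    )
    fit.measures = global_measures(fit.loglik, fit.resid, np.asarray(y, float),
                                   len(fit.params), trend=fit.trend)
    return fit


def sm_cov(fit: OLSFit) -> np.ndarray:
    """OLS coefficient covariance (classical, sigma2 (X'X)^-1)."""
    X = fit.design.to_numpy()
    n, k = X.shape
    sigma2 = float(fit.resid @ fit.resid) / (n - k)
    return sigma2 * np.linalg.inv(X.T @ X)


def _spatial_error_ml(design: pd.DataFrame, y: np.ndarray,
                      weights: SpatialWeights) -> dict:
    """Concentrated-likelihood ML for a model with SAR(1) errors."""
    Xd = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    W = weights.W.tocsr()
    Wy = W @ y
    WX = W @ Xd
    lo, hi = weights.lambda_bounds()
    lo_b, hi_b = lo + LAMBDA_MARGIN, hi - LAMBDA_MARGIN
    const = -0.5 * n * (np.log(2.0 * np.pi) + 1.0)

    def profile(lam: float) -> float:
        Ay = y - lam * Wy
        AX = Xd - lam * WX
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        e = Ay - AX @ beta
        sigma2 = float(e @ e) / n
        return const - 0.5 * n * np.log(sigma2) + log_det(weights, lam)

    res = optimize.minimize_scalar(
        lambda lam: -profile(lam), bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    if not res.success:
        raise ConvergenceError(f"lambda optimizer failed: {res.message}")
    if lam - lo_b < 1e-5 * (hi_b - lo_b) or hi_b - lam < 1e-5 * (hi_b - lo_b):
        raise ConvergenceError(
            f"lambda estimate {lam:.6f} sits on the admissible boundary"
        )

    Ay = y - lam * Wy
    AX = Xd - lam * WX
    beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
    e = Ay - AX @ beta
    sigma2 = float(e @ e) / n
    loglik = profile(lam)

    cov_beta = sigma2 * np.linalg.inv(AX.T @ AX)

    # SE of lambda from the curvature of the profile likelihood, whose
    # inverse negative Hessian is the correct asymptotic variance for the
    # profiled parameter
    h = min(1e-4, 0.5 * (hi_b - lam), 0.5 * (lam - lo_b))
    d2 = (profile(lam + h) - 2.0 * loglik + profile(lam - h)) / h**2
    lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan

    trend = Xd @ beta
    return {
        "lam": lam, "lam_se": lam_se, "beta": beta, "cov_beta": cov_beta,
        "sigma2": sigma2, "loglik": float(loglik), "resid": e,
        "u": y - trend, "trend": trend, "n": n,
    }


def _make_error_fit(kind: str, variables: list[str], design: pd.DataFrame,
                    y: np.ndarray, weights: SpatialWeights) -> SpatialFit:
    ml = _spatial_error_ml(design, y, weights)
    names = list(design.columns)
    params = pd.Series(ml["beta"], index=names)
    cov = pd.DataFrame(ml["cov_beta"], index=names, columns=names)
    bse = pd.Series(np.sqrt(np.diag(ml["cov_beta"])), index=names)
    z = params / bse
    fit = SpatialFit(
        kind=kind,
        variables=variables,
        params=params, bse=bse, zvalues=z,
        pvalues=pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names),
        cov_params=cov,
        lam=ml["lam"], lam_se=ml["lam_se"],
        loglik=ml["loglik"], nobs=ml["n"],
        resid=ml["resid"], u=ml["u"], trend=ml["trend"],
        impacts=_impact_table(variables, params, cov),
    )
    fit.measures = global_measures(
        fit.loglik, fit.resid, np.asarray(y, float), fit.k_model,
        trend=fit.trend,
    )
    return fit


def sem_fit(X: pd.DataFrame, weights: SpatialWeights, y: np.ndarray) -> SpatialFit:
    """Spatial error model: trend in X, SAR(1) disturbance."""
    if weights.n != len(X):
        raise ValueError("weights do not match the design length")
    design = _with_const(X)
    return _make_error_fit("SEM", list(X.columns), design, y, weights)


def sdem_fit(X: pd.DataFrame, weights: SpatialWeights, y: np.ndarray) -> SpatialFit:
    """Spatial Durbin error model: trend in [X, WX], SAR(1) disturbance."""
    if weights.n != len(X):
        raise ValueError("weights do not match the design length")
    design = _with_const(_augment_with_lags(X, weights))
    return _make_error_fit("SDEM", list(X.columns), design, y, weights)


def _with_const(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    out.insert(0, "const", 1.0)
    return out


def full_loglik(fit: SpatialFit, weights: SpatialWeights | None = None) -> float:
    """Direct evaluation of the Gaussian likelihood at the fitted parameters.

    For SEM/SDEM this re-evaluates
    -(n/2) ln(2 pi sigma2) - e'e/(2 sigma2) + ln|I - lambda W| from the
    stored innovations; for SLX the same without the spatial terms.  Used
    as an independent consistency check on the concentrated-likelihood
    path.
    """
    e = fit.resid
    n = len(e)
    sigma2 = float(e @ e) / n
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - float(e @ e) / (2.0 * sigma2)
    if fit.lam is not None:
        if weights is None:
            raise ValueError("weights needed to evaluate the spatial likelihood")
        ll += log_det(weights, fit.lam)
    return float(ll)
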