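"""Spatial-dependence diagnostics on OLS residuals.

Two families justify (or not) moving from OLS to a spatial model:

* Moran's I of the residuals, I = (n/S0) e'We / e'e, tested with the
  normal approximation whose null moments account for the hat matrix
  (Cliff-Ord regression-residual moments), one-sided against positive
  autocorrelation;
* the Lagrange-multiplier score tests for an omitted spatial error or
  spatial lag, with the robust variants that correct each statistic for
  the presence of the other alternative.  All four are chi-square(1).

The emitted table keeps the labels of the diagnostic report this package
mirrors: columns "SEM"/"R-SEM" are LM-error and robust LM-error, columns
"SLX"/"R-SLX" the classical LM-lag and robust LM-lag statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import OLSFit
from .weights import SpatialWeights


@dataclass
class DiagnosticsResult:
    I: float
    E_I: float
    Var_I: float
    SD: float
    p_moran: float
    LM_err: float
    p_LM_err: float
    LM_lag: float
    p_LM_lag: float
    RLM_err: float | None
    p_RLM_err: float | None
    RLM_lag: float | None
    p_RLM_lag: float | None
    n: int

    def moran_row(self) -> dict:
        return {"N": self.n, "I": self.I, "Exp": self.E_I,
                "Var": self.Var_I, "SD": self.SD, "p": self.p_moran}

    def lm_row(self) -> dict:
        return {
            "SEM": self.LM_err, "p_SEM": self.p_LM_err,
            "R-SEM": self.RLM_err, "p_R-SEM": self.p_RLM_err,
            "SLX": self.LM_lag, "p_SLX": self.p_LM_lag,
            "R-SLX": self.RLM_lag, "p_R-SLX": self.p_RLM_lag,
        }


def _checked_dense_w(ols: OLSFit, weights: SpatialWeights) -> np.ndarray:
    n = len(ols.resid)
    if weights.n != n:
        raise ValueError(
            f"weights order ({weights.n}) does not match residuals ({n})"
        )
    return weights.W.toarray()


def moran_residual_test(
    ols: OLSFit, weights: SpatialWeights
) -> tuple[float, float, float, float, float]:
    """Residual Moran's I with normal-approximation moments.

    With M = I - X(X'X)^-1 X' and the row-standardized W:

      E[I]   = (n / ((n-k) S0)) tr(MW)
      Var[I] = (n/S0)^2 [tr(MWMW') + tr((MW)^2) + (tr MW)^2]
               / ((n-k)(n-k+2))  -  E[I]^2

    Returns (I, E_I, Var_I, SD, one-sided upper-tail p).
    """
    w = _checked_dense_w(ols, weights)
    e = ols.resid
    X = ols.design.to_numpy()
    n, k = X.shape
    s0 = w.sum()
    I = float(n / s0 * (e @ (w @ e)) / (e @ e))

    XtX_inv = np.linalg.inv(X.T @ X)
    M = np.eye(n) - X @ XtX_inv @ X.T
    MW = M @ w
    tr_mw = np.trace(MW)
    tr_mwmwt = np.trace(MW @ (M @ w.T))
    tr_mw2 = np.trace(MW @ MW)

    E_I = n * tr_mw / ((n - k) * s0)
    Var_I = ((n / s0) ** 2 * (tr_mwmwt + tr_mw2 + tr_mw**2)
             / ((n - k) * (n - k + 2.0))) - E_I**2
    SD = (I - E_I) / np.sqrt(Var_I)
    p = float(stats.norm.sf(SD))
    return I, float(E_I), float(Var_I), float(SD), p


def lm_tests(
    ols: OLSFit, weights: SpatialWeights, y: np.ndarray | None = None
) -> dict:
    """Anselin LM diagnostics for spatial error and spatial lag.

    With sigma2 = e'e/n, T = tr((W' + W)W) and
    J = (WXb)'M(WXb)/sigma2 + T:

      LM_err  = (e'We / sigma2)^2 / T
      LM_lag  = (e'Wy / sigma2)^2 / J
      RLM_lag = (d_lag - d_err)^2 / (J - T)
      RLM_err = (d_err - (T/J) d_lag)^2 / (T - T^2/J)

    Robust forms need J > T; otherwise they are reported as None with a
    warning (a degenerate design where the lag alternative carries no
    information beyond the error one).
    """
    w = _checked_dense_w(ols, weights)
    e = ols.resid
    X = ols.design.to_numpy()
    n, k = X.shape
    if y is None:
        y = ols.y
    y = np.asarray(y, dtype=float)

    sigma2 = float(e @ e) / n
    T = float(np.sum((w.T + w) * w.T))  # tr((W'+W)W)
    d_err = float(e @ (w @ e)) / sigma2
    d_lag = float(e @ (w @ y)) / sigma2

    xb = X @ np.asarray(ols.params)
    wxb = w @ xb
    XtX_inv = np.linalg.inv(X.T @ X)
    m_wxb = wxb - X @ (XtX_inv @ (X.T @ wxb))
    J = float(wxb @ m_wxb) / sigma2 + T

    lm_err = d_err**2 / T
    lm_lag = d_lag**2 / J
    chi2_sf = stats.chi2(1).sf
    out = {
        "LM_err": lm_err, "p_LM_err": float(chi2_sf(lm_err)),
        "LM_lag": lm_lag, "p_LM_lag": float(chi2_sf(lm_lag)),
    }
    if J > T:
        rlm_lag = (d_lag - d_err) ** 2 / (J - T)
        rlm_err = (d_err - (T / J) * d_lag) ** 2 / (T - T**2 / J)
        out.update({
            "RLM_err": rlm_err, "p_RLM_err": float(chi2_sf(rlm_err)),
            "RLM_lag": rlm_lag, "p_RLM_lag": float(chi2_sf(rlm_lag)),
        })
    else:
        warnings.warn("J <= T: robust LM statistics are undefined here")
        out.update({"RLM_err": None, "p_RLM_err": None,
                    "RLM_lag": None, "p_RLM_lag": None})
    return out


def run_diagnostics(ols: OLSFit, weights: SpatialWeights) -> DiagnosticsResult:
    I, E_I, Var_I, SD, p = moran_residual_test(ols, weights)
    lm = lm_tests(ols, weights)
    return DiagnosticsResult(
        I=I, E_I=E_I, Var_I=Var_I, SD=SD, p_moran=p, n=len(ols.resid), **lm
    )


SIGNIFICANCE_CODES = (
    (1e-3, "***"), (1e-2, "**"), (5e-2, "*"), (1e-1, "."),
)


def significance_code(p: float | None,
                      codes=SIGNIFICANCE_CODES) -> str:
    """Star code for a p-value following the diagnostic-table legend."""
    if p is None or np.isnan(p):
        return ""
    for cutoff, code in codes:
        if p < cutoff:
            return code
    return "n.s."
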