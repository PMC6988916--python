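"""Local model specification by nested likelihood-ratio restriction.

Starting from the most general local model, the SDEM, three restrictions
are tested: theta = 0 (SDEM -> SEM), lambda = 0 (SDEM -> SLX) and both
(SDEM -> OLS).  Each LHR = 2 (logLik_SDEM - logLik_restricted) is
compared to chi-square with as many degrees of freedom as restricted
parameters.  The decision at level alpha:

* OLS restriction not rejected          -> OLS;
* only theta = 0 not rejected           -> SEM;
* only lambda = 0 not rejected          -> SLX;
* both restrictions rejected            -> SDEM;
* both individually not rejected while OLS is rejected (a corner the
  ladder can produce) -> the restriction with the larger p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import sdem_fit, sem_fit, slx_fit
from .regression import ols_fit
from .weights import SpatialWeights

LOGLIK_SLACK = 1e-6

MODEL_LABELS = ("OLS", "SEM", "SLX", "SDEM")


def lr_test(loglik_full: float, loglik_restricted: float, df: int
            ) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-square(df) p-value."""
    lhr = 2.0 * (loglik_full - loglik_restricted)
    if lhr < -LOGLIK_SLACK:
        raise ValueError(
            f"negative likelihood ratio {lhr:.3g}: the restricted model "
            "outscores the full one, which signals optimizer failure"
        )
    lhr = max(lhr, 0.0)
    if df == 0:  # identical models (e.g. no lag terms to restrict)
        return lhr, 1.0
    return lhr, float(stats.chi2(df).sf(lhr))


@dataclass
class SpecificationResult:
    """The three restriction tests and the resulting model choice."""

    lhr_sem: float
    df_sem: int
    p_sem: float
    lhr_slx: float
    df_slx: int
    p_slx: float
    lhr_ols: float
    df_ols: int
    p_ols: float
    alpha: float
    selected: str

    def to_row(self) -> dict:
        return {
            "LHR_SEM": self.lhr_sem, "p_SEM": self.p_sem,
            "LHR_SLX": self.lhr_slx, "p_SLX": self.p_slx,
            "LHR_OLS": self.lhr_ols, "p_OLS": self.p_ols,
            "selected": self.selected,
        }


def select_model(p_sem: float, p_slx: float, p_ols: float,
                 alpha: float = 0.05) -> str:
    """Model label from the three restriction p-values.

    ``p_sem`` tests theta = 0, ``p_slx`` tests lambda = 0, ``p_ols``
    tests both at once.
    """
    sem_rejected = p_sem < alpha
    slx_rejected = p_slx < alpha
    ols_rejected = p_ols < alpha
    if not ols_rejected:
        return "OLS"
    if not sem_rejected and slx_rejected:
        return "SEM"
    if not slx_rejected and sem_rejected:
        return "SLX"
    if sem_rejected and slx_rejected:
        return "SDEM"
    # both individually acceptable yet OLS rejected: keep the restriction
    # the data opposes least
    return "SEM" if p_sem >= p_slx else "SLX"


def specify(
    X: pd.DataFrame,
    weights: SpatialWeights,
    y: np.ndarray,
    alpha: float = 0.05,
) -> tuple[dict, SpecificationResult]:
    """Fit the four-model family on one variable set and run the ladder.

    Returns ({"OLS": ..., "SEM": ..., "SLX": ..., "SDEM": ...}, result).
    Degrees of freedom: one lag coefficient per variable for the theta
    restrictions, plus one for lambda.
    """
    fits = {
        "OLS": ols_fit(X, y),
        "SLX": slx_fit(X, weights, y),
        "SEM": sem_fit(X, weights, y),
        "SDEM": sdem_fit(X, weights, y),
    }
    n_theta = X.shape[1]
    full = fits["SDEM"].loglik
    lhr_sem, p_sem = lr_test(full, fits["SEM"].loglik, n_theta)
    lhr_slx, p_slx = lr_test(full, fits["SLX"].loglik, 1)
    lhr_ols, p_ols = lr_test(full, fits["OLS"].loglik, n_theta + 1)
    result = SpecificationResult(
        lhr_sem=lhr_sem, df_sem=n_theta, p_sem=p_sem,
        lhr_slx=lhr_slx, df_slx=1, p_slx=p_slx,
        lhr_ols=lhr_ols, df_ols=n_theta + 1, p_ols=p_ols,
        alpha=alpha,
        selected=select_model(p_sem, p_slx, p_ols, alpha=alpha),
    )
    return fits, result
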