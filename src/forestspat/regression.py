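"""Non-spatial regression stage: screening, selection, OLS, global measures.

The workflow mirrors a conventional cross-sectional specification search:
simple regressions rank each predictor, a bivariate-correlation screen
(|r| >= 0.6 by default) drops the redundant member of each collinear
pair, and backwards stepwise elimination under BIC selects the final OLS
variable set.  Spatial models downstream reuse that selected set.

Model-size convention used everywhere: ``k_model`` counts estimated mean
and spatial parameters (intercept, betas, thetas, lambda); information
criteria add one for the profiled-out error variance, ``k_ic = k_model
+ 1``.  Only relative AIC/BIC differences matter for selection, so the
single convention is applied to all four model families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .variables import VARIABLES

COLLINEARITY_THRESHOLD = 0.6


def _canonical_rank(name: str) -> int:
    try:
        return VARIABLES.index(name)
    except ValueError:
        return len(VARIABLES)


def global_measures(
    loglik: float,
    resid: np.ndarray,
    y: np.ndarray,
    k_model: int,
    trend: np.ndarray | None = None,
) -> dict:
    """Shared goodness-of-fit panel for OLS and spatial fits.

    AIC = 2 k_ic - 2 logLik and BIC = k_ic ln n - 2 logLik with
    k_ic = k_model + 1; ML_unb = e'e / (n - k_model) is the unbiased
    error-variance estimate and SER its square root.  The adjusted R^2
    uses 1 - (1 - R^2)(n - 1)/(n - k_model); for spatial fits R^2 is the
    squared correlation of the deterministic trend with y.
    """
    resid = np.asarray(resid, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= k_model:
        raise ValueError(f"n={n} must exceed k_model={k_model}")
    k_ic = k_model + 1
    rss = float(resid @ resid)
    if trend is None:
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
    else:
        trend = np.asarray(trend, dtype=float)
        if np.std(trend) == 0.0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(trend, y)[0, 1]) ** 2
    ml_unb = rss / (n - k_model)
    return {
        "loglik": float(loglik),
        "aic": 2.0 * k_ic - 2.0 * loglik,
        "bic": k_ic * np.log(n) - 2.0 * loglik,
        "ml_unb": ml_unb,
        "ser": float(np.sqrt(ml_unb)),
        "r2": float(r2),
        "adj_r2": float(1.0 - (1.0 - r2) * (n - 1) / (n - k_model)),
        "n": n,
        "k_model": k_model,
    }


@dataclass
class OLSFit:
    """Fitted OLS model with the selected variable set."""

    variables: list[str]
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    resid: np.ndarray
    fitted: np.ndarray
    loglik: float
    nobs: int
    design: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    fvalue: float | None = None
    f_pvalue: float | None = None
    measures: dict = field(default_factory=dict)

    @property
    def k_model(self) -> int:
        return len(self.params)

    @property
    def bic(self) -> float:
        return self.measures["bic"]

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues,
        })


def ols_fit(X: pd.DataFrame, y: np.ndarray) -> OLSFit:
    """Least-squares fit of y on [1, X] with Gaussian MLE log-likelihood."""
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(pd.DataFrame(X), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    fit = OLSFit(
        variables=[c for c in design.columns if c != "const"],
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        loglik=float(res.llf),
        nobs=int(res.nobs),
        design=design,
        y=y,
        fvalue=float(res.fvalue) if design.shape[1] > 1 else None,
        f_pvalue=float(res.f_pvalue) if design.shape[1] > 1 else None,
    )
    fit.measures = global_measures(fit.loglik, fit.resid, y, fit.k_model)
    return fit


def simple_regressions(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """R^2 of y regressed on each single predictor (plus intercept)."""
    y = np.asarray(y, dtype=float)
    out = {}
    for col in X.columns:
        res = sm.OLS(y, sm.add_constant(X[[col]])).fit()
        out[col] = float(res.rsquared)
    return pd.Series(out, name="r2")


@dataclass
class ScreenReport:
    """Collinearity screen outcome: what was dropped and why."""

    correlations: pd.DataFrame
    retained: list[str]
    dropped: list[dict]
    simple_r2: pd.Series

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped": self.dropped,
            "simple_r2": self.simple_r2.to_dict(),
        }


def collinearity_screen(
    X: pd.DataFrame,
    y: np.ndarray,
    threshold: float = COLLINEARITY_THRESHOLD,
) -> ScreenReport:
    """Iteratively drop the weaker member of each highly correlated pair.

    At each pass the pair with the largest |r| at or above the threshold
    is resolved by dropping the variable with the smaller simple-regression
    R^2 against y (ties drop the variable later in the canonical order),
    until no violating pair remains.  The surviving set is therefore
    independent of the input column order.
    """
    if X.shape[1] < 1:
        raise ValueError("no predictors to screen")
    corr = X.corr()
    r2 = simple_regressions(X, y)
    retained = sorted(X.columns, key=_canonical_rank)
    dropped: list[dict] = []
    while True:
        worst = None
        for a_idx in range(len(retained)):
            for b_idx in range(a_idx + 1, len(retained)):
                a, b = retained[a_idx], retained[b_idx]
                r = abs(corr.loc[a, b])
                if r >= threshold and (worst is None or r > worst[0] + 1e-15):
                    worst = (r, a, b)
        if worst is None:
            break
        r, a, b = worst
        if not np.isclose(r2[a], r2[b]):
            loser = a if r2[a] < r2[b] else b
        else:
            loser = max(a, b, key=_canonical_rank)
        keeper = b if loser == a else a
        dropped.append({
            "variable": loser, "against": keeper, "abs_r": float(r),
            "r2_dropped": float(r2[loser]), "r2_kept": float(r2[keeper]),
        })
        retained.remove(loser)
    return ScreenReport(
        correlations=corr, retained=retained, dropped=dropped, simple_r2=r2
    )


def stepwise_bic(X: pd.DataFrame, y: np.ndarray) -> OLSFit:
    """Backwards greedy elimination with smallest-BIC stop rule.

    Starts from the full model and repeatedly removes the single variable
    whose removal lowers BIC the most; stops when every removal would
    raise BIC.  The intercept is always kept, so the floor is the
    intercept-only model.  BIC ties remove the variable later in the
    canonical order.
    """
    if X.shape[1] < 1:
        raise ValueError("stepwise selection needs at least one candidate")
    current = list(X.columns)
    fit = ols_fit(X[current], y)
    while current:
        candidates = []
        for var in current:
            reduced = [v for v in current if v != var]
            trial = ols_fit(X[reduced], y)
            # equal-BIC candidates resolve to the later canonical variable
            candidates.append((trial.bic, -_canonical_rank(var), var, trial))
        best_bic, _, best_var, best_fit = min(candidates)
        if best_bic < fit.bic - 1e-12:
            current.remove(best_var)
            fit = best_fit
        else:
            break
    return fit
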