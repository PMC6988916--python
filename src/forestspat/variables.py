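"""Response and explanatory variables for the forest-cover regressions.

From raw unit attributes this module builds:

* ``FC``   forest cover, FA / FA_pot, the fraction of a unit's potentially
  forested area actually carrying forest (the response, in (0, 1));
* ``A_TOT`` total area [ha];
* ``PVA``  share of potential vegetation on total surface, FA_pot / A_TOT;
* ``PP_FA`` population pressure, P_TOT / FA by default (persons per
  hectare of remaining forest; switchable to P_TOT / A_TOT);
* ``RD``   road density, R_TOT / A_TOT in km per km^2;
* ``FL``   flatness, FL_TOT / A_TOT (share of terrain below 16% slope);
* ``CSI``  crop suitability index (0-100), passed through;
* ``CY``   maximum cereal caloric yield [kcal/ha], passed through when
  available.

Because forest-transition theory motivates a sigmoid relation between
forest cover and its drivers, the response is linearized with the logit
FC* = ln(1/FC - 1) (note the sign: FC* falls as FC rises), the predictors
are log-transformed, and each predictor is standardized within its sample
to zero mean and unit (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import json

import numpy as np
import pandas as pd

from .geodata import SampleId, UnitRecord

#: canonical predictor order, also the tie-breaking order in selection
VARIABLES = ("A_TOT", "PVA", "PP_FA", "RD", "FL", "CSI", "CY")

#: variables whose zero or missing value excludes a unit
NIL_SCREENED = ("FC", "PVA", "CSI", "RD")

PPFA_MODES = ("per_forest_area", "per_total_area")


def compute_variables(
    units: Sequence[UnitRecord],
    ppfa_mode: str = "per_forest_area",
) -> pd.DataFrame:
    """Raw variable table (one row per unit, canonical column order).

    Units with FA_pot = 0 get FC = NaN and are left to the exclusion
    filter rather than raising.  RD converts A_TOT from hectares to km^2
    (1 km^2 = 100 ha).
    """
    if ppfa_mode not in PPFA_MODES:
        raise ValueError(f"ppfa_mode must be one of {PPFA_MODES}")
    rows = []
    for u in units:
        fc = u.FA / u.FA_pot if u.FA_pot > 0 else np.nan
        pva = u.FA_pot / u.A_TOT if u.A_TOT > 0 else np.nan
        if ppfa_mode == "per_forest_area":
            ppfa = u.P_TOT / u.FA if u.FA > 0 else np.nan
        else:
            ppfa = u.P_TOT / u.A_TOT if u.A_TOT > 0 else np.nan
        rd = u.R_TOT / (u.A_TOT / 100.0) if u.A_TOT > 0 else np.nan
        fl = u.FL_TOT / u.A_TOT if u.A_TOT > 0 else np.nan
        rows.append({
            "unit_id": u.unit_id, "FC": fc, "A_TOT": u.A_TOT, "PVA": pva,
            "PP_FA": ppfa, "RD": rd, "FL": fl, "CSI": u.CSI,
            "CY": np.nan if u.CY is None else u.CY,
        })
    df = pd.DataFrame(rows).set_index("unit_id")
    if df["CY"].isna().all():
        df = df.drop(columns=["CY"])
    return df


def compute_cereal_yield(
    maize_series: "pd.Series | dict | None",
    rice_series: "pd.Series | dict | None",
    kcal_factors: tuple[float, float],
    reference_year: int,
) -> float | None:
    """Maximum cereal caloric yield [kcal/ha] over the trailing decade.

    Per crop: arithmetic mean of the yields [t/ha] in the ten years ending
    at ``reference_year`` (inclusive), times the crop's caloric factor
    [kcal/t].  The larger of the two crops is returned, on the assumption
    that the more caloric crop is the one grown.  None when neither crop
    has data in the window.
    """
    window = range(reference_year - 9, reference_year + 1)
    candidates = []
    for series, factor in zip((maize_series, rice_series), kcal_factors):
        if series is None:
            continue
        s = pd.Series(series, dtype=float)
        s.index = s.index.astype(int)
        vals = s[s.index.isin(window)].dropna()
        if len(vals):
            candidates.append(float(vals.mean()) * float(factor))
    return max(candidates) if candidates else None


def exclusion_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop units that cannot enter the log/logit transforms.

    Removed: FC missing, nil (<= 0) or extreme (>= 1); PVA, CSI or RD
    missing or nil.  Zeros in other variables are left to model selection.
    Returns (kept table, per-unit exclusion report).
    """
    reasons: dict[str, list[str]] = {}

    def flag(idx, reason):
        for unit in table.index[idx]:
            reasons.setdefault(unit, []).append(reason)

    fc = table["FC"]
    flag(fc.isna(), "FC missing")
    flag(fc <= 0.0, "FC nil")
    flag(fc >= 1.0, "FC extreme")
    for var in ("PVA", "CSI", "RD"):
        col = table[var]
        flag(col.isna(), f"{var} missing")
        flag(col == 0.0, f"{var} nil")

    report = pd.DataFrame(
        [{"unit_id": u, "reason": "; ".join(r)} for u, r in reasons.items()],
        columns=["unit_id", "reason"],
    )
    kept = table.drop(index=list(reasons))
    if kept.empty:
        raise ValueError("exclusion filter removed every unit")
    return kept, report


def linearize_response(fc: np.ndarray) -> np.ndarray:
    """Logit linearization FC* = ln(1/FC - 1), defined on the open (0, 1)."""
    fc = np.asarray(fc, dtype=float)
    if np.any(~np.isfinite(fc)) or np.any(fc <= 0.0) or np.any(fc >= 1.0):
        raise ValueError("FC values must lie strictly inside (0, 1)")
    return np.log(1.0 / fc - 1.0)


def invert_response(fc_star: np.ndarray) -> np.ndarray:
    """Inverse of :func:`linearize_response`: FC = 1 / (1 + exp(FC*))."""
    return 1.0 / (1.0 + np.exp(np.asarray(fc_star, dtype=float)))


@dataclass
class SampleFrame:
    """One sample's aligned response and predictor matrices.

    Row order is pinned at construction and shared with the weights
    matrix and every model fit downstream.
    """

    sample_id: SampleId
    units: list[str]
    FC: np.ndarray
    FC_star: np.ndarray
    X_raw: pd.DataFrame
    X_log: pd.DataFrame
    X_std: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def variables(self) -> list[str]:
        return list(self.X_std.columns)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        resp = pd.DataFrame(
            {"unit_id": self.units, "FC": self.FC, "FC_star": self.FC_star}
        )
        resp.to_csv(outdir / "response.csv", index=False)
        self.X_raw.to_csv(outdir / "X_raw.csv")
        self.X_log.to_csv(outdir / "X_log.csv")
        self.X_std.to_csv(outdir / "X_std.csv")
        manifest = {
            "sample": str(self.sample_id),
            "n": self.n,
            "variables": self.variables,
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def transform_and_standardize(
    table: pd.DataFrame, sample_id: SampleId
) -> SampleFrame:
    """Log-transform and z-standardize the predictors; linearize FC.

    Standardization is within-sample (pantropical samples standardize over
    the pooled units) with the n-1 standard-deviation denominator.  A CY
    column with any missing value is dropped for the sample, since only
    some samples carry cereal-yield data.  Constant columns raise.
    """
    table = table.copy()
    if "CY" in table.columns and table["CY"].isna().any():
        table = table.drop(columns=["CY"])
    predictors = [c for c in table.columns if c != "FC"]
    X_raw = table[predictors]
    if (X_raw <= 0.0).any().any():
        bad = [c for c in predictors if (X_raw[c] <= 0.0).any()]
        raise ValueError(f"non-positive values in {bad}; run exclusion_filter first"
                         if set(bad) & set(NIL_SCREENED)
                         else f"non-positive values block the log transform: {bad}")
    X_log = np.log(X_raw)
    mu = X_log.mean()
    sigma = X_log.std(ddof=1)
    zero_var = sigma.index[(sigma == 0.0) | sigma.isna()].tolist()
    if zero_var:
        raise ValueError(f"zero-variance predictors: {zero_var}")
    X_std = (X_log - mu) / sigma
    fc = table["FC"].to_numpy(dtype=float)
    return SampleFrame(
        sample_id=sample_id,
        units=list(table.index.astype(str)),
        FC=fc,
        FC_star=linearize_response(fc),
        X_raw=X_raw,
        X_log=X_log,
        X_std=X_std,
        mu=mu,
        sigma=sigma,
    )


def build_sample_frame(
    units: Sequence[UnitRecord],
    sample_id: SampleId,
    ppfa_mode: str = "per_forest_area",
) -> tuple[SampleFrame, pd.DataFrame]:
    """Convenience chain: compute, filter, transform.  Returns (frame, report)."""
    raw = compute_variables(units, ppfa_mode=ppfa_mode)
    kept, report = exclusion_filter(raw)
    return transform_and_standardize(kept, sample_id), report
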