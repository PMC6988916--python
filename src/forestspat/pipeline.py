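"""End-to-end orchestration of the per-sample analysis.

Stage order for every (country-scope, level) sample: variable
construction and exclusion -> log/standardize -> collinearity screen on
the log variables -> backwards-BIC OLS selection -> SOI weights on the
kept units' centroids -> Moran and LM diagnostics -> four-model fits and
the LR specification ladder -> impact and global-measure tables for the
selected model.  Pantropical samples pool the three countries' units,
standardize over the pool, and use geodesic centroid distances (their
SOI graph may split into per-country blocks, which the estimation
tolerates).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .diagnostics import DiagnosticsResult, run_diagnostics, significance_code
from .geodata import (COUNTRIES, SampleId, UnitRecord, project_and_measure,
                      read_units)
from .regression import (COLLINEARITY_THRESHOLD, OLSFit, ScreenReport,
                         collinearity_screen, stepwise_bic)
from .specify import SpecificationResult, specify
from .variables import SampleFrame, build_sample_frame
from .weights import SpatialWeights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full twelve-sample run."""

    samples: dict = field(default_factory=dict)  # "ZAM:macro" -> paths
    ppfa_mode: str = "per_forest_area"
    kcal_factors: dict = field(default_factory=dict)
    collinearity_threshold: float = COLLINEARITY_THRESHOLD
    alpha: float = 0.05
    crs_overrides: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.collinearity_threshold < 1.0:
            raise ValueError("collinearity threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        for sample, entry in cfg.samples.items():
            SampleId.parse(sample)
            for key in ("boundaries", "attributes"):
                if key in entry and not Path(entry[key]).exists():
                    raise FileNotFoundError(
                        f"{sample}: configured {key} path missing: {entry[key]}"
                    )
        return cfg


@dataclass
class SampleResult:
    """Everything one sample's run produces."""

    sample_id: SampleId
    frame: SampleFrame
    exclusions: pd.DataFrame
    screen: ScreenReport
    ols: OLSFit
    weights: SpatialWeights
    diagnostics: DiagnosticsResult
    fits: dict
    specification: SpecificationResult

    @property
    def selected_fit(self):
        return self.fits[self.specification.selected]

    def summary_row(self) -> dict:
        fit = self.selected_fit
        row = {
            "sample": str(self.sample_id),
            "n": self.frame.n,
            "selected": self.specification.selected,
            "lambda": getattr(fit, "lam", None),
            "adj_r2": fit.measures["adj_r2"],
            "ser": fit.measures["ser"],
            "loglik": fit.measures["loglik"],
        }
        impacts = getattr(fit, "impacts", None)
        if impacts is not None:
            for var, imp in impacts["total"].items():
                row[f"total.{var}"] = imp
        else:
            for var in self.ols.variables:
                row[f"total.{var}"] = self.ols.params[var]
        return row

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.to_dir(outdir / "sample")
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        with open(outdir / "screen.json", "w") as fh:
            json.dump(self.screen.to_dict(), fh, indent=2)
        self.ols.coefficient_table().to_csv(outdir / "ols_coefficients.csv")
        self.weights.to_gal(outdir / "weights.gal")
        with open(outdir / "weights_summary.json", "w") as fh:
            json.dump(self.weights.summaries, fh, indent=2)
        diag = {**self.diagnostics.moran_row(), **self.diagnostics.lm_row()}
        pd.DataFrame([diag]).to_csv(outdir / "diagnostics.csv", index=False)
        spec_row = self.specification.to_row()
        for key in ("p_SEM", "p_SLX", "p_OLS"):
            spec_row[key.replace("p_", "code_")] = significance_code(spec_row[key])
        pd.DataFrame([spec_row]).to_csv(outdir / "specification.csv", index=False)
        fit = self.selected_fit
        fit.coefficient_table().to_csv(outdir / "selected_coefficients.csv")
        impacts = getattr(fit, "impacts", None)
        if impacts is not None:
            impacts.to_csv(outdir / "impacts.csv")
        with open(outdir / "measures.json", "w") as fh:
            json.dump({m: f.measures for m, f in self.fits.items()}, fh, indent=2)


def analyze_units(
    units: Sequence[UnitRecord],
    sample_id: SampleId,
    ppfa_mode: str = "per_forest_area",
    collinearity_threshold: float = COLLINEARITY_THRESHOLD,
    alpha: float = 0.05,
) -> SampleResult:
    """Run the full chain on an in-memory unit list."""
    frame, exclusions = build_sample_frame(units, sample_id, ppfa_mode=ppfa_mode)
    if len(exclusions):
        logger.info("%s: excluded %d units", sample_id, len(exclusions))

    pooled = sample_id.country_scope == "PAN"
    coord = {}
    for u in units:
        coord[u.unit_id] = u.lonlat if pooled else u.centroid
    missing = [uid for uid in frame.units if coord.get(uid) is None]
    if missing:
        raise ValueError(f"units without centroids: {missing[:5]}")
    points = np.array([coord[uid] for uid in frame.units])
    weights = SpatialWeights.from_points(
        frame.units, points, metric="geodesic" if pooled else "planar"
    )

    y = frame.FC_star
    screen = collinearity_screen(frame.X_log, y,
                                 threshold=collinearity_threshold)
    for item in screen.dropped:
        logger.info("%s: screened out %s (|r|=%.2f with %s)",
                    sample_id, item["variable"], item["abs_r"], item["against"])
    ols = stepwise_bic(frame.X_std[screen.retained], y)
    logger.info("%s: stepwise kept %s", sample_id, ols.variables)

    diagnostics = run_diagnostics(ols, weights)
    fits, specification = specify(
        frame.X_std[ols.variables] if ols.variables
        else frame.X_std[[]],
        weights, y, alpha=alpha,
    )
    logger.info("%s: selected %s", sample_id, specification.selected)
    return SampleResult(
        sample_id=sample_id, frame=frame, exclusions=exclusions,
        screen=screen, ols=ols, weights=weights,
        diagnostics=diagnostics, fits=fits, specification=specification,
    )


def load_sample_units(config: RunConfig, sample_id: SampleId
                      ) -> list[UnitRecord]:
    """Load (and project) the units of one configured sample.

    Pantropical scopes pool the three per-country entries of the same
    level.
    """
    if sample_id.country_scope == "PAN":
        units: list[UnitRecord] = []
        for country in COUNTRIES:
            units.extend(load_sample_units(
                config, SampleId(country, sample_id.level)))
        return units
    key = str(sample_id)
    if key not in config.samples:
        raise KeyError(f"sample {key} not configured")
    entry = config.samples[key]
    units, rejects = read_units(
        entry["boundaries"], entry["attributes"],
        join_key=entry.get("join_key", "unit_id"),
        country=sample_id.country_scope, level=sample_id.level,
        layer=entry.get("layer"),
    )
    if len(rejects):
        logger.warning("%s: %d unmatched records", key, len(rejects))
    return project_and_measure(
        units, crs_spec=config.crs_overrides.get(sample_id.country_scope))


def run_sample(config: RunConfig, sample_id: SampleId) -> SampleResult:
    units = load_sample_units(config, sample_id)
    result = analyze_units(
        units, sample_id,
        ppfa_mode=config.ppfa_mode,
        collinearity_threshold=config.collinearity_threshold,
        alpha=config.alpha,
    )
    if config.outdir:
        result.to_dir(Path(config.outdir) / str(sample_id).replace(":", "_"))
    return result


def run_all(config: RunConfig, samples: Sequence[SampleId] | None = None
            ) -> tuple[pd.DataFrame, dict]:
    """Run every configured (or requested) sample; failures are recorded
    per sample and do not stop the rest.  Returns (summary table,
    {sample: SampleResult or error record})."""
    if samples is None:
        scopes = {SampleId.parse(k) for k in config.samples}
        levels = {s.level for s in scopes}
        samples = list(scopes) + [
            SampleId("PAN", level) for level in sorted(levels)
            if all(SampleId(c, level) in scopes for c in COUNTRIES)
        ]
        samples = sorted(samples, key=str)
    if not samples:
        raise ValueError("no samples configured")
    results: dict = {}
    rows = []
    for sid in samples:
        try:
            res = run_sample(config, sid)
            results[str(sid)] = res
            rows.append(res.summary_row())
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            logger.error("%s failed: %s", sid, exc)
            results[str(sid)] = {"error": f"{type(exc).__name__}: {exc}"}
            rows.append({"sample": str(sid), "n": None, "selected": "ERROR"})
    summary = pd.DataFrame(rows)
    if config.outdir:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(config.outdir) / "summary.csv", index=False)
    return summary, results
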