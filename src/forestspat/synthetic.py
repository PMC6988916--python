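"""Synthetic nested jurisdictional samples with known spatial structure.

The generator emulates the statistical structure the regression pipeline
assumes, not real geographies: unit centroids scattered (or gridded) over
a square region, log-normal covariates with a configurable correlation
matrix, and a forest-cover response built by inverting the logit
linearization of a spatial Durbin error process,

    FC* = beta0 + X^ beta + W X^ theta + u,   u = (I - lambda W)^-1 eps,
    FC  = 1 / (1 + exp(FC*)),

with W the SOI graph of the generated centroids and X^ the within-sample
standardized log covariates — exactly the quantities the variable builder
reconstructs.  Raw attributes (FA, FA_pot, A_TOT, ...) are back-solved
from the drawn covariates so that running the real pipeline on the
generated units reproduces X^ and FC* to machine precision.

Randomness is consumed in a fixed order (centroids, then covariates,
then errors) so a seed pins the sample across versions.  Default scales
are chosen to resemble tropical micro-level administrative units: total
areas around 2 x 10^4 ha, potential-vegetation shares around 0.55,
population pressures around 1.5 persons per forest hectare, road
densities around 0.3 km/km^2, and a mild positive correlation between
population pressure and road density (the two move together in the data
this emulates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon

from . import crs
from .geodata import UnitRecord, write_units, write_units_geojson
from .variables import invert_response
from .weights import SpatialWeights

DEFAULT_LOG_MEAN = {
    "A_TOT": np.log(20_000.0),  # ha
    "PVA": np.log(0.55),
    "PP_FA": np.log(1.5),       # persons / forest ha
    "RD": np.log(0.3),          # km / km^2
    "FL": np.log(0.5),
    "CSI": np.log(35.0),
    "CY": np.log(6.0e6),        # kcal/ha
}
DEFAULT_LOG_SD = {
    "A_TOT": 0.8, "PVA": 0.25, "PP_FA": 1.0, "RD": 0.7,
    "FL": 0.3, "CSI": 0.4, "CY": 0.3,
}
#: shares and bounded indices cannot exceed their physical ceiling
VARIABLE_CAPS = {"PVA": 0.999, "FL": 1.0, "CSI": 100.0}

DEFAULT_BETA = {"A_TOT": 0.0, "PVA": 0.2, "PP_FA": 1.8,
                "RD": -0.1, "FL": 0.0, "CSI": 0.15}
DEFAULT_THETA = {"A_TOT": 0.0, "PVA": 0.0, "PP_FA": -0.1,
                 "RD": 0.0, "FL": 0.0, "CSI": 0.2}


@dataclass
class SyntheticScenario:
    """Ground-truth description of one generated sample."""

    seed: int
    n_units: int = 400
    layout: str = "uniform_random"  # or "grid"
    extent_m: float = 500_000.0
    country: str = "ZAM"
    level: str = "micro"
    variables: tuple = ("A_TOT", "PVA", "PP_FA", "RD", "FL", "CSI")
    log_mean: dict = field(default_factory=lambda: dict(DEFAULT_LOG_MEAN))
    log_sd: dict = field(default_factory=lambda: dict(DEFAULT_LOG_SD))
    corr: pd.DataFrame | None = None
    beta0: float = 1.2
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    lam: float = 0.6
    sigma_eps: float = 0.5
    ppfa_mode: str = "per_forest_area"

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.variables)
        if self.corr is None:
            corr = pd.DataFrame(np.eye(p), index=self.variables,
                                columns=self.variables)
            if "PP_FA" in self.variables and "RD" in self.variables:
                corr.loc["PP_FA", "RD"] = corr.loc["RD", "PP_FA"] = 0.3
        else:
            corr = self.corr.loc[list(self.variables), list(self.variables)]
        mat = corr.to_numpy(dtype=float)
        if not np.allclose(mat, mat.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(mat).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        return mat

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get(v, 0.0) for v in self.variables])

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta.get(v, 0.0) for v in self.variables])


def _draw_centroids(rng: np.random.Generator, scenario: SyntheticScenario
                    ) -> np.ndarray:
    n = scenario.n_units
    if n < 2:
        raise ValueError("need at least two units")
    if scenario.layout == "uniform_random":
        return rng.uniform(0.0, scenario.extent_m, size=(n, 2))
    if scenario.layout == "grid":
        side = int(np.ceil(np.sqrt(n)))
        spacing = scenario.extent_m / side
        ij = np.arange(side)
        xx, yy = np.meshgrid(ij, ij, indexing="xy")
        pts = (np.column_stack([xx.ravel(), yy.ravel()]) + 0.5) * spacing
        return pts[:n]
    raise ValueError(f"unknown layout {scenario.layout!r}")


def _draw_covariates(rng: np.random.Generator, scenario: SyntheticScenario
                     ) -> pd.DataFrame:
    variables = list(scenario.variables)
    mean = np.array([scenario.log_mean[v] for v in variables])
    sd = np.array([scenario.log_sd[v] for v in variables])
    corr = scenario.correlation_matrix()
    cov = corr * np.outer(sd, sd)
    z = rng.multivariate_normal(mean, cov, size=scenario.n_units,
                                method="cholesky")
    raw = pd.DataFrame(np.exp(z), columns=variables)
    for var, cap in VARIABLE_CAPS.items():
        if var in raw.columns:
            raw[var] = raw[var].clip(upper=cap)
    return raw


def _standardize_logs(raw: pd.DataFrame) -> pd.DataFrame:
    logs = np.log(raw)
    return (logs - logs.mean()) / logs.std(ddof=1)


def _spatial_response(rng: np.random.Generator, scenario: SyntheticScenario,
                      weights: SpatialWeights, x_std: pd.DataFrame
                      ) -> np.ndarray:
    lo, hi = weights.lambda_bounds()
    if not lo + 1e-9 < scenario.lam < hi - 1e-9:
        raise ValueError(
            f"lambda {scenario.lam} outside the admissible ({lo:.4f}, 1)"
        )
    n = scenario.n_units
    W = weights.W.tocsc()
    eps = rng.normal(0.0, scenario.sigma_eps, size=n)
    u = spsolve(sp.identity(n, format="csc") - scenario.lam * W, eps)
    xb = x_std.to_numpy() @ scenario.beta_vector()
    wxt = W @ (x_std.to_numpy() @ scenario.theta_vector())
    return scenario.beta0 + xb + wxt + u


def _backsolve_units(scenario: SyntheticScenario, raw: pd.DataFrame,
                     fc: np.ndarray, centroids: np.ndarray,
                     ids: list[str] | None = None) -> list[UnitRecord]:
    units = []
    zone = crs.zone_for_country(scenario.country)
    lon, lat = crs.utm_to_geographic(centroids[:, 0], centroids[:, 1], zone)
    for i in range(len(raw)):
        a_tot = float(raw["A_TOT"].iloc[i])
        fa_pot = float(raw["PVA"].iloc[i]) * a_tot
        fa = float(fc[i]) * fa_pot
        if scenario.ppfa_mode == "per_forest_area":
            p_tot = float(raw["PP_FA"].iloc[i]) * fa
        else:
            p_tot = float(raw["PP_FA"].iloc[i]) * a_tot
        unit = UnitRecord(
            unit_id=ids[i] if ids else f"{scenario.country}-{scenario.level}-{i:05d}",
            country=scenario.country,
            level=scenario.level,
            A_TOT=a_tot,
            FA=fa,
            FA_pot=fa_pot,
            P_TOT=p_tot,
            R_TOT=float(raw["RD"].iloc[i]) * a_tot / 100.0,
            FL_TOT=float(raw["FL"].iloc[i]) * a_tot,
            CSI=float(raw["CSI"].iloc[i]),
            CY=float(raw["CY"].iloc[i]) if "CY" in raw.columns else None,
            centroid=(float(centroids[i, 0]), float(centroids[i, 1])),
            lonlat=(float(lon[i]), float(lat[i])),
        )
        unit.validate()
        units.append(unit)
    return units


def generate_sample(scenario: SyntheticScenario
                    ) -> tuple[list[UnitRecord], dict]:
    """Draw one sample; returns (units, ground-truth record).

    The truth record carries the generator parameters plus the realized
    weights, standardized design and response, for parameter-recovery and
    reconstruction tests.
    """
    rng = np.random.default_rng(scenario.seed)
    centroids = _draw_centroids(rng, scenario)
    weights = SpatialWeights.from_points(
        [f"{scenario.country}-{scenario.level}-{i:05d}"
         for i in range(scenario.n_units)],
        centroids,
    )
    raw = _draw_covariates(rng, scenario)
    x_std = _standardize_logs(raw)
    fc_star = _spatial_response(rng, scenario, weights, x_std)
    fc = invert_response(fc_star)
    units = _backsolve_units(scenario, raw, fc, centroids, ids=weights.ids)
    truth = {
        "scenario": scenario,
        "beta0": scenario.beta0,
        "beta": pd.Series(scenario.beta_vector(), index=scenario.variables),
        "theta": pd.Series(scenario.theta_vector(), index=scenario.variables),
        "lam": scenario.lam,
        "sigma_eps": scenario.sigma_eps,
        "weights": weights,
        "X_std": x_std,
        "FC_star": fc_star,
        "FC": fc,
        "centroids": centroids,
    }
    return units, truth


# ---------------------------------------------------------------------------
# nested multi-level samples

@dataclass
class NestedSample:
    """Micro units plus their aggregated meso and macro parents."""

    units: dict  # level -> list[UnitRecord]
    parents: dict  # level -> {child unit_id: parent unit_id}
    truth: dict


def _aggregate(children: list[UnitRecord], groups: dict[str, list[int]],
               country: str, level: str) -> list[UnitRecord]:
    out = []
    for parent_id, idxs in groups.items():
        sub = [children[i] for i in idxs]
        a_tot = sum(u.A_TOT for u in sub)
        cx = sum(u.centroid[0] * u.A_TOT for u in sub) / a_tot
        cy_ = sum(u.centroid[1] * u.A_TOT for u in sub) / a_tot
        lon = sum(u.lonlat[0] * u.A_TOT for u in sub) / a_tot
        lat = sum(u.lonlat[1] * u.A_TOT for u in sub) / a_tot
        has_cy = all(u.CY is not None for u in sub)
        out.append(UnitRecord(
            unit_id=parent_id, country=country, level=level,
            A_TOT=a_tot,
            FA=sum(u.FA for u in sub),
            FA_pot=sum(u.FA_pot for u in sub),
            P_TOT=sum(u.P_TOT for u in sub),
            R_TOT=sum(u.R_TOT for u in sub),
            FL_TOT=sum(u.FL_TOT for u in sub),
            CSI=sum(u.CSI * u.A_TOT for u in sub) / a_tot,
            CY=max(u.CY for u in sub) if has_cy else None,
            centroid=(cx, cy_), lonlat=(lon, lat),
        ))
    return out


def nested_scenario(template: SyntheticScenario,
                    branching: tuple[int, int, int] = (4, 5, 10),
                    ) -> NestedSample:
    """Three nested levels: micro units drawn inside meso cells inside
    macro cells, parents aggregating their children's extensive
    attributes exactly (areas, population, road length are sums; CSI is
    the area-weighted mean; CY the maximum where present).

    ``branching`` is (number of macro blocks, meso blocks per macro,
    micro units per meso).  Micro centroids are uniform within their meso
    cell; the response is generated once, at the micro level, by the same
    process as :func:`generate_sample`.
    """
    n_macro, meso_per_macro, micro_per_meso = branching
    if min(meso_per_macro, micro_per_meso) < 2 or n_macro < 2:
        raise ValueError("branching factors must be at least 2")
    n_micro = n_macro * meso_per_macro * micro_per_meso
    scenario = replace(template, n_units=n_micro, level="micro")

    rng = np.random.default_rng(scenario.seed)
    # macro blocks on a coarse grid; meso cells on a sub-grid of each block
    g_macro = int(np.ceil(np.sqrt(n_macro)))
    macro_side = scenario.extent_m / g_macro
    g_meso = int(np.ceil(np.sqrt(meso_per_macro)))
    meso_side = macro_side / g_meso

    centroids = np.empty((n_micro, 2))
    micro_parent: dict[str, str] = {}
    meso_parent: dict[str, str] = {}
    meso_groups: dict[str, list[int]] = {}
    macro_groups: dict[str, list[int]] = {}
    idx = 0
    for m in range(n_macro):
        mx, my = m % g_macro, m // g_macro
        macro_id = f"{scenario.country}-macro-{m:02d}"
        macro_groups[macro_id] = []
        for s in range(meso_per_macro):
            sx, sy = s % g_meso, s // g_meso
            meso_id = f"{scenario.country}-meso-{m:02d}-{s:02d}"
            meso_parent[meso_id] = macro_id
            meso_groups[meso_id] = []
            x0 = mx * macro_side + sx * meso_side
            y0 = my * macro_side + sy * meso_side
            pts = rng.uniform(0.0, meso_side, size=(micro_per_meso, 2))
            for k in range(micro_per_meso):
                centroids[idx] = (x0 + pts[k, 0], y0 + pts[k, 1])
                micro_id = f"{scenario.country}-micro-{idx:05d}"
                micro_parent[micro_id] = meso_id
                meso_groups[meso_id].append(idx)
                macro_groups[macro_id].append(idx)
                idx += 1

    weights = SpatialWeights.from_points(
        [f"{scenario.country}-micro-{i:05d}" for i in range(n_micro)],
        centroids,
    )
    raw = _draw_covariates(rng, scenario)
    x_std = _standardize_logs(raw)
    fc_star = _spatial_response(rng, scenario, weights, x_std)
    fc = invert_response(fc_star)
    micro_units = _backsolve_units(scenario, raw, fc, centroids,
                                   ids=weights.ids)
    meso_units = _aggregate(micro_units, meso_groups, scenario.country, "meso")
    macro_units = _aggregate(micro_units, macro_groups, scenario.country, "macro")
    truth = {
        "scenario": scenario, "weights": weights, "X_std": x_std,
        "FC_star": fc_star, "FC": fc,
        "beta": pd.Series(scenario.beta_vector(), index=scenario.variables),
        "theta": pd.Series(scenario.theta_vector(), index=scenario.variables),
        "lam": scenario.lam, "sigma_eps": scenario.sigma_eps,
    }
    return NestedSample(
        units={"micro": micro_units, "meso": meso_units, "macro": macro_units},
        parents={"micro": micro_parent, "meso": meso_parent},
        truth=truth,
    )


def write_sample(units: list[UnitRecord], outdir: str | Path,
                 square_side_m: float = 1000.0) -> None:
    """Write a generated sample in the layouts the readers consume.

    Emits ``units.csv`` (attribute table) and ``boundaries.geojson``
    (square placeholder polygons of the given side centred on each
    centroid, in geographic coordinates), so the file-based pipeline can
    be exercised end to end without real boundaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_units(units, outdir / "units.csv")
    with_geoms = []
    for u in units:
        zone = crs.zone_for_country(u.country)
        x, y = u.centroid
        h = square_side_m / 2.0
        xs = np.array([x - h, x + h, x + h, x - h, x - h])
        ys = np.array([y - h, y - h, y + h, y + h, y - h])
        lon, lat = crs.utm_to_geographic(xs, ys, zone)
        u2 = replace(u, geometry=Polygon(zip(lon, lat)))
        with_geoms.append(u2)
    write_units_geojson(with_geoms, outdir / "boundaries.geojson")
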