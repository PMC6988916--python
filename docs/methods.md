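# Methods note

This note records the statistical model, the conventions and numerical
choices made in `forestspat`, what the synthetic generator does and does not
emulate, and the package's known limitations.

## 1. Model and assumptions

For a sample of `n` jurisdictional units the response is the linearised
forest-cover fraction `FC* = ln(1/FC − 1)` with `FC = FA / FA_pot`, defined
only for `0 < FC < 1`. Predictors are natural-log transformed and
z-standardised within the sample (denominator `n − 1`); units with
`FC ≤ 0`, `FC ≥ 1`, or nil `PVA`, `CSI` or `RD` are excluded before the
transform, with per-unit reasons reported. Zeros in other predictors do not
exclude a unit but block the log transform with a named error, so the
condition is surfaced rather than silently patched.

The general estimating equation is the spatial Durbin error model

```
y = β0·1 + X β + W X θ + u,    u = λ W u + ε,    ε ~ N(0, σ² I)
```

with nested restrictions SLX (λ = 0), SEM (θ = 0) and OLS (both). `W` is the
row-standardised sphere-of-influence (SOI) graph: units `i` and `j` are
neighbours iff `|r_i − r_j| < d(i,j) < r_i + r_j` strictly, where `r_i` is
the distance from `i` to its nearest neighbour. Tangency is excluded; the
SOI graph always contains the nearest-neighbour graph, and coincident
centroids are an error (the offending indices are named). Assumptions:
homoskedastic Gaussian innovations, exogenous regressors, a fixed known
neighbour graph, and `λ` inside the admissible interval `(1/ω_min, 1)` where
`ω_min` is the smallest eigenvalue of `W`.

Weights-graph summaries count links as ordered pairs (`n_links`, average
links `n_links / n`) and report `pct_nonzero = 100 · n_links / n²`.

## 2. Estimation

* **OLS / SLX.** Least squares on `[1, X]` and `[1, X, WX]` respectively;
  lag columns are labelled `lag.<var>`. Coefficient covariance is
  `σ̂² (X'X)⁻¹` with the `n − k` denominator.
* **SEM / SDEM.** Concentrated maximum likelihood. For fixed `λ`, β̂(λ) is
  the least-squares fit of the spatially filtered data
  `(I − λW) y` on `(I − λW) X_design`, and the concentrated log-likelihood is
  `ℓ(λ) = −(n/2)(ln 2π + 1) − (n/2) ln σ̂²(λ) + ln|I − λW|`. A bounded
  scalar optimiser searches the admissible interval shrunk by a margin of
  1e-6 at both ends with `xatol = 1e-8`; a maximiser within 1e-5 of the
  interval boundary (relative to its width) raises a convergence error
  rather than returning a boundary estimate.
* **log-determinant.** Because `W` is a row-standardised symmetric
  adjacency, `ln|I − λW| = Σ ln(1 − λ ω_i)` with real eigenvalues obtained
  from the similar symmetric matrix `D^{-1/2} A D^{-1/2}`. Dense
  eigendecomposition is used up to `n = 2000` (the spectrum is cached on the
  weights object, so repeated fits are cheap); above that a sparse LU
  factorisation of `I − λW` is used per evaluation.
* **Standard errors.** `SE(β) = σ̂² (AX' AX)⁻¹` at `λ = λ̂` with
  `A = I − λ̂W`; `SE(λ)` from the curvature of the profile likelihood by
  central finite differences with step `h ≤ 1e-4`.
* **Impacts.** In SLX/SDEM the direct impact of a variable is its `β`, the
  indirect impact its `θ`, total = β + θ with
  `Var(total) = Var(β) + Var(θ) + 2 Cov(β, θ)` from the coefficient
  covariance.

### Fit measures and the parameter-count convention

`k_model` counts mean and spatial parameters (intercept + β + θ + λ);
`k_ic = k_model + 1` additionally counts the profiled σ². Then
`AIC = 2 k_ic − 2ℓ`, `BIC = k_ic ln n − 2ℓ`, the standard error of
regression is `SER = sqrt(e'e / (n − k_model))`, and the spatial pseudo-R² is
the squared correlation between the trend `Xβ̂ (+ WXθ̂)` and `y`, with the
adjusted version `1 − (1 − R²)(n − 1)/(n − k)`. Fit measures refuse samples
with `n ≤ k_model` rather than emit infinite or undefined values.

## 3. Diagnostics and specification

* **Residual Moran's I** on OLS residuals with Cliff–Ord moments under the
  regression null (using `M = I − X(X'X)⁻¹X'`), reported as the standard
  deviate `SD = (I − E[I]) / sqrt(Var[I])` with a one-sided upper p-value.
* **Lagrange-multiplier tests** (error, lag, and their robust forms) from
  the OLS fit. When `J ≤ T` the robust statistics are undefined; they are
  reported as missing with a warning instead of a negative statistic.
* **Model specification** by nested likelihood-ratio tests against the SDEM:
  `LHR = 2(ℓ_full − ℓ_restricted) ~ χ²(df)` with `df` = number of lag terms
  (SEM restriction), 1 (SLX restriction, the single λ), or lag terms + 1
  (OLS). A numerical-slack of 1e-6 absorbs tiny negative differences;
  larger negative differences are an error (they indicate a failed
  optimisation). `df = 0` (no lag terms in the model) yields `p = 1.0` by
  convention. The decision rule at `α = 0.05`: if both single restrictions
  reject, choose SDEM; if exactly one rejects, choose the unrestricted side
  of that test (SEM or SLX); if neither rejects, choose OLS unless the joint
  OLS restriction still rejects, in which case the corner is resolved toward
  the single-restriction model with the *larger* p-value (weaker evidence
  against it).

### Variable screening

Before the spatial stage, OLS variables pass two screens, both operating on
a fixed canonical variable order (`A_TOT, PVA, PP_FA, RD, FL, CSI, CY`):

* **Collinearity**: iteratively resolve the pair with the largest
  `|r| ≥ 0.6` (computed on the log scale) by dropping the member with the
  lower simple-regression R² against the response; exact ties drop the
  later-canonical variable, making the screen order-invariant.
* **Backwards stepwise by BIC**: greedily remove the variable whose removal
  lowers BIC the most, while the improvement exceeds 1e-12; equal-BIC
  candidates are resolved by removing the later-canonical variable.

The spatial models are then fit on the stepwise-selected set.

## 4. Geometry

An in-package transverse Mercator (6th-order Krüger series in
`n = f/(2 − f)`, WGS84, `k0 = 0.9996`) handles projection and its inverse
(Newton iteration on the conformal latitude); it was verified against a
numerically integrated meridian arc to sub-millimetre accuracy. Country
defaults: Zambia UTM 35S, Ecuador 17S, Philippines 51N. Areas are reported
in hectares. Pooled multi-country samples have no common UTM zone, so their
centroids stay geographic and inter-centroid distances are great-circle
(haversine, mean Earth radius 6 371 008.8 m); within-country samples use
planar UTM distances.

## 5. Synthetic generator: scope

`SyntheticScenario` draws unit centroids (uniform or grid layout over a
square extent, default 500 km), log-normal covariates from a multivariate
normal on the log scale (Cholesky draw; default means/SDs give realistic
magnitudes, with caps `PVA ≤ 0.999`, `FL ≤ 1.0`, `CSI ≤ 100`), and a
response from the SDEM process with chosen `β`, `θ`, `λ` and `σ_ε`, solving
`u = (I − λW)⁻¹ ε` exactly. Raw unit attributes are then back-solved so that
the variable builder reproduces the intended design matrix to machine
precision — the generator therefore tests the entire pipeline, not just the
estimators. `nested_scenario` builds a three-level hierarchy by aggregating
micro units (sums for extensive quantities, potential-area-weighted forest
cover, area-weighted CSI, area-weighted centroids).

The generator emulates the *statistical* structure of a multi-level
jurisdictional dataset: nested units, realistic covariate scales and
correlations, spatially autocorrelated errors and neighbour effects. It does
not emulate real administrative geometry (boundary polygons are written as
small placeholder squares around each centroid), measurement error in the
attribute sources, or within-country heterogeneity of the covariate process.

## 6. Problem sizes and defaults

These sizes are the package's own defaults, chosen to balance statistical
resolution against run time on a laptop:

* default synthetic sample: 400 units; test fixtures use 100–400;
* the reproduction script (`scripts/acceptance.py`) uses a nested design of
  16 macro × 4 meso × 8 micro units per country (1 536 pooled micro units
  across three countries). Sixteen macro units per country guarantees that
  the richest candidate model (SDEM with all six default predictors, 14
  mean/spatial parameters) remains estimable at every level regardless of
  which predictors survive screening;
* Monte-Carlo checks in the test suite: 1 000 replicates for the
  likelihood-ratio type-I error, 200 for λ recovery and confidence-interval
  coverage, 500–10 000 for the Moran/LM null behaviour;
* `PP_FA` defaults to population per forest area, switchable to population
  per total area; the cereal-yield proxy `CY` uses a 10-year trailing mean
  ending at the reference year, converted to kcal/ha with caloric factors
  supplied through the configuration (they are inputs, not constants), and
  takes the maximum over crops.

## 7. Limitations

* Estimation assumes homoskedastic Gaussian innovations; there are no
  heteroskedasticity-robust standard errors.
* `SE(λ)` comes from the profile-likelihood curvature, which ignores the
  β–λ information cross-terms; for small `n` it can understate uncertainty
  (coverage was verified by simulation at `n = 400` only).
* The SOI graph is built on centroids; elongated or interlocking polygons
  may produce neighbourhoods that differ from contiguity-based graphs.
* Geodesic distances for pooled samples treat the Earth as a sphere; the
  sub-0.5 % flattening error is irrelevant for neighbourhood topology but
  the choice is a documented convention, not the only defensible one.
* The dense-eigenvalue log-determinant path caps at `n = 2000`; beyond that
  the sparse-LU path is slower per likelihood evaluation and the profile
  search cost grows accordingly.
* Stepwise selection and the collinearity screen are greedy heuristics; they
  are deterministic and order-invariant but not guaranteed to find the
  globally BIC-optimal subset.
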