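# Methods

This note records the models, conventions and numerical choices behind
`canopy2cohorts`, and what the synthetic experiments do and do not show.

## Scope and data model

The package covers the initialization chain (point cloud → leaf-area-density
profile → functional-type attribution → cohort stack → scaled ensemble), the
understory flammability model, the drought/MCWD analysis machinery, and the
hierarchical-bootstrap evaluation. It does not contain a biosphere model:
the `pss`/`css` files it writes are initial conditions for one, and all fuel
and necromass pools are inputs, not simulated stocks.

Core containers: `CanopyProfile` (1-m height bins up to 80 m, leaf-area
density per bin), `CohortStack` (cohorts of DBH, height, PFT, stem density,
LAI share), `PlotProperties` (AGB kg m⁻², basal area cm² m⁻², stems ha⁻¹,
LAI), and `Ensemble` (equal-weight patches per region × disturbance class).

## Allometry

Height–diameter uses the saturating form `H = H_max·(1 − exp(−a·DBH^b))`,
strictly increasing and analytically invertible below `H_max`; leaf area per
individual is `l₀·DBH^q`; aboveground biomass is the Chave-form power law on
`ρ·DBH²·H`. The registry ships four functional types (early/mid/late
successional trees, C4 grass). **The shipped coefficients are plausible
tropical placeholders, not fitted values** — the `AllometrySet` YAML config
is the intended way to supply site-calibrated laws, and the synthetic truth
uses the same registry as the inversion, so tests exercise consistency, not
allometric accuracy. Wood area is ignored in the leaf-area accounting (a
known ~7–15% omission in optical LAI terms).

## Lidar simulator (what it emulates, what it does not)

Stands: stem positions uniform; DBH i.i.d. truncated power law on
[10, 120] cm (default tail exponent 2.6, spanning 2.2–3.2 in the pipeline's
training generator); PFT by mixture draw; crowns are vertically uniform
cylinders occupying the top 45% of tree height with radius 0.6 + 0.065·DBH m.
Defaults (520 stems ha⁻¹ ≥ 10 cm; LAI ≈ 3–7) sit in the range of Amazon
terra-firme inventories.

Pulses are stratified per 1 × 1 m cell (⌈density⌉ per cell, jittered), which
guarantees the 4 returns m⁻² minimum over ≥ 99.5% of cells by construction.
Each pulse runs top-down through the local LAD column; per bin it is
intercepted with probability `1 − exp(−k·LAD·Δz)` (k = 0.5, the spherical
leaf-angle value); intercepted bins become returns (up to 4 per pulse) and a
never-intercepted pulse becomes a ground return, so the expected
ground-return fraction equals the Beer–Lambert gap fraction exactly — the
property the Monte-Carlo test checks. Not represented: terrain (ground is
flat z = 0; profiles are height-normalized anyway), waveform physics, beam
divergence, partial interceptions, off-nadir geometry, occlusion between
pulses. Consequently the simulated clouds are *kinder* than real surveys:
passing the synthetic recovery tests demonstrates internal consistency of
the method, not field accuracy.

## Profiles

Pseudo-waveforms: returns below 0.5 m count as ground energy; the canopy
histogram is convolved with a truncated Gaussian (σ = 0.5 m, 3σ support);
mass smoothed below the lowest edge is folded into ground energy and above
the 80 m cap into the top bin, so energy is conserved to round-off.
MacArthur–Horn works top-down on cumulative energies; columns with no ground
energy are floored at transmittance 0.01, capping apparent optical depth at
ln(100) ≈ 4.6 — dense canopies therefore saturate, which is one reason the
global scaling factor exceeds 1/k. Half-open `[min, max)` gridding with
0-based indices; metrics (mean height, p10–p95, cover > 2 m, skewness,
kurtosis, ground fraction) use linear-interpolation quantiles and the
convention skewness = kurtosis = 0 for degenerate columns.

## Property regressions

`y = k·Πxⱼ^aⱼ·ε` fitted on the log scale with per-plot log-sd
`σ₀·μ^(c−1)`, so sd(y) ≈ σ₀·μ^c. For each predictor subset (exhaustive, size
≤ p, default p = 2 in the pipeline, 3 at the API) and each c on
{0, 0.25, …, 2}, coefficients come from iteratively reweighted least squares
(weights μ^(2(1−c)), ≤ 8 iterations, deterministic); BIC with
|subset| + 3 parameters selects the winner. Predictions apply the lognormal
mean correction `exp(s²/2)`. Constant or non-positive metrics are dropped
with a warning; collinear subsets are skipped by a rank check.

## Layer splitting and cohort construction

Retained maxima are strict local maxima (plateaus: leftmost bin) surviving a
prominence filter — peak LAD must exceed the higher flanking valley by ≥ 5%
of the profile maximum; weakest peaks merge first. Boundaries sit at the
minimum-LAD bin between retained maxima; the valley bin joins the upper
layer, so layers partition the occupied support and leaf area is conserved
exactly.

Two extensions matter in practice and are enabled in `PipelineConfig` while
the library functions keep the plain defaults:

* **Saddle-style subdivision** (`max_layer_depth`, pipeline default 5 m).
  A smooth unimodal profile otherwise collapses an entire canopy into one
  layer at one height, i.e. one cohort diameter for trees of every size. A
  cohort layer deeper than a single crown cannot represent one size class,
  so thicker layers are cut into equal slabs; a saddle-bounded slab has no
  meaningful peak, so its representative height is the LAD-weighted mean.
* **Crown-offset correction** (`crown_offset_fraction`, pipeline default
  0.2). The profile measures where *leaves* are; a crown's leaf-area
  centroid sits below the tree top by about half the relative crown depth.
  Cohort height is therefore `peak/(1 − 0.2)`. With offset 0 (the function
  default) the cohort height is exactly the layer peak height.

Grass receives layer mass only below 2 m (its share is redistributed to
trees above); a PFT whose height law saturates below a layer passes its
share to the tallest feasible type; a layer above every law is capped at the
tallest type's maximum invertible height. Cohort density is
`leaf area share / L_i(DBH)/area`, which makes Σ cohort LAI equal the scaled
profile LAI to machine precision — the conservation invariant tested
end-to-end.

## Scaling

The plot factor minimizes the equally weighted sum of squared relative
errors of the four properties (subset configurable) over s ∈ [0.05, 20].
Because layer geometry is invariant under uniform profile scaling, every
integrated property is linear in s and the objective is quadratic; the
implementation still re-derives cohorts per evaluation and solves by a
40-point log-spaced bracket plus bounded Brent (xatol = 10⁻⁴), which also
survives non-smooth edge cases (layers appearing/disappearing at thresholds
is possible with pathological profiles). When compared against
inventory-calibrated targets, AGB/BA/stem density integrate only census
cohorts (DBH ≥ 10 cm, `census_dbh_min`), while LAI keeps all foliage —
otherwise sub-census cohorts created from low-canopy leaf area inflate stem
density and bias the compromise factor low. The global factor is the median
(even count: mean of the central pair) of plot factors.

## Fire model

Strict inequalities at both thresholds: fire-prone requires depth-mean
θ < θ_crit, and seedling fuel requires height < 2 m exactly as stated.
Depth-averaging handles a partially covered bottom layer by linear
weighting and errors if the layers do not reach z_F. α_F < 100 always;
α_F → 100·λ_F·Δt as λ_F → 0. Fuel pools are in kgC m⁻²; cohort biomass
entering `fuel_from_cohorts` is taken as carbon with no hidden conversion
factor.

## Drought metrics

Deficit is PET − P (positive = deficit). MCWD uses the reset-to-zero
recursion within a trailing 12-month window (the field-standard accumulation
convention), switchable to a windowed sum of positive deficits
(`convention="window_sum"`). The first 11 months are NaN. Drought length
tests the raw monthly difference (surpluses are not clamped first) against
the 20 mm threshold; class boundaries are < 12 / 12–36 / > 36 months with
both boundary values mapped to "severe". Priestley–Taylor uses the FAO
saturation-slope formula, γ = 0.067 kPa °C⁻¹, λᵥ = 2.45 MJ kg⁻¹, floored at
zero. Quantile binning uses `pandas.qcut` with duplicate-edge dropping, so
heavily tied MCWD series may yield fewer than the requested bins. Curve fits
("shifted" = nonzero intercept y₀, an interpretation):
`y = y∞ − (y∞ − y₀)·e^(−(x/τ)^k)`, k ≡ 1 for the exponential; 5 multi-start
initializations from data quantiles with a fixed seed; BIC on the Gaussian
RSS form; acceptance requires adjusted R² > 0.5; non-convergence of both
families returns a rejected fit with diagnostics rather than raising.

## Cross-validation

Regions are drawn with replacement (R draws from R regions), plots are then
drawn with replacement from the pooled plots of the drawn regions (with
multiplicity) up to the original training count — pooled, not re-stratified,
sampling. Out-of-region prediction uses only replicates whose region draw
excluded the target, truncated to the common minimum count across regions;
an assertion proves the held-out set never intersects a calibration set.
Default DBH classes [10,20), [20,40), [40,60), [60,100), [100,∞) cm; groups
under 20 plots are excluded from reports. The desk-scale default is 200
replicates; the full 2,000 is a parameter away.

## Problem sizes and determinism

The shipped experiments use 0.25-ha stands at 4 pulses m⁻², training
libraries of 40–60 plots, 30-stand recovery runs, 100-seed regression
recovery, 10⁴ bootstrap replicates, and a Δs = 10⁻³ grid oracle over
s ∈ [0.05, 10] — sizes chosen so the whole suite and the acceptance script
each run in minutes on one core while keeping Monte-Carlo error well inside
the asserted tolerances. Every random draw flows from an explicit
`numpy.random.default_rng` seed; writers use fixed decimal formats so
seeded outputs are byte-stable.

## Known limitations

* Allometric coefficients are placeholders; real use requires calibrated
  laws supplied via config.
* The MacArthur–Horn transmittance floor compresses profiles of optically
  thick canopies; the global scaling factor absorbs the mean effect but
  dense stands remain biased low in recovered LAI/basal area (the ~30%
  worst-case errors in the recovery experiment are these stands).
* The lidar simulator omits terrain, occlusion and waveform physics; results
  on synthetic scenes bound method consistency, not field performance.
* Functional-type attribution inherits whatever structure–composition
  correlation exists in the training library; with the synthetic library's
  weak correlation it mainly tests the matching machinery.
* LAS/LAZ and NetCDF ingestion are not implemented; all I/O is through the
  documented plain-text dialects.
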