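# Methods

This note documents the models and procedures implemented in
`borealcarbon`, the choices made where several defensible options existed,
and what the synthetic-data tests do and do not demonstrate.

## Soil carbon accounting

Per-plot soil organic carbon (SOC) is the sum of an organic-layer pool and
a mineral-soil pool, both in Mg C ha⁻¹.

**Organic layer.** The pooled volumetric cores give the stock directly:
(C%/100) · dry mass / sampled area, converted from g cm⁻² by the factor
100. Profiles with organic thickness > 30 cm are treated as peat: the
measured 0–30 cm core density is extrapolated by *constant density* to the
full organic thickness, capped at 100 cm below the organic surface. The
constant-density rule is the simplest extrapolation consistent with having
no depth–density profile; the hook (`peat_extrapolated_stock`) is the place
to substitute a depth-decay function if core profiles become available.

**Mineral soil.** Each sampled layer contributes
(C%/100) · ρ_b · thickness · (100 − stone%)/100, with the pedotransfer bulk
density ρ_b = 1.5463·exp(−0.3130·√C) + 0.0027·z (g cm⁻³). The depth
argument z is the layer midpoint (5, 15, 60 cm) — a single representative
depth per layer, unbiased for a linear depth term. Stone volume comes from
the mean of 12 rod-penetration depths through the linear clamped transfer
v = clip(44.3 − 1.44·p̄, 0, 100) %; the constants follow published Swedish
penetration-rod calibrations and are configuration-exposed.

The accounted mineral column is 0–50 cm. The sampling scheme measures
0–10, 10–20 and 55–65 cm; the 55–65 cm density stands in for the unsampled
20–50 cm interval with weight 3 (three 10 cm layers). This is a declared
accounting decision, not a measurement: alternatives (linear density
interpolation, ignoring the deep sample) are reachable through the
`deep_layer_weight` parameter. Where a thick organic layer displaces
mineral soil, the accounted column is truncated to
min(50, max(0, 100 − organic thickness)) cm pro rata per layer, which makes
total SOC continuous in organic thickness across both the 30 cm peat
threshold and the 100 cm cap (property-tested).

## Tree carbon accounting

Stem biomass uses log-linear allometric component equations
ln(m_kg) = b₀ + b₁·ln(DBH_cm) + b₂·ln(h_m) summed over stump, stem, bark,
living/dead branches and foliage, plus a DBH-only belowground equation.
The shipped coefficient table is a **synthetic default** of that standard
national-equation form — the national coefficient tables are not
redistributed — tuned so stem magnitudes and the ≈24 % belowground share
are realistic for boreal pine/spruce/birch. Lodgepole pine maps to the pine
equations, other deciduous species to birch. Analyses that need the
national coefficients can load them via `AllometryTable.from_dict`.

Unmeasured heights are imputed from the Näslund curve
h = 1.3 + (d/(a + b·d))², fitted per species over all measured stems
(linearised as d/√(h−1.3) = a + b·d, so noiseless data recover (a, b)
exactly), then rescaled per plot by the ratio of measured to predicted
(h − 1.3) — a one-parameter, shrinkage-free stand-in for plot-level mixed
modelling that reproduces the structure (plot-specific curves) with
auditable arithmetic. Measured heights are never altered. Plot stocks
assume a 50 % C fraction of dry biomass (config-overridable) and scale by
10⁴/(π r²) to per-hectare; saplings (DBH ≤ 4 cm) are excluded from biomass.

## Wetness regression and retransformation

Stocks are regressed on a degree-1 or degree-2 polynomial in the mapped
wetness probability x ∈ [0, 1] (maps published on a 0–100 % scale are
divided by 100 at ingestion). Fits are computed in an orthonormal basis of
the observed design (QR factorisation) for numerical stability; both the
raw power-basis and orthonormal-basis coefficients are reported, and the
two give identical fitted values to 1e−10. Raw quadratic coefficients on a
skewed 0–1 design are strongly collinear — their standard errors, also
reported, make that visible.

Log-scale models are back-transformed with Duan's smearing estimator (mean
of exponentiated residuals; ≥ 1 for any OLS-with-intercept residual set).
Out-of-sample error uses leave-one-out cross-validation by literal refit,
with the smearing factor recomputed inside each fold so no information
leaks from the held-out point. Prediction refuses x outside [0, 1]:
extrapolation beyond the index's domain is meaningless. The linear-design
LOOCV used by the ALS model applies the exact hat-matrix identity
e_i/(1 − h_ii), which equals the refit loop for linear least squares.

## ALS area-based mapping

Cell metrics on normalized point heights: P95 (95th percentile, linear
interpolation between order statistics), HSD (standard deviation, n−1
denominator) and VR (fraction of returns above a canopy threshold, default
1.5 m — conventional area-based practice). Both definitional choices are
documented because percentile and SD conventions differ between tools.
Plots whose field Lorey height (basal-area-weighted mean height, weights
DBH²) differs from P95 by more than 5 m are excluded and logged with their
discrepancy; the filter is idempotent.

The tree-C model, tree C = c₀ + c₁(P95·VR)^1.2 − c₃·HSD, is linear in its
coefficients given the fixed exponent 1.2 (a config flag allows profiling
the exponent over a grid instead). Wall-to-wall prediction on 12.5 m metric
rasters propagates nodata and clamps negative predictions to zero with a
logged count — the model form does not forbid negatives; bare or
high-variance cells can produce them.

## Landscape summaries

Pool statistics (N/mean/SD/median/min/max/SE, SE = sd/√n) are reported for
three cases: including peat, excluding peat, only peat. Partition shares
divide case means by the grand total (mean soil + mean tree stock); the
peat share of soil C weights the peat-case mean by its plot count; the
excluding-peat mean follows the weighted-mean identity
n·mean = n_peat·mean_peat + n_rest·mean_rest. Shares are rounded to integer
percent for display, with full precision retained in machine-readable
output. The SOC map applies the fitted (smeared) model cellwise to the 2 m
wetness raster; out-of-range wetness cells become nodata and are counted.
An optional mask (tree-C floor, wetness ceiling) reproduces the common
practice of blanking clear-cuts and open peatland in display maps.

## The synthetic catchment generator

The generator defines the study conditions under which the pipeline is
tested; its defaults are fixed, not tuning knobs:

* 430 plots of 10 m radius on a 350 m grid; stand ages on 0–272 yr with the
  marginal mean adjusted to 79 yr by mixing a uniform with a younger gamma
  component (weight chosen once, in closed form, from those three numbers);
* field moisture classes in proportions 7/73/11/7/2 %, assigned by
  empirical wetness quantiles at the cumulative proportions;
* a wetness field built by Gaussian-smoothing an iid normal grid
  (correlation length 50 m, circular boundary), standardizing, and mapping
  through the Beta(1.0, 14) quantile transform — a monotone squashing to
  [0, 1] whose marginal concentrates below x ≈ 0.3, the range where the
  raw-basis log-quadratic stock curve yields physically sane stocks;
* total SOC generated on log(y) = 4.23 + 8.51x + 3.35x², residual sd 0.24
  (log scale); tree C on the quadratic 44 + 170x − 200x² (Mg C ha⁻¹,
  truncated at 0, unimodal with vertex at x = 0.425), residual sd 18;
* an 11 % marginal peat-plot fraction, achieved by anchoring the
  deterministic thickness curve's 30 cm crossing at the wetness marginal's
  89th percentile;
* ALS returns at 20 points m⁻² as a ground/canopy mixture whose canopy
  fraction is the stand's crown cover 1 − exp(−Σ crown area / plot area).

The central construction is **inversion through the pipeline itself**: the
organic core mass is set in closed form and the top mineral C concentration
is root-solved (Brent, xtol 1e−12) so that the *accounted* total SOC equals
the generating curve value — noise draw included — exactly; the organic
pool absorbs the mineral solver's residual, so the identity holds to
floating-point precision. Tree lists are calibrated the same way by
root-solving a single DBH scale factor through the allometric aggregation.
Consequently, with all residual sds at zero, refitting recovers the
generating coefficients to numerical precision, and with noise on, the
regression residuals are exactly the injected draws — which is what makes
the simulation-based coverage checks clean.

What the generator does **not** emulate: real pedogenic noise structure
(every sd is a free configuration parameter, not an estimate), terrain or
stream networks, species-composition realism beyond the three-label mix,
LiDAR waveform physics, survey-crew measurement idiosyncrasies, or the
empirical noise that produced the survey's real-data fit statistics.
Passing tests therefore demonstrate that the accounting, regression and
mapping machinery is correct and internally consistent — not that the
pipeline would reach any particular R² on field data. The survey's
real-data quantities (field-class pool means, the observed model R²/RMSE,
the majority-soil-share statistic) depend on undeposited data and are
covered only by qualitative pattern checks on generator output (R²
ordering of organic vs mineral models, interior-class peak of the tree
share).

## Numerical choices and problem sizes

* All randomness flows from one seed through named `SeedSequence`
  substreams per module and plot; any generated catchment is
  bit-reproducible from (config, seed).
* Rasters are ESRI ASCII grids written with `%.17g`, so write/read round
  trips are bit-exact for float64; origin is the upper-left corner,
  row-major, cell centres at origin + (i + 0.5)·cell; plot–raster joins use
  point-in-cell by plot centre. CRS is carried as an opaque label.
* Degenerate inputs: empty tree lists are valid plots (clear-cuts) with
  zero pools; empty ALS cells yield nodata metric records; an all-zero
  canopy term degrades the ALS model to intercept − c₃·HSD; missing mineral
  layers raise a flagged missing-data error rather than silently zeroing.
* Test and script problem sizes are chosen to exercise every path at
  comfortable statistical resolution: full-scale 430-plot surveys for the
  200-replicate coverage study (fit-only path, no rasters), 36–120-plot
  catchments with 60–80 m spacing for end-to-end runs, 80-plot designs ×
  50 replicates for the ALS noise study, and 5000 draws for generator
  marginals.

## Known limitations

* The default allometry is synthetic; absolute tree-C levels on real
  surveys require the national coefficient tables.
* The 20–50 cm mineral stand-in (weight 3 on the 55–65 cm sample) and the
  constant-density peat extrapolation are accounting conventions; both are
  single parameters away from alternatives, but no data-driven choice is
  made here.
* The printed-style raw-basis log-quadratic explodes for x near 1; fits are
  stable (orthonormal basis) but raw coefficients should be interpreted
  only over the observed wetness range.
* No spatial autocorrelation correction in the regressions and no
  uncertainty propagation into the wall-to-wall maps; prediction intervals
  would need either bootstrap-over-plots or a geostatistical treatment.
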