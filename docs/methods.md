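# Methods

`lakecarbon` computes annual lake carbon budgets — emission of CO₂ and CH₄
to the atmosphere and burial of organic carbon in sediment — and compares
the per-lake emission:burial balance across biomes. This note documents
the models, the parameters that matter, the synthetic-data generator, and
the numerical and design choices, in that order.

## 1. Gas physics

Dissolved gas concentrations follow Henry's law with a van 't Hoff
temperature dependence,

    K_h(T) = K_ref · exp(C · (1/T − 1/298.15)),    C = K·kelvin

with freshwater reference solubilities K_ref = 0.034 mol L⁻¹ atm⁻¹ (CO₂)
and 0.0014 mol L⁻¹ atm⁻¹ (CH₄) and van 't Hoff constants 2400 K and
1700 K. These are stored in `gas_constants.yaml` and can be swapped for
another parameterization without touching code. Schmidt numbers use the
standard freshwater cubic polynomials in temperature (°C); the CO₂
polynomial evaluates to ≈599.4 at 20 °C, which is what anchors the k600
convention. Carbonate speciation is deliberately out of scope: fluxes act
on free CO₂, and the lakes this package targets are dilute, soft-water
systems where ionization corrections are second-order for flux purposes.

Headspace equilibration inverts a two-compartment mass balance: the
original dissolved amount equals the post-equilibration dissolved amount
plus the gas transferred to the headspace above its initial content. The
initial headspace composition defaults to 400 ppm (ambient air) and is a
parameter.

## 2. Sensor correction and calibration

Raw infrared pCO₂ sensor output is density-compensated with the ideal-gas
relation, corrected = raw · (P_ref/P) · (T_K/T_ref,K) with P_ref =
1013.25 hPa and T_ref = 25 °C. The compensation is isolated in one
function so a manufacturer-specific curve can replace it. Standard-gas
calibrations (≥2 standards, OLS reading→truth) are fitted before and
after the field season; the per-timestamp gain and offset are linearly
interpolated between the two sessions by default (`pre_only` and `mean`
policies are selectable). A sensor with a linear gain drift distorted by
density effects is recovered exactly under this scheme (round-trip test:
relative error < 0.5 % noiseless).

## 3. Diffusive surface flux

Fick's law across the interface, F = k · (C_water − C_eq), with the
piston velocity from the Cole–Caraco wind relation

    k600 = 2.07 + 0.215 · U10^1.7   (cm h⁻¹)

rescaled to gas and temperature by k = k600 · (Sc/600)^(−n), n = 0.5 by
default (0.67 selectable for low-wind smooth surfaces). Anemometer wind
at 7.5 m is scaled to 10 m with a neutral logarithmic profile (roughness
length 0.0002 m, configurable; pass-through for pre-normalized wind).
The atmospheric pCO₂ baseline defaults to 390 μatm (circa 2010). Wind
and pCO₂ series are joined nearest-in-time within 30 min; timestamps
without wind are flagged and excluded, never silently filled.

## 4. Chamber CH₄ fluxes

Headspace mixing ratios convert to molar content via the ideal gas law.
The default estimator is the OLS slope of content over time; when the
final headspace exceeds the value in equilibrium with the water (the
signature of a bubble having driven the chamber past equilibrium, so the
end-of-deployment gradient reverses), the endpoint mass balance is used
instead — the two agree exactly on linear series. Ebullition is
partitioned at the lake-period level: diffusive = mean of shielded
chambers, ebullitive = max(0, mean(total) − diffusive), negative
differences floored at zero and flagged. Shielded and total chambers are
pooled per lake-period rather than paired one-to-one — with only two
shielded chambers per lake a pooled baseline is the only defensible
reading. The spatial mean is area-weighted over depth zones by default
(arithmetic pooling selectable).

## 5. Bathymetry

Soundings plus shoreline zero points are interpolated with neighborhood
inverse-distance weighting (power 2, 12 nearest neighbors) onto a grid
clipped to the convex hull of the points; the interpolator is pluggable
so a geostatistical method (kriging) can substitute. Neighborhood rather
than global IDW matters: global IDW pulls every cell toward the basin
mean and distorts the depth–area curve. The cell size is chosen so the
bounding box holds ≥4×10⁴ cells; analytic test basins (cylinder, cone)
are recovered within 5 % in volume at that resolution, typically ~2 %.
Hypsometry is tabulated in 0.5 m half-open strata by cell counting;
stratum volumes sum to the raster integral exactly. The winter
hypsometry removes a flat ice slab: strata above the ice are dropped and
the straddled stratum is pro-rated by depth fraction.

## 6. Under-ice storage and ice-out emission

Grab-sample profiles are mapped to strata by nearest sample depth
(linear interpolation optional), integrated to a whole-lake dissolved
amount (under-ice snapshots use the winter hypsometry, open-water
snapshots the full one), and the ice-out emission is the across-break-up
inventory drop per unit lake area, E = (N_ice − N_open) · 12.011 / A in
g C m⁻². Lakes with maximum depth ≤ 1.5 m are assumed to freeze solid
and get zero storage release. A negative difference (more gas after
ice-off) is reported as zero with a flag. CH₄ oxidation during the melt
window is ignored: the inventory difference is treated as emitted.

## 7. Seasonal integration and budgets

The ice-free season runs from first open water to full ice cover (the
bundled study dates, 2010-05-21 → 2010-10-22, give 154 days). The CO₂
flux series is integrated trapezoidally; gaps ≤6 h are bridged by the
trapezoid, longer gaps are filled at the observed-window mean with the
coverage fraction reported, and coverage below 50 % is an error. Chamber
period means integrate as a step function partitioned at the half-way
timestamps between deployment periods; the shoulders before the first
and after the last deployment take the nearest period's mean — the
June–August campaign must be extended to the full season somehow, and
nearest-value extension adds no trend assumption. Winter contributes
only through the ice-out term; no flux through ice is modeled. Annual
budgets are g C m⁻² yr⁻¹ with the ice-out release counted inside its
species' component, so total = CO₂ + CH₄.

## 8. ²¹⁰Pb dating and burial

Under constant ²¹⁰Pb flux and constant sedimentation the excess activity
declines exponentially with cumulative dry mass m:
A_ex(m) = A₀ · exp(−λ m / w), λ = ln 2 / 22.3 yr⁻¹. The mass
accumulation rate w (g cm⁻² yr⁻¹) comes from OLS of ln A_ex on m; its
standard error is propagated from the slope SE by the delta method.

Numerical choices that required judgement:

- **Supported level.** Estimated as the mean of the deepest slices that
  are statistically indistinguishable (deepest 3 as the base, extended
  upward while within 2 counting σ of the base mean); a profile with no
  flat tail raises and asks for a manual value. When a core does not
  fully reach the asymptote this overestimates the supported level
  slightly and biases w low by a few percent — the dedicated recovery
  tests therefore separate dating precision (excess given: machine
  precision noiseless, <2 % bias under 5–10 % counting noise, ~93–95 %
  CI coverage) from the full workflow (within ~10 %).
- **Fit range.** Starts at the excess maximum at or below 2.5 cm — the
  uppermost sediment is excluded so rates represent layers where
  decomposition is slow, and a property test documents that fitting a
  mixed-layer core from the surface biases w upward. Slices whose excess
  is within 3 counting σ of zero are excluded (never substituted): a
  weak excess is dominated by the supported subtraction and would
  distort the log fit.
- **Burial.** burial = w · mean C fraction · 10⁴ in g C m⁻² yr⁻¹, with
  the C fraction averaged over the dated range by default (whole-core
  selectable). Multi-core lakes average per-core burial arithmetically.
- **Focusing.** The whole-core excess inventory is compared with a
  2.2 kBq m⁻² atmospheric-supply reference; exceedance sets an
  informational flag but no correction is applied, so burial estimates
  are conservative.

Inorganic carbon is screened by a one-sided one-sample t test of
acid-fumigation mass loss > 0 (α = 0.05 default).

## 9. Biome statistics and upscaling

Emission:burial ratios are computed per lake before any aggregation
(mean of ratios, never ratio of means — a metamorphic test enforces
this). Group comparison is a two-group one-way ANOVA on log-transformed
ratios (their distribution is strongly right-skewed; the reported means
± SDs stay on the raw scale). Within-biome emission~burial relationships
are OLS; slope homogeneity across biomes is an ANCOVA F test of the
burial × biome interaction, with optional log-lake-area and DOC
covariates. Regional upscaling multiplies the mean areal emission by the
regional lake area; the uncertainty convention is SD propagation
(SD × area), with an SE option.

## 10. Synthetic data: what it emulates, and what it does not

`synthetic.generate_lake` emits every input stream with known truth: a
conical (or paraboloid) basin sampled by ~300 soundings plus 100
shoreline zeros; an hourly pCO₂ series over the 154-day season with a
diel cycle (mean 800 μatm, amplitude 80, slow trend), linear
gain/offset calibration drift and density effects baked into the raw
output, ±5 ppm sensor noise; Weibull wind at 7.5 m (scale 4 m s⁻¹,
shape 2); six 48-h chamber campaigns (June–August, 10 total + 2
shielded chambers over two depth zones) with Poisson-timed bubble
injections (~7 mL CH₄ each, 0.5 events d⁻¹) into unshielded chambers
only; uniform under-ice and open-water grab profiles with winter
accumulation; and 1-cm cores following the CF:CS exponential
(w = 0.02 g cm⁻² yr⁻¹, supported 30 Bq kg⁻¹, surface excess
300 Bq kg⁻¹, C fraction 10 %, counting CV 7 %). Noise magnitudes are
plausible field values and configurable. One seeded generator per lake
with independent substreams per data type makes datasets byte-identical
under a fixed seed and insensitive to adding streams.

Truth is bookkept in closed form from the scenario parameters — analytic
basin volumes, the injected rates and the actually injected bubble
loads — in a code path separate from the pipeline. In noiseless mode
bubbles are placed deterministically, and the pipeline reproduces the
true annual CO₂, CH₄ and ice-out emissions within 3 % (observed: ≲1 %),
the residual being bathymetric discretization.

What the generator does **not** emulate, hence what passing tests do not
show about real data: no spatial pCO₂ heterogeneity (one raft position
stands for the lake), no storm-driven gas exchange beyond the wind
relation, no chamber artifacts (leakage, heating, surfactant effects),
no vertical concentration gradients in the grab profiles by default, no
sediment mixing or compaction profiles, and no covariance between
emission and burial within the biome table beyond the ratio structure
imposed.

The biome-table generator draws burial lognormal (mean 9, SD 6 g C m⁻²
yr⁻¹, identical across biomes — burial is comparable between biomes) and
per-lake ratios lognormal around biome targets of 34 ± 37 (boreal) and
2.4 ± 1.7 (subarctic–arctic); emission = ratio × burial. With the
default sample sizes (89 boreal, 10 subarctic–arctic) the log-ratio
ANOVA rejects in >99 % of seeds, and its size is ≈5 % under equal
targets. The regional upscaling constant is 1.4×10¹² m² of lake area
north of 63° N; with the synthetic arctic mean emission this lands at
~30 ± 30 Tg C yr⁻¹ (SD convention).

## 11. Problem sizes and known limitations

Default problem sizes (hourly season series ≈ 3 700 points, 4×10⁴-cell
rasters, 200-seed dating ensembles, 500/1000-seed power and size
simulations) keep the full test suite and the acceptance script in the
tens of seconds on one CPU while leaving the Monte Carlo standard errors
well below the tolerances being checked.

Known limitations: the CF:CS model assumes constant sedimentation — no
CRS (constant rate of supply) alternative is provided; the ANCOVA
degrees of freedom follow the standard interaction-test accounting and
are reported transparently rather than matching any particular published
df convention; CO₂ chamber fluxes are out of scope (CO₂ is sensor +
Fick only); and the upscaling uncertainty is a convention, not an error
propagation.
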