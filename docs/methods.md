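# Methods

This note documents the models and procedures `elderheat` implements, the
assumptions they rest on, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Demographic downscaling

The target is a mid-century (default 2050) age-stratified population grid
consistent with two coarser products: gridded projections of *total*
population per scenario, and country-level projections *by age stratum*.
Starting from a base-year age-stratified grid `n_{a,g,0}`, the imputation
applies two levels of multiplicative growth factors:

* a per-cell total growth factor `γ^T_{g,s} = N_{g,s} / Σ_a n_{a,g,0}`,
  which carries all sub-national spatial information about where population
  grows;
* a per-country, per-stratum adjustment
  `λ_{a,c,s} = N_{a,c,s} / Σ_{g∈c} γ^T_{g,s} n_{a,g,0}`, which rescales each
  stratum so the projected grid reproduces the country-by-age totals
  *exactly* (the adjustment is the ratio of the target to the unadjusted
  sum, so the constraint holds by construction; the test suite verifies it
  to 1e-9 relative, and in practice it holds to machine precision).

The projected grid is `N* = λ · γ^T · n` and per-cell 69+ shares follow as
`A+ = Σ_{a≥69} N* / Σ_a N*`. This is an *imputation*, not demographic
simulation: no cohort dynamics, fertility, mortality or migration schedules
are modelled. Its structural assumption is that within a country each age
stratum grows at a spatially homogeneous rate relative to total growth;
where that fails, country totals still hold but cell-level allocation is
biased (quantified below).

Age strata are a general labelled list with a flag marking strata at or
above the old-age cutoff (69 by default, configurable); the two-bin case
(<69 / 69+) is the default configuration, matching how such analyses
aggregate multi-stratum sources.

Degenerate inputs are resolved as follows, always with a logged count,
never silently:

* **Cells with zero base population but positive projected totals** leave
  `γ^T` undefined. They receive their country's population-weighted mean
  growth factor. Since such cells have no base population in any stratum
  they contribute nothing to the projected grid through the multiplicative
  path; the fallback keeps the factor surface finite and explicit.
* **A country stratum with zero base mass but a positive target** leaves
  the `λ` denominator zero. The target is then distributed uniformly over
  the country's populated cells: constraint satisfaction takes precedence
  over proportional allocation, which is impossible with no base signal.
* **Cells with zero projected total** have an undefined 69+ share, stored
  as NaN — never coerced to 0, which would understate old-age shares in
  empty cells downstream.

All arithmetic is double precision.

## Heat metrics

Three per-cell indicators are computed from daily series over a labelled
multi-year epoch (20 years by default):

* **CDD** (°C·day/yr): per year, `Σ_d max(0, T̄_d − T*)` with base
  threshold `T* = 24 °C`; the surface stores the arithmetic mean over the
  epoch's years, with the per-year series kept as an auxiliary field.
* **TMAX95** (°C): the 95th percentile of the *pooled* multi-year sample of
  daily maxima. The quantile convention is linear interpolation between
  order statistics (numpy's default); any fixed convention would do, but it
  must be fixed and stated for reproducibility, and the same convention is
  reused everywhere a quantile appears (weighted boxplot statistics,
  across-model interquartile ranges).
* **HD** (days/yr): count of days with daily maximum **≥** 37.5 °C
  (inclusive comparison), divided by the number of years. The raw epoch
  count rides along as an auxiliary field. Reporting per-year frequency
  rather than the raw 20-year count matches how such results are
  communicated ("days per year") while keeping the count available.

The daily *mean* temperature is taken as provided; no `(Tmin+Tmax)/2`
reconstruction is attempted. Calendars are idealized inside the metrics
(epochs are whole numbers of `days_per_year`-day years); real-data
ingestion is responsible for normalizing leap days or 360-day model
calendars before an epoch is constructed. Ensemble aggregation across
climate models is the cell-wise median (mean of the two central values for
even counts).

All three metrics are monotone non-decreasing under any cell-day warming,
and TMAX95 is exactly translation-equivariant; both properties are used as
test invariants.

## Exposure

Per-cell exposure multiplies the 69+ head count by the metric:
`PDD = A+·N·CDD`, `PD95 = A+·N·TMAX95`, `PHD = A+·N·HD`, with `N` the
cell's total population. Regional exposure is the plain sum over member
cells, so it is linear in population and additive under partition
refinement. Population grids finer than the climate grid are aligned by
block summation (mass-conserving to 1e-12 relative; the coarse cell's
country ID is the population-weighted mode of its fine cells); non-integer
resolution ratios are rejected with instructions to pre-resample rather
than silently interpolated.

Exceedance curves report the population living in cells whose metric is
**≥** a threshold (consistent with hot-day counting); they are
non-increasing step functions of the threshold. Benchmark changes between
scenarios count the population of cells that cross 30 hot days/yr, 37.5 °C,
or 1200 °C·day/yr — whole cells, with no within-cell interpolation. The
CDD benchmark is itself derivable from data as the mean CDD over cells
whose *historical* TMAX95 exceeds 37.5 °C; the unweighted cell mean is the
default (a population-weighted variant is exposed as an option).

Weighted statistics treat population counts as frequency weights: a cell
with `w` persons behaves as `w` identical person-level observations of the
cell's metric. The weighted quantile is the exact frequency-weight
generalization of the linear-interpolation sample quantile (for integer
weights it equals the quantile of the expanded sample). The two-group test
is a Welch test on weighted means and variances with effective sample sizes
equal to the weight sums; with unit weights it reduces exactly to the
standard Welch test, and a permutation oracle on the expanded person-level
sample backs it in the test suite. Its calibration is checked
unconditionally — each replicate draws a fresh null world — because the
rejection rate conditional on one particular random grid fluctuates around
the nominal level by construction.

## Decomposition of exposure change

Regional exposure is a sum of three-factor products, so its fractional
change between a baseline and a scenario epoch can be attributed to
age-structure, population-size and climate shifts. Three weighting schemes
are implemented:

* **`paper`** (default): per-cell fractional factor changes weighted by the
  cell's *scenario-epoch* share of baseline exposure,
  `w_g = A₁N₁H₁ / E_{r,0}`. This formulation is not an exact identity —
  factor cross-terms survive — so the residual
  `total − (ε^A + ε^N + ε^H) − emergent` is always computed and reported,
  never dropped. For large changes the residual is large; that is a
  property of the formulation, faithfully reproduced.
* **`baseline`**: weights `w_g = A₀N₀H₀ / E_{r,0}`. First-order exact
  (residual `O(δ²)` for factor perturbations of size `δ`, verified
  numerically at `δ = 1e-4`), and a pure single-factor change is attributed
  100% to that factor.
* **`lmdi`**: logarithmic-mean Divisia weights,
  `ε^X = Σ_g L(E₁_g, E₀_g) · ln(X₁/X₀) / E_{r,0}` with
  `L(x,y) = (x−y)/(ln x − ln y)`. Because
  `ln A₁/A₀ + ln N₁/N₀ + ln H₁/H₀ = ln E₁/E₀`, the three terms sum to
  `ΔE/E₀` exactly (to 1e-9 in floating point, typically 1e-15). The
  absolute (numerator) terms are symmetric: swapping epochs negates them.

Cells where a factor is zero in either epoch — most importantly places with
no hot days under the historical climate that acquire them under warming,
a realistic mid-latitude situation — have undefined fractional or
logarithmic changes. Their entire exposure change is reported as a separate
**emergent** term, so the accounting identity
`ε^A + ε^N + ε^H + emergent + residual = ΔE/E₀` closes under every scheme.

PD95 decomposes temperature in °C as-is; fractional changes of a
Celsius-scale quantity are origin-dependent, which is a documented caveat
of that family rather than something the package corrects.

## Validation of downscaled projections

Downscaled 69+ counts are aggregated (mass-conserving) to arbitrary
sub-national units and compared against reference projections with
per-unit absolute percentage error (APE), its unweighted mean across units
(MAPE; units with zero reference population are excluded from APE and
counted), the total error in persons, and the country-total percent error.
References built under non-SSP scenario assumptions are flagged
(`ssp_consistent=False`) rather than rejected, since part of any
discrepancy is then attributable to scenario mismatch. Reproducing
published comparison tables is out of scope: it requires external
sub-national reference datasets; the module is exercised against the
synthetic generator's hidden truth instead.

## The synthetic world

The generator emulates the five input families with controllable ground
truth, at desk scale: a 10×10 climate grid of 0.25°-like cells, a 2× finer
population grid, 4 countries, two strata split at 69, and 20-year epochs of
365-day years.

**Temperature.** Daily mean = cell baseline + seasonal sinusoid + scenario
warming offset + Gaussian noise; daily maximum = daily mean + half the
diurnal range (10 °C default). The baseline follows a north–south gradient
(8…28 °C) plus a small fixed east–west texture; the seasonal amplitude is
8 °C and the noise s.d. 1.5 °C. Warming offsets (1.0, 1.5, 2.0, 3.0 °C for
the four scenario labels) span the range of mid-century scenario warming;
the resulting world has historical hot days only in its warm belt, so
emergent-exposure cases arise naturally. Noise streams are keyed on
(seed, scenario, model index) through CRC32-hashed spawn keys, making every
artifact bit-reproducible across processes. A pure sinusoid was chosen over
autocorrelated weather because it admits closed-form CDD oracles; GCM-like
spatial covariance and humidity variables are deliberately not emulated
(the metrics are dry-bulb only), so passing tests say nothing about
spatially correlated model error in real ensembles.

**Demography.** Countries are axis-aligned column strips of climate cells
— a trivially valid cell→country mapping with easy block-sum checks. Base
totals combine a smooth density gradient with lognormal texture. The hidden
2050 truth applies per-country, per-stratum growth rates (elderly 2.0–3.5×,
younger 0.9–1.5×, mildly scenario-dependent); country tables are the exact
country sums of this truth and gridded totals its exact age sums, so all
emitted inputs are mutually consistent by construction and the truth grid
is available (flagged test-only) for recovery assertions.

Exact recovery by the two-level procedure requires `γ^T` to be constant
within each country, which in turn requires the base-year age *composition*
to be constant within a country (with homogeneous stratum growth, `γ^T` in
a cell is the cell-mix-weighted mean of the stratum rates). The generator
therefore draws the 69+ share as a gradient *across* countries (5%–20%),
constant within each. The optional perturbation multiplies the elderly
growth rate cell-wise by `(1 + m·p_g)` with a fixed zero-mean within-country
pattern `p_g ∈ [−1, 1]`: a controlled violation of the homogeneity
assumption whose magnitude `m` the validation module's error tracks
monotonically, while all emitted inputs remain exactly self-consistent.

## Problem sizes and defaults

The shipped study conditions are 100 climate cells × 20-year epochs ×
365-day years × 5 climate models × 4 scenarios, with the full pipeline
completing in seconds; tests use these sizes (or smaller grids where a
literal per-day Python loop is the oracle) and fixed seeds throughout. The
weighted-test calibration uses 1000 replicates of 2000 persons per stratum
over 100 cells. Thresholds default to 24 °C (CDD base), 37.5 °C (hot day),
and benchmarks 30 days/yr and 1200 °C·day/yr; the age cutoff defaults
to 69. All are configuration, not constants.

## Known limitations

* The downscaling inherits the homogeneity assumption of its construction;
  the validation module measures, but cannot remove, the resulting
  cell-level bias.
* Exceedance accounting is whole-cell; populations are not interpolated
  across a threshold within a cell.
* The synthetic temperature field has white daily noise and no spatial
  correlation, so ensemble spread statistics on synthetic data understate
  the structure of real model disagreement.
* Acute-intensity (PD95) fractional changes depend on the Celsius origin.
* Real-data ingestion (calendar normalization, variable mapping, CRS
  handling beyond regular lat/lon grids) is limited to the formats the
  package reads and writes; bias correction and climate downscaling are out
  of scope.
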