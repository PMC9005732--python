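# Methods

## Scope and structure

`afforwet` implements a complete attribution chain from tree planting to
wetland change: (1) Budyko partitioning of annual precipitation into
evapotranspiration and runoff as a function of aridity and vegetation;
(2) a bucket soil-moisture surrogate whose ET responds to forest cover
through the Budyko curves; (3) a soil-moisture-deficit wetland diagnostic
with static and dynamic calibration; (4) factorial S1−S0 attribution and
the chain sensitivity decomposition by climate zone; (5) near-term
planting scenarios; (6) basin aggregation and protection-level
statistics. Every input is synthetic, generated with known ground truth,
so calibration and attribution are verifiable end to end.

## Budyko partitioning

The two-parameter form ET/P = (1 + wφ)/(1 + wφ + φ⁻¹) with the
complementary Q/P sharing the same denominator, so ET/P + Q/P = 1 is an
algebraic identity (asserted to 1e−12). The plant-available water
coefficient is a fixed two-class parameter — w = 2 for forest, w = 0.5
for grass — never calibrated. Runoff change from planting is
δQ = P·Δf·[Q/P(φ, w_f) − Q/P(φ, w_g)], evaluated per cell-year with that
year's P and the cell's *climatological* φ (per-year φ available behind
an option): the attribution figures this feeds use climatological aridity,
and the split keeps interannual δQ variability driven by P alone. The
fractional reduction |δQ|/P at fixed Δf is unimodal in φ with an interior
maximum near φ ≈ 1.1; for Δf = 0.20 it exceeds 2% of annual P everywhere
on φ ∈ [0.6, 2.2].

For the bucket surrogate a cell's effective coefficient is the
area-weighted mix w = f·w_forest + (1−f)·w_grass; the non-forest
remainder is grass by construction.

## Bucket soil-moisture surrogate

A monthly storage model per cell:

    SM' = clamp(SM + P_m − ET − Q, 0, SM_sat)
    ET  = a · P_m · (SM/SM_sat),   Q = q · SM

where a = ET/P(φ, w(f)) is the annual Budyko evaporative fraction of that
year and P_m the monthly share of annual P (flat 1/12 by default; a
sinusoidal cycle exists but is off, since annual-maximum statistics under
a flat split do not depend on it). Defaults: SM_sat = 300 mm, drainage
q = 0.06 month⁻¹, initial storage 50% of capacity, three spin-up
repetitions of the first forcing year. On steps where neither bound
binds, ΔSM − (P − ET − Q) = 0 to machine precision; clamping at SM_sat
represents saturation excess (lost to fast runoff) and at 0 complete
drying, and the budget identity is asserted only on unclamped steps.

The parameter choices follow from the steady state
s* = P_m/(a·P_m + q·SM_sat) (s = SM/SM_sat): with the default
precipitation base (800 mm yr⁻¹) wet-zone cells (φ < 1) have s* > 1 and
sit pinned at capacity — planting cannot move their soil moisture, the
"abundant precipitation keeps soils moist" regime — while mesic and dry
cells equilibrate below saturation with deficits of roughly 15 and
40–50 mm and respond to planting through a. This surrogate is a stand-in
for a full land-surface model: it has no soil physics, no lateral
redistribution, no snow, and its purpose is a correct and analytically
transparent sign structure (more forest → higher ET fraction → lower SM,
strongly in dry climates, not at all in saturated ones), not quantitative
realism of any one process.

## Wetland diagnostic and calibration

The saturated fraction is a generalized sigmoid of the deficit,
f(D) = f_max·(1 + v·exp(k(D − d0)))^(−1/v), a CDF-like stand-in for the
cumulative topographic-index distributions used by subgrid saturation
schemes (explicit CTI fitting from high-resolution DEMs is out of scope).
v defaults to 1 (symmetric logistic, f(d0) = f_max/2).

* **Static calibration** fixes the shape (k, d0, v) and inverts the
  single long-term-maximum observation: f_max = obs/shape(D_min). One
  observation cannot identify three parameters; cells observed at zero
  get f_max = 0. The operation is idempotent and reproduces the
  observation at the minimum-deficit timestep by construction.
* **Dynamic calibration** fits (f_max, k, d0) to ≥ 4 annual maxima by
  bounded trust-region least squares (f_max ∈ [0,1], k ∈ [1e−4, 2] mm⁻¹,
  d0 ∈ [0, max deficit + 100] mm), v held fixed; the SSE and a
  convergence flag are returned rather than raised, and a deficit series
  without interannual variability is flagged degenerate (k, d0
  unidentifiable).

Monthly fractions are aggregated to annual maxima before any comparison
with observations; wetland "area" is fraction × full cell area, with no
sub-cell lowland masking.

### Ground-truth parameters for the synthetic world

The generator draws f_max ~ U(0.05, 0.4) with 30% of cells at zero, and
uses spatially uniform k = 0.15 mm⁻¹, d0 = 45 mm, v = 1. Uniform shape
parameters encode the assumption that the flooding threshold is a
topographic, climate-independent property. A consequence worth stating:
wet-zone deficits (~0) sit far above the threshold (wetlands pinned near
f_max), mesic deficits (~15 mm) on the flat shoulder, and dry-zone
deficits (~40–50 mm) near the steep midpoint — so the higher
vulnerability of dry-zone wetlands emerges from the interaction of
climate with a climate-blind landscape, rather than being painted into
the parameters.

## Attribution and sensitivity decomposition

The forest effect is isolated factorially: S1 (with forest change) minus
S0 (constant year-2000 forest), both under identical climate. Period
changes entering the chain identity are end-minus-start differences
(final-year minus first-year analogues) of the S1−S0 series for wetland
area and annual-mean SM, and of the raw trajectory for forest area —
cumulative-change plots imply difference-based δ quantities; a
regression-based alternative is a possible extension. Because all three
δ's are plain differences, the identity
δA_wet/δA_forest = (δA_wet/δSM)·(δSM/δA_forest) holds exactly wherever
both denominators are nonzero; the acceptance-style check (90% of
included cells within 10%) is an estimator-consistency guard, not a
tolerance the construction needs.

Filters: cells with no forest over the period, no forest change, a mean
annual maximum wetland fraction not exceeding 1% (strict), or rice
coverage above 10% (strict) are excluded. Boundary conventions, all
documented choices where the rules leave them open: fraction thresholds
are strict inequalities; φ values of exactly 1 or 2 fall in the mesic
zone (closed interval); a zero trend is "boundary", not a quadrant.

Outliers: the 5th–95th percentile band uses linear interpolation between
order statistics (the numpy default; for values 1..100 the band is
[5.95, 95.05], retaining 6..95). Inside `sensitivity_ratios` the band on
δA_wet/δA_forest is computed over **all finite-ratio cells** and then
intersected with the filter mask. Computing the band on the post-filter
pool instead would make the band depend on the filter configuration and
degenerates for small pools (any symmetric percentile band on two values
keeps both or neither); the all-finite pool keeps the outlier criterion
stable and filter-independent. The standalone `drop_outliers` (used for
the per-zone box statistics) operates on whatever values it is given.

Trends are ordinary least squares against calendar year with a two-sided
t-test; a constant series has slope 0 and p = 1 by convention, an exact
nonconstant fit p = 0, and fewer than three points a missing result.

## Scenarios

Four kinds share one national target over 2017–2035: `SA` allocates
proportionally to each cell's historical planting; `SA_dry`/`SA_mesic`/
`SA_wet` put the whole target in one climate zone, proportionally to
remaining plantable area (the rules give no within-zone prescription;
remaining-capacity weighting is the declared choice). Allocation caps
every cell at 95% forest (a reserved non-plantable remainder) and
redistributes the excess iteratively; an infeasible target raises an
error carrying the shortfall. "Constant climate" is seeded resampling of
historical years with replacement — the 19-year window exceeds the
17-year record, so a pure permutation cannot cover it — and the draw is
part of the scenario configuration. Projection runs the bucket under the
scenario and under a constant-forest control with identical forcing and
attributes wetland change as S1−S0; a zero-target scenario is
bit-identical to its control. Losses are percentages of the baseline-year
control wetland area; gains are flagged, never reported as negative
losses; the loss histogram bins are [2,4), [4,6), [6,8), [8,10) and
strictly >10%, so a loss of exactly 10% is uncounted (documented
convention). Alternate climate realizations can be supplied as any
climate series in place of the recycled one.

## Basins

Aggregation is exact summation or area-weighted means; basin-scale δQ
aggregates P, PET and forest fraction to basins first and then applies
the attribution equation with the basin's climatological φ. Note that
because |δQ|/P is unimodal in φ, a basin mixing cells from both limbs of
the curve can show a larger |δQ| than any member cell; the
"aggregation smooths extremes" intuition holds only within one limb.
Group regressions run through the yearly cumulative-change points
(ΔA_wet vs ΔA_forest summed over the basins of each protection group),
with an intercept, starring significance at the 99% level; a basin's
protection level is the highest-level reserve it contains, resolved at
generation time. Threshold exceedance counts are strict (> 10% by
default), overall and per level.

## Synthetic generators: what they emulate and what they do not

The generators emulate 0.5° gridded forcing with a west–east aridity
gradient spanning PET/P 0.3–3 (all three zones populated), multiplicative
interannual noise (CV 0.15) drawn independently for P and PET, monotone
piecewise-linear forest gain allocated over random concentration weights
(default national increase 15,000 km², ~3% of the default domain — the
same order as China's 2000–2016 forest expansion relative to its area),
contiguous basins by seeded region growing with protection shares
15/20/25/40%, and a static rice mask (12% of cells). The precipitation
base is spatially uniform, so aridity is driven by demand alone — a
controlled-experiment design that isolates the demand pathway. Not
emulated: spatial autocorrelation of climate noise, co-variation of P
with aridity, seasonality (flat monthly split), dynamic rice extent,
satellite retrieval artifacts beyond multiplicative noise, and any
land–atmosphere feedback of planting on precipitation. Passing tests
therefore demonstrate the correctness and internal consistency of the
method on a world obeying its assumptions, not the realism of any
specific regional number.

## Problem sizes and determinism

The standard domain is 10×20 cells (≈ 0.46 Mkm²) over 17 historical and
19 projection years at a monthly bucket step — large enough to populate
all three zones and every filter class, small enough that the full
pipeline runs in seconds. All randomness flows from a single seed, split
per stage by a fixed affine map so stages rerun independently yet
reproducibly; rerunning a configuration reproduces byte-identical outputs
and manifest hashes. Gridded products are CF-style NetCDF (lat/lon/time
with units), tables CSV, configuration declarative YAML.

## Known limitations

The bucket's δSM response peaks in the mesic zone when measured per unit
forest-fraction change (the Budyko sensitivity ∂(ET/P)/∂w is largest near
φ ≈ 1); the dry-zone dominance of the final wetland sensitivity arises
from where deficits sit on the diagnostic's sigmoid. Systems in which
dry-zone soil moisture itself responds most strongly would need a richer
surrogate. Static calibration inherits any bias in the long-term-maximum
observation; dynamic calibration of k and d0 is weakly identified when
interannual deficit variability is small (flagged, and f_max remains well
determined). Basin polygons are not handled — membership is a cell table.
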