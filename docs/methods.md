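# Methods

## Model overview

The package treats a crop's climatic niche as an *empirical envelope*: the
set of climate conditions under which the crop's major production happens
today. No physiology, yield response, soil or management information enters
the model; the only claim is that climates hosting major production now are
demonstrably compatible with producing that crop under current practices.
Consequences of this assumption: the niche can only be as wide as the
crop's current geographic spread, narrow-range crops get narrow niches, and
"outside the niche" means *unprecedented for major production of this
crop*, not *impossible to cultivate*.

## Climate parameters

All climate enters through five per-cell annual quantities computed from
12-month climatologies:

| parameter | definition | units | notes |
|---|---|---|---|
| annual precipitation | Σₘ precipₘ | mm/yr | negative inputs rejected |
| biotemperature | (1/12) Σₘ max(Tₘ, 0) | °C | divide-by-12 convention (below) |
| PET | 58.93 × biotemperature | mm/yr | Holdridge constant |
| aridity | PET / precipitation | — | capped at 2⁸ when precipitation is 0 |
| frost indicator | min ₘ Tminₘ > 0 | bool | 0 °C counts as frost |

Monthly mean temperature is estimated as (Tmin+Tmax)/2 where a true mean is
unavailable, and bias-corrected by adding the reference period's
(mean − midpoint) difference per cell and month. The correction is additive
and deliberately not idempotent — applying it twice adds the bias twice.

**Divide-by-12.** "Mean of monthly temperatures above 0 °C" is ambiguous
between dividing the clamped sum by 12 or by the number of positive months.
We divide by 12: it is the convention of the Holdridge framework the
envelope concept builds on, and it is the only choice that keeps annual
PET = 58.93 × annual biotemperature consistent with summing monthly PET
values. No upper biotemperature clamp is applied by default (`cap`
argument available; some life-zone variants clamp at 30 °C).

**Aridity at zero precipitation.** The ratio is undefined on truly
precipitation-free cells; we assign 2⁸, which lies beyond the driest
log2 humidity class, so such cells stay distinguishable yet finite for
binning. Cells with zero PET and zero precipitation get aridity 0.

**Frost.** `frost_free` requires *strictly* positive monthly minima; a 0 °C
month counts as frost. When parameter bundles are interpolated between
periods the binary field is interpolated numerically like every other
parameter and re-binarised at ≥ 0.5.

**Life zones.** The classic 38-zone Holdridge table
(1 polar + 4 subpolar + 5 boreal + 6 cool-temperate + 7 warm-temperate +
7 subtropical + 8 tropical) is shipped as a versioned CSV
(`cropscs/data/hlz_zones.csv`). Classification uses half-open [low, high)
intervals on the log2 biotemperature and precipitation class edges, with
the frost flag splitting the 12–24 °C band into warm-temperate (frosty) and
subtropical (frost-free) rows. Aridity classes follow from the other two
axes through the PET constant. Non-finite inputs yield zone 0
(unclassified).

## Warming levels

Each level (1.5/2/3/4 °C over pre-industrial) is represented by the first
scenario whose central crossing estimate reaches it; parameters are
linearly interpolated between the two 20-year period climatologies whose
centre years bracket the crossing year:
Y = (Y₀(x₁−x) + Y₁(x−x₀))/(x₁−x₀). The shipped default table
(`cropscs/data/warming_levels.csv`) is

| level | scenario | x (crossing) | x₀ | x₁ |
|---|---|---|---|---|
| 1.5 | SSP1-2.6 | 2033 | 2031 | 2051 |
| 2 | SSP2-4.5 | 2053 | 2051 | 2071 |
| 3 | SSP3-7.0 | 2076 | 2071 | 2091 |
| 4 | SSP5-8.5 | 2085 | 2071 | 2091 |

x₀/x₁ follow from the rule "the two future periods overlapping the crossing
estimate's range"; users can override the table.

## Niche delineation and membership

Cells are ranked by production (descending; ties broken in row-major cell
order for reproducibility) and the shortest prefix reaching 95% of total
tonnage is the *major production area*; the threshold-crossing cell is
included, so the realised share is ≥ the nominal one. The niche is the set
of climate-space bins those cells occupy. The *marginal* cells are the
complement (the lowest-5% contributors), plus zero-production cropland when
"marginal or no production" is meant.

The climate space is discretised on log2-spaced edges aligned with the
Holdridge class geometry — precipitation 62.5–16000 mm/yr, biotemperature
1.5–24 °C, aridity 1/8–32, each with `bins_per_class` (default 2) geometric
sub-bins per class, plus open outer bins and the boolean frost axis. The
envelope depends on this resolution, so `bins_per_class` is recorded in
every SCS definition's provenance and in the run provenance. Membership is
a pure bin-set lookup; cells with non-finite parameters are always outside.

## Ensemble and consensus

Membership is evaluated independently per GCM and warming level. Consensus
is a majority vote with the inclusive threshold ⌈n/2⌉ ("at least half"; 4
of 8 suffices). Cell-level indicator maps use consensus membership; the
crop-level production-outside indicator keeps the full ensemble and reports
median and 25th/75th percentiles, computed with linear interpolation
between order statistics (recorded in provenance). Consensus is computed
independently per level — a cell may re-enter a niche at a higher level.

## Indicators

*Risk to production.* Per cell and level, the production-weighted share of
all food crops' output outside their niches; per cell, the lowest level at
which the share reaches the threshold (default 0.25; 0.5 and 0.75 as
sensitivity values), with an infinite sentinel for "never at any studied
level". First crossing wins even if the share later falls back below the
threshold. Regional summaries divide at-risk cropland hectares by regional
cropland hectares; cropland cells without food-crop production stay in the
denominator. Group aggregation sums member crops' tonnages outside before
normalising by the group's reference tonnage.

*Area change.* On the total-cropland extent, A_b and A_w are the cropland
hectares within the niche at baseline and at a level; net% =
(A_w−A_b)/A_b·100, gain% and loss% = shifting-area/A_b·100, and
net = gain − loss exactly. Area weighting always uses the supplied physical
cropland hectares, never geometric cell area, which sidesteps geodesy and
matches "share of cropland area" semantics. Group ratios are formed from
summed area components per GCM before taking ensemble quantiles.

*Potential diversity.* The count of food crops whose niche contains the
cell's climate, on total cropland, from consensus memberships. Change
categories: exactly −100% its own class; 25-point left-open/right-closed
bins on both sides ((−100,−75], …, (−25,0), (0,25], …, (75,100], >100%);
exactly 0 is "no change". Cells inside no niche at baseline are "marginal
in baseline": we operationalise this climate-side (baseline count = 0)
because major-production cells are inside their own crop's niche by
construction, so baseline-zero cells can host at most marginal production;
the production-side reading (lowest-5% rank) is available via
`select_marginal_cells` as a cross-check. Such cells become "cropland with
emerging climatic potential" if at least one niche arrives under warming.
Zonal summaries report cropland-hectare shares per region, latitude band
and elevation band ({<500, 500–1500, 1500–2500, >2500 m} by default — the
high band is where emerging potential tends to concentrate).

## Synthetic world

The generator emulates the structure of the real inputs, not their physics:

- temperature: latitudinal gradient 28 °C (equator) to ≈ −15 °C (poles)
  with a poleward-growing seasonal sinusoid (opposite phase per
  hemisphere), ±5 °C diurnal bracket for Tmin/Tmax, white noise
  (default sd 0.3 °C);
- precipitation: latitudinal bands (≈2200 mm/yr equator, ≈350 subtropics,
  ≈900 mid-latitudes, ≈250 poles) with smooth longitudinal modulation and
  log-normal noise (default sd 0.05 in log space) — enough structure to
  spread cells across many life-zone bins and make aridity informative;
- pseudo-GCMs: shared warming offset and precipitation scale per level
  (defaults +1.5/2/3/4 °C with scales 0.98/0.96/0.93/0.90, a mild drying
  trend), differing only by seeded noise, so vote outcomes are predictable;
- crops: niche boxes anchored at quantiles of the realised baseline
  parameters (guaranteeing occupancy), log-normal production inside the
  box, and a 2% *marginal scatter* — production share placed on cells
  outside the box — to exercise the lowest-5% machinery;
- cropland area: uniform in (0, 8500] ha on producing cells; region masks
  are grid quadrants; latitude bands use 23.5°/55°; elevation is a sum of
  smooth random massifs.

Everything is drawn from one seeded generator: identical configs give
bit-identical bundles, and zero-noise/zero-delta futures equal the baseline
byte for byte.

What passing tests on this world do **not** show: behaviour under real
spatial autocorrelation of production, coastlines/missing data, disagreeing
GCM patterns (pseudo-GCMs differ only by noise), observational biases of
real climatologies, or the actual magnitudes of the global results — those
require the full climate and production archives, which this package
deliberately does not bundle.

## Reference problem sizes

The shipped study conditions are a 60×120 grid with up to 6 crops, 4
pseudo-GCMs and 4 warming levels; the full pipeline completes in seconds at
this size, and the test suite uses 16×32 to 60×120 grids. All sizes are
configuration, not code: the same code paths run on arbitrary aligned
grids.

## Numerical conventions and degenerate inputs

- All-zero production: rejected (no ranking possible).
- Non-finite parameters: excluded from delineation (counted in provenance),
  always outside in membership, zone 0 in classification.
- Zero baseline within-niche area: net/gain/loss reported as NaN
  ("undefined"), never as ±inf.
- Bin edges: values exactly on an edge fall in the upper bin (half-open
  [low, high) intervals everywhere, including the life-zone table).
- Ties in production rank: row-major cell order (stable sort).
- Warming interpolation is exact at endpoints by construction.

## I/O and provenance

NetCDF I/O goes through xarray's scipy backend; single-band fields are
written as plain single-page TIFF via tifffile (no CRS tags — grids are
matched by shape and coordinate vectors, and misalignment is a hard error
rather than a resample). Every pipeline run carries a provenance record:
config SHA-256, package version, the decisions in force (bin resolution,
vote rule, percentile method, aridity cap) and stage digests; reruns with
unchanged inputs are byte-identical because no wall-clock content enters
result files.

## Known limitations

- The envelope ignores within-year timing (growing seasons); an analysis
  restricted to cropping-season months would need crop-calendar data.
- No yield levels, CO₂ fertilisation, soils, irrigation availability or
  socio-economic feasibility — "inside the niche" is a climatic statement
  only.
- Niche width is confounded with current geographic spread; comparisons
  across crops inherit that.
- The bin-set envelope is resolution-dependent; report `bins_per_class`
  with any result.
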