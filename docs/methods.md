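# Methods

This note documents the models behind `amazonfires`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Fire-type classification

The unit of classification is the **pixel-year**: all detections at one
~1-km pixel within one calendar year share a label, consistent with the
persistence definition (distinct detection days per pixel-year). The three
rules, applied in order:

1. **deforestation** — persistence ≥ `min_persistent_days` (2) **and**
   annual deforestation rate ≥ `min_defor_rate` (5%). The 5% floor
   corresponds to the smallest clearing a PRODES-style product resolves in a
   1-km cell.
2. **forest** — persistence ≤ `max_forest_days` (3) **and** year-2000 tree
   cover ≥ `min_tree_cover` (70%) **and** cumulative deforestation since
   2001 ≤ `max_cum_defor` (20%): burning under largely intact canopy.
3. **maintenance** — everything else.

All comparisons are inclusive (≥ / ≤) at the thresholds. Pixel-years with
2–3 detection days can satisfy rules 1 and 2 simultaneously; the rules'
order of statement resolves the overlap in favour of deforestation, and the
`precedence` argument flips it for sensitivity analysis (tests pin down that
flipping changes exactly the overlap cells and nothing else). Persistence is
counted over the calendar year by default; a `months` window restricts it to
a dry season instead, since both definitions appear in operational use and
they differ whenever a pixel burns outside the season.

## Trend machinery

* **Mann–Kendall**: S = Σ_{i<j} sign(x_j − x_i); Var(S) with the standard
  tie correction (n(n−1)(2n+5) − Σ t(t−1)(2t+5))/18; z with the ±1
  continuity correction; p two-tailed from the normal approximation. For
  tie-free series with n ≤ 10 the exact p is computed from the Mahonian
  (inversion-count) null distribution and reported alongside; tests verify
  it against full permutation enumeration and against the exact Kendall-tau
  test. All-equal series are degenerate: S = 0, p = 1, flagged.
* **Theil–Sen**: slope via `scipy.stats.theilslopes` (median of pairwise
  slopes) with distribution-free 95% confidence limits; the intercept uses
  the median-residual convention median(y − slope·t). The reported interval
  is the Sen slope CI and is labelled as such — no claim is made that it
  matches any other ± convention.
* **OLS** (`scipy.stats.linregress` behind the module surface): R² = 1 −
  SSE/SST and the two-sided t-test on the slope. Significance defaults:
  α = 0.01 for fire-count trends, 0.05 elsewhere; both configurable.
* **Phase regressions** regress annual fires on deforested area within each
  policy phase (defaults: 2004–2008, 2009–2011, 2012–2015, 2016–2019) plus
  the full span; phases with < 3 years are flagged non-testable, 3-year
  phases carry a low-n flag rather than being dropped.

## Anomaly extent

z-scores use the per-pixel mean and **sample** (n−1) SD over the reference
window (configurable to population SD). Pixels with zero variance — which
includes every never-burning pixel — cannot be standardized and are masked
and counted. Exceedance is strict (z > threshold, default 2). Because the
valid-area denominator is a genuine ambiguity (whole region vs fire-affected
pixels), `extent_above` exposes both and the pipeline reports both columns;
the fire-affected denominator is the default since never-burning pixels
would only dilute the index.

## FRP intensity

Percentiles use linear interpolation between order statistics (NumPy's
`linear` method), so FRP90 of {1..10} is 9.1. Densities are Gaussian KDEs on
log-FRP with Scott's-rule bandwidth, transformed back to FRP space (divide
by x), which respects positivity and the heavy right tail; groups under 30
values fall back to a normalized histogram with a warning. Densities are
descriptive only — nothing downstream consumes them.

The breakpoint model fits, for every candidate knot year b with at least 3
points on each side, a two-segment line **continuous at the knot** (design
matrix [1, t, (t−b)⁺]) and selects the b with minimal SSE; ties break to the
earliest candidate, and when no candidate improves on a single straight line
the fit is flagged `no_break`. A discontinuous two-line mode is available
behind a flag. Branch Mann–Kendall tests include the knot year in both
branches, treating it as a shared turning point.

## EOF/PC decomposition

The decomposition runs on the years × valid-pixels matrix of standardized
anomalies via thin SVD — the natural orientation when years (~17) ≪ pixels.
λ_k = 100·s_k²/Σs²; PCs are the year projections u_k·s_k; EOFs are
orthonormal right singular vectors. The sign gauge makes the largest-|loading|
element of each EOF positive (deterministic across platforms; every
PC_k·EOF_k product is gauge-invariant). No rotation is applied. Because
standardization already centres each pixel over the reference period, no
additional centring is done.

## [CO] analysis

The [CO] trend uses OLS-on-time (the R²-with-p reporting convention),
while fire counts use MK/Theil–Sen; both tests run on either series if
wanted. `window_adjust` recomputes a single year's annual mean over a
shifted 12-month window (e.g. April–March for a late fire-season onset)
from monthly values. The sensitivity scan multiplies the target years by
(1 − k/100) for k = 0, step, 2·step, …, reruns the trend regression and
reports the minimal k with p < α along with the full profile; the pipeline
applies the window adjustment before the scan and records that order.

## Synthetic generator

One root seed feeds named child streams (`landscape`, `seasons`, `co`,
`monthly_co`, spawned in that order), so regeneration is bit-identical.

* **Landscape.** Pixels are high-cover (tree cover in [70, 100)) or
  low-cover ([0, 70)) per `tree_cover_mix` (default 60/40). Each year an
  exact share `defor_front_fraction` (default 2%) of the grid — drawn
  without replacement from low-cover, non-exhausted pixels — clears at
  5–15%/yr. The exact-share draw (rather than per-pixel Bernoulli) keeps the
  annual deforested-area series smooth, like the operational products it
  emulates; a Bernoulli front would give the area series a ~20% CV at desk
  grid sizes. High-cover pixels are never cleared, which keeps the three
  type strata disjoint and truth labels unambiguous.
* **Fire seasons.** Expected totals decline geometrically
  (`annual_trend` = −5%/yr from 3 detections·pixel⁻¹ in 2003); per type and
  year the count is Poisson with mean total·mix·drought factor. Drought
  years default to {2005, 2007, 2010, 2015} with multipliers forest 3.0,
  maintenance 2.0, deforestation 1.0 — anchored to the observed drought-year
  dominance of forest fires (a 53% baseline share rising to ~65% of a
  drought year's total requires roughly a 3× forest amplification with
  maintenance near 2×), and to deforestation burning being policy- rather
  than weather-driven. Deforestation detections get ≥ 2 distinct days per
  pixel-year, forest ≤ 3, maintenance exactly 1, inside a July–November
  season (the region's dry season; the season window is configurable).
* **FRP.** Lognormal per type: deforestation (μ=3.4, σ=1.1), maintenance
  (2.3, 0.8), forest (2.4, 0.8), chosen so deforestation FRP90 is ≈ 4× the
  forest value while medians barely differ — the heavy-tail contrast that
  makes high percentiles discriminating. A multiplicative log-linear V
  (knot 2013, slopes −0.06/+0.08 per year) modulates all FRP by year, so
  the annual FRP90 series carries a known injected breakpoint.
* **[CO].** [CO]_t = 95 + 0.002·totals_t + N(0, 1.5) ppbv, resampled if
  non-positive; monthly values add zero-sum within-year wobble so calendar
  means reproduce the annual series exactly while shifted windows differ.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: cloud/overpass detection gaps, spatial
autocorrelation of burning beyond the stratum structure, within-season
timing patterns, the migration of the deforestation frontier (front pixels
are re-drawn each year, so deforestation fires are *less* spatially
persistent than observed, which flattens their EOF spectrum relative to the
real system), deforestation rates trending in time, and emission transport
from outside the region (the [CO] series is driven purely by internal fire
counts, so the 2007/2010-targeted sensitivity scan typically finds the
coupled series already significant or unrescuable — the scan's mechanics
are therefore tested on constructed fixtures with explicit import shocks).

## Problem sizes and determinism

Default study: 60×60 km grid, 2003–2019, ~170k detections — the full
pipeline runs in seconds and the whole test suite in well under a minute of
simulation time, while keeping Poisson noise small relative to the injected
effects. Simulation-based tests fix every seed; calibration checks
(type-I error, breakpoint recovery, drought separation) use 200–1000
replicates with binomial tolerance bands. CSV output uses a fixed `%.10g`
float format and NetCDF-classic rasters, so manifests hash reproducibly.

## Known limitations

* Persistence windows other than the calendar year interact with the
  deforestation-rate year label; the PRODES-style Aug–Jul reference window
  is exposed only as the configurable month window, not as a raster
  resampling.
* No autocorrelation-corrected (prewhitened) Mann–Kendall variant.
* Single breakpoint only; no multi-knot search.
* `aggregate_to_grid` requires the fine raster to divide the analysis grid
  evenly and supports no reprojection.
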