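# Methods

## Movement model

A track is an ordered sequence of daily fixes `(t_i, x_i, y_i)` in
projected meters, `t` in days since fledging. Between consecutive fixes
the animal is assumed to perform planar Brownian motion conditioned on
both endpoints (a Brownian bridge). At elapsed fraction
`α = (t − t_a)/T` of a segment of duration `T`, the position is isotropic
bivariate normal with mean on the straight line between the fixes and
per-axis variance

    σ²(α) = T·α(1−α)·σ_m² + ((1−α)² + α²)·δ²

`σ_m²` (m²/day) is the Brownian motion variance — per-axis displacement
variance accrued per day — and `δ²` (m²) the location-error variance of a
fix (default 9 m², i.e. GPS accuracy ± 3 m; a per-fix override exists on
the `Fix` type). With this convention the mean squared (2-D) net
displacement of an unconditioned walk is `2 σ_m² t`.

A degenerate consequence worth noting: for two coincident fixes and
`σ_m² → 0` the time-integrated distribution is a *scale mixture* of
Gaussians with variance `((1−α)²+α²)δ²` (between δ²/2 and δ²), not a
single Gaussian with variance δ²; the unit tests check against the
analytic mixture.

## Utilization distribution

The utilization distribution is the duration-weighted time average of the
bridge densities:

    h(z) = (1/T_total) Σ_i T_i ∫₀¹ φ(z; μ_i(α), σ_i²(α)) dα

The α-integral per segment is evaluated by fixed-order Gauss–Legendre
quadrature (default 20 nodes per segment; doubling the order changes
every cell mass by < 10⁻⁴ on the test tracks). Because the integrand is
separable in x and y, each quadrature node costs two 1-D Gaussian
evaluations and one outer product, so full studies run in well under a
second per individual.

**Cell value convention.** The per-cell value is the density at the cell
center times the cell area, *not* the cell-integrated probability. This
is exact in the limit σ ≫ cell size and is accurate to < 0.1% once the
smallest bridge sd exceeds ~0.8 cell widths. Near the fixes the bridge sd
approaches δ = 3 m, which is below the 30 m land-cover resolution, so the
fix cells are slightly over-weighted on NLCD-scale grids; this biases no
directional comparison but is why the Monte-Carlo validation grids use
5 m cells with δ = 10 m, inside the convention's validity range.

**Grid.** The default grid covers the fix bounding box with a margin of
3× the maximum per-segment sd (+1 cell); when a land-cover raster is
supplied the grid snaps to its lattice and is clipped to its extent so
cell centers coincide. The raw masses are renormalized to sum to 1; a
pre-normalization mass below 0.99 (too-tight grid, or clipping at the
landscape edge) triggers a warning and is recorded on the `PDFGrid`.

**Variance estimation.** `σ_m²` is estimated per individual × period by
the standard leave-one-out scheme: every odd-indexed fix is modelled as a
bridge observation between its two neighbours and the product of
isotropic normal densities is maximized over `σ_m²` in [10⁻⁶, 10⁸] m²/day
(bounded scalar search on the log scale; deterministic). On simulated
Brownian tracks (500 fixes, truth 400 m²/day, δ = 3 m) the median of 20
replicate estimates falls within ±15% of truth. Whether to pool the
estimate per species or per period is a genuinely open choice; the
per-individual × period default matches how the home ranges are built.

## Home range and habitat use

The home range at level p (default 0.95) is found by ranking cells by
density and accumulating mass until ≥ p, with every cell tied at the
threshold density included (so an exactly uniform PDF yields its whole
support). Area is cell count × cell area; the mask may be spatially
disconnected — no connectivity filtering is applied. Against a
discretized isotropic Gaussian the contour area matches the closed form
π·(−2 ln 0.05)·σ² within 5%.

Weighted habitat proportions restrict the UD mass to the home-range mask
and renormalize within it ("use within the home range"); mass outside the
95% contour is discarded, not redistributed. An alternative reading —
weighting over all grid cells before renormalization — would differ only
by the ≤ 5% mass outside the contour; the mask-restricted form is the
default and the only one exposed. Proportions sum to 1 per individual ×
period (tolerance 10⁻⁹) and per-class areas to the home-range area
(10⁻⁶ km²). Classes used by no individual in either period are dropped
before group summaries. SE uses the n−1 standard deviation; singleton
groups report SE 0 with an explicit `se_undefined` flag.

## Movement metrics and statistics

Per individual × period: mean step length (the per-individual "path
length"; raw steps are also returned), total displacement (sum of step
lengths), net displacement (first to last fix), and home-range area from
that period's own PDF. The split assigns fixes with t ≤ 20 d to the
pre-independence period. Individuals that died with their last fix at
t ≤ 1 d are censored before any analysis.

CV = sd(n−1)/mean of per-class area across a group's individuals;
ΔCV = CV_post − CV_pre; groups with < 2 individuals or zero mean are
flagged undefined. The chi-square independence test uses Pearson X² with
no continuity correction after removing classes whose total count is
below 2 (and all-zero rows). Because the pipeline produces proportions,
not counts, a conversion rule is required and is an explicit, reported
choice: each individual × period contributes one count to its
modal (highest-proportion) class. Under the null the test's empirical
type-I error at α = 0.05 is 0.05 ± 0.02 (2,000 simulated tables with
expected counts ≥ 5).

## Synthetic data generator

The generator exists so every stage can be validated with known truth; it
emulates the study conditions, not any particular bird.

- **Landscape** (defaults): 200 × 200 cells of 30 m (6 × 6 km); matrix
  cells drawn i.i.d. from a developed/agricultural class mixture; 8
  forest patches placed as discs whose cell count equals a uniformly
  drawn area in 5–163 ha (nearest-k cells around a random center, kept
  fully inside the raster); a rectangular road grid at 1 km spacing
  rasterized on top (any cell a line intersects becomes the road class).
  Class codes follow the NLCD legend plus code 1 reserved for roads.
- **Trajectories:** one fix per day at integer t. Each day proposes a
  Gaussian displacement with the current period's σ_m² and accepts it
  with Metropolis probability min(1, w_dest/w_cur), where a cell's weight
  is `forest_affinity` for forest classes, `1/road_avoidance` for road
  cells and 1 otherwise — the simplest mechanism whose stationary
  distribution is proportional to the habitat weights (uniform when all
  weights are 1). Rejected moves stay put; positions reflect at the
  landscape boundary; recorded fixes add isotropic Gaussian error
  (sd 3 m) and are folded back inside the bounds. A constant daily
  Bernoulli survival (default 0.995) can truncate a track, setting fate
  to "died".
- **Cohorts:** two species × 20 individuals by default, each started in a
  random forest cell and tracked for a uniform 2–88 days. Default motion
  variances are 3,000 m²/day pre- and 12,000 m²/day post-independence,
  chosen to put mean daily steps in the 60–135 m range typical of
  post-fledging songbirds; the specialist has forest affinity 5 and road
  avoidance 5, the generalist is indifferent (both 1).

What the generator does **not** emulate: memory, nest-centering or
parental attraction; missing tracking days (the estimator accepts gaps,
the generator never produces them); heterogeneous GPS error;
non-stationary habitat preference. Passing the end-to-end checks
therefore shows the pipeline recovers contrasts a biased random walk
encodes — not that real fledglings move this way.

## Problem sizes and determinism

The test suite and the acceptance script use: 20 replicate studies of
2 × 20 individuals for the directional checks; 10⁶ Monte-Carlo samples
for the utilization oracle on 2- and 5-fix tracks; 500-fix tracks × 20
replicates for variance recovery; 2,000 simulated tables for chi-square
calibration. Everything derives from explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); identical seeds give
byte-identical rasters, tracks and manifests.

## Known limitations

- Single σ_m² per track segment set; no dynamic/behavioural switching
  within a period, no x–y covariance (anisotropy).
- Center-density cell values under-resolve the UD where the bridge sd is
  below the cell size (see above).
- The chi-square proportion→count rule is a convention; different rules
  change the statistic (the test's calibration, not its application to
  any particular published table, is what is validated here).
- ESRI ASCII grids and GeoJSON are the only raster/vector formats; no CRS
  handling beyond requiring a shared projected system in meters.
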