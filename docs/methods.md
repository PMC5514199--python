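# Methods

`landfrag` analyses time series of categorical land-cover rasters with three
substantive classes — mature forest (MF), non-forest (NF) and secondary
forest (SF) — as they occur in Landsat-style classifications of Amazonian
colonisation frontiers. This note documents the models, conventions and
numerical choices; everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`, not asserted from memory.

## Raster model and conventions

A landscape is a 2-D integer grid with a cell size in metres (default 30 m, a
Landsat pixel) and a nodata code. Zones (e.g. inside vs outside a
conservation unit, CU) are boolean masks that partition the non-nodata cells;
a zone is analysed as its own landscape by setting everything outside it to
nodata, which clips patches at the zone boundary.

Two neighbourhood rules coexist, both config-exposed:

* **Patch delineation** uses queen (8-neighbour) connectivity: two cells of
  the same class touching even at a corner belong to one patch.
* **Adjacency counting** for the clumpiness index uses rook (4-neighbour)
  cell sides with the double-count convention: each internal like-class side
  contributes 2 to `g_ii`, each unlike side contributes 1 to `g_ik` and 1 to
  `g_ki`. Sides facing nodata or the grid boundary are never tallied.

The grid boundary and nodata are treated as "outside the landscape": they
count toward a patch's *perimeter* (a patch at the map edge is still closed)
but not toward *edge density* and not toward adjacencies. This matches the
common no-border default of raster fragmentation tools; a
`count_boundary_edge` flag flips the edge-density behaviour for workflows
that supply a landscape border. Because the upstream convention for border
handling in any particular study is rarely documented, this default is a
documented choice, not a reproduction claim.

## Class-level metrics

For class i with patches j of area `a_j` (ha) and perimeter `p_j` (m):

* **ED** (m/ha) = (total length of sides between class i and a *different
  substantive class*) / landscape area. An A|B side counts toward both ED(A)
  and ED(B) — class-level semantics.
* **Minimum perimeter rule.** The smallest perimeter a raster patch of z
  cells can have is `4n` sides if `n^2 = z` (n = floor(sqrt z)), `4n + 2` if
  `z <= n(n+1)`, else `4n + 4`; equivalently `2*ceil(2*sqrt(z))`. The tests
  confirm the rule by exhaustive enumeration of all 8-cell polyominoes.
* **SHAPE** of a patch = `p_j / (min_p(z_j) * cell_size)`; 1 for a square,
  larger for irregular shapes. **SHAPE_AM** = sum_j SHAPE_j * a_j / sum_j a_j.
* **AREA_AM** (ha) = sum_j a_j^2 / sum_j a_j, the area-weighted mean patch
  size; it always lies between the smallest and largest patch.
* **CLUMPY.** With `G_i = g_ii / (sum_k g_ik - min_e_i)` (min_e_i the
  minimum-perimeter side count for the whole class area; if the denominator
  is not positive the uncorrected ratio is used), CLUMPY =
  `(G_i - P_i)/P_i` when `G_i < P_i` and `P_i < 0.5`, else
  `(G_i - P_i)/(1 - P_i)`, clamped to [-1, 1]. P_i is the class's share of
  non-nodata area. A perfect checkerboard scores exactly -1; i.i.d. random
  placement averages ~0 (the min_e correction removes the small upward bias
  of the raw like-adjacency ratio); a solid block approaches +1.

Undefined metrics (class absent; single-class landscape, P_i = 1) are
reported as missing values, never imputed as zero — downstream trend fits
simply skip missing years, which the observed series require anyway because
of image gaps.

Scale behaviour (tested): doubling the cell size leaves CLUMPY and SHAPE_AM
unchanged, multiplies patch areas by 4 and halves ED.

## Transitions and the relative incidence of deforestation

Deforestation is the MF -> NF transition between two consecutive maps,
cross-tabulated per zone. Direct MF -> SF transitions violate the succession
rule (secondary forest must be preceded by non-forest) and are therefore
reported in a separate QC column, excluded from the deforested area D by
default; an `include_sf_clearing` switch additionally counts SF -> NF as
clearing for sensitivity analyses. D is per interval, not annualised, by
default (an `annualize` flag divides the reported area by the interval
length; the incidence ratio itself is scale-free and unaffected).

For zone class i with deforested area `D_i` and area `A_i`:

    RID_i = (D_i / D_total) / (A_i / A_total)

RID is undefined when `D_total = 0`, zero when only other zones were
cleared, 1 when clearing is proportional to area. Two algebraic identities
hold on every computed interval and are asserted in the tests: the
area-weighted mean `sum_i (A_i/A_total) RID_i = 1`, and invariance of RID to
cell size. Zone stratifications supported are binary inside/outside and any
multi-zone partition (e.g. federal/state/county CU categories), since a zone
set is just a partition of the grid.

## Trend tests with ARMA errors

Each series (metric or RID per zone/class) is regressed on calendar year.
The error process is stationary ARMA(p, q) on the annual lattice; years
missing from a series enter through the lattice autocovariance — the
covariance matrix of the observed years is the corresponding submatrix, which
is exactly the marginal Gaussian likelihood a state-space evaluation with
missing observations would give, so 1–4 year gaps preserve their lag
semantics.

1. **Order selection** (`select_error_structure`): grid search over
   p, q <= 2 on the OLS residuals, exact Gaussian ML per candidate, choose
   the smallest AICc (k = p + q + 1); ties prefer smaller p + q, then
   smaller p. Series with fewer than 8 observations are forced to (0, 0).
2. **Fit** (`fit_trend`): restricted maximum likelihood (REML) for the
   ARMA correlation parameters (unconstrained optimisation through the
   partial-autocorrelation transform, Nelder–Mead), profiling the scale;
   GLS for slope and intercept. Years are centred internally for
   conditioning; the slope is invariant to centring.
3. **Inference**: the slope test uses the Kenward–Roger small-sample
   adjustment — the slope variance is inflated for the uncertainty of the
   estimated covariance parameters (expected REML information), and the
   statistic is referred to a t distribution with Satterthwaite degrees of
   freedom, capped at n - 2. With order (0, 0) the whole procedure reduces
   *exactly* to the OLS t-test, which the tests verify in closed form.

The adjustment matters: with an estimated AR(1) correlation at n = 27 a
naive z-test on the GLS slope rejects a true null far above the nominal 5%;
the Kenward–Roger test is calibrated (the acceptance suite measures the
empirical size over 500 replicates at phi = 0.6 and checks it lies in
[2%, 9%], and that the mean slope estimate under slope 0.3 is within 0.05).
At least 5 observations are required for any fit. Non-convergence of the
REML search is reported via a warning and a `converged` flag, never
swallowed. No multiple-testing correction is applied by default (each
regression is reported on its own); a flag adds Benjamini–Hochberg across a
table. The default significance threshold for summary columns is 0.05.
Degenerate series (numerically exact fit: constant series or a perfect
line) short-circuit to p = 1 or p = 0 respectively rather than dividing
round-off by round-off.

## Synthetic landscape generator

The generator emulates the qualitative dynamics the analysis is designed to
detect, so directional claims can be tested against a known construction:

* **Initial state**: mature forest everywhere except road cells (non-forest).
  Roads are polylines rasterised by Bresenham segments; `fishbone_roads`
  builds the planned-settlement geometry of one spine with perpendicular
  ribs at fixed spacing.
* **Clearing**: each year a fixed budget of MF cells converts to NF in
  compact plots (default 6 cells each) — anthropogenic clearings are regular
  pasture/cropland blocks, which is exactly the contrast with irregular fire
  scars the shape metrics are designed to detect. Plot seeds are sampled
  with weight
  `contagion * 1[adjacent to NF] + (1 - contagion) * exp(-d_road / scale)`,
  multiplied by a protection factor in [0, 1] inside the CU mask, and each
  plot grows by maximally compact accretion around its seed. The road
  kernel uses Chebyshev distance (scale default 8 cells) — the simplest
  monotone stand-in for road-driven colonisation. Protection factor 0 makes
  the CU inviolate: plots can neither seed nor grow into it (a hard
  constraint, tested). If fewer eligible cells exist than the budget, the
  available cells are cleared; a wildfire larger than the remaining forest
  is an error.
* **Wildfire**: a scheduled (year, size, irregularity) event grows a
  connected scar from a random forest seed by biased random accretion:
  frontier cells compete with weight `u * exp(lambda * compactness)`, with
  compactness the fraction of rook neighbours already burning, u uniform
  noise and `lambda = 4 (1 - 2 * irregularity)`. Irregularity 0 fills
  concavities first (near-disc), 0.5 is unbiased Eden growth, 1 prefers
  low-contact cells and branches dendritically — standalone scar shape
  indices rise monotonically from about 1.5 to about 4 across that range.
  A fire whose connected fuel runs out "spots" to a fresh ignition point,
  so the scheduled size is always burned.
* **Regrowth and re-clearing**: NF left fallow for at least `min_fallow`
  complete years (>= 1, so regrowth can never occur in the clearing step
  itself) becomes SF with an annual probability; SF is re-cleared to NF at a
  smaller annual rate; road cells never regrow. SF can therefore only ever
  appear after NF — the succession-legality invariant is checked exhaustively
  on generated series.
* **Gaps**: listed gap years are simulated but omitted from the output, so
  output series have the 1–4 year holes the trend machinery must handle.

Defaults are 30 m cells and annual steps 1984–2011. Three presets span the
contrast between an isolated low-pressure landscape, spontaneous
colonisation with two large wildfire years (1993 and 1998), and a fishbone
settlement with heavy contagious clearing; preset budgets and fire sizes
scale with grid area so the presets behave consistently at test sizes.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: classification error and cloud-gap artefacts,
georeferencing jitter between years, real road-network growth, economically
driven (rather than stochastic) clearing decisions, and calibration to real
deforestation rates. Directional pipeline tests (protection lowers RID
inside CUs; fire years spike NF edge density and shape; higher contagion
raises NF clumpiness) are claims about the method's sensitivity, not about
any real landscape.

## Problem sizes and numerical choices

Test and validation workloads are sized for interactive runs: exhaustive
oracle comparison on all 65,536 two-class 4x4 grids plus 1,000 random
three-class 10x10 grids; CLUMPY randomness on 200 landscapes of 100x100;
trend calibration with 500 Monte Carlo replicates at n = 27; directional
synthetic checks on 40x40 grids over 20 seeds. Floating-point comparisons in
tests use 1e-9 relative tolerance; the CLUMPY clamp and the min-perimeter
denominator guard handle the tiny-class corner cases where the adjacency
convention is otherwise ill-defined. All stochastic draws in the generator
come from a single seeded `numpy` Generator recorded in run metadata, and
pipeline runs are byte-identical under a fixed config.

## Known limitations

* GeoTIFF georeference is carried as opaque metadata (cell size, origin,
  CRS string), not interpreted; reprojection and resampling are out of
  scope, and inputs of one site must already share grid and extent.
* Vector zones are rasterised by cell-centre containment only.
* Landscape-level (as opposed to class-level) metrics and the wider metric
  families of fragmentation tools are deliberately not implemented.
* The ARMA order search is limited to p, q <= 2, mirroring the short
  (n <= 28) annual series the method targets; longer series may warrant a
  wider search.
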