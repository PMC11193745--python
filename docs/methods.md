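# Methods

## Raster model and conventions

All grids are north-up with square pixels in an equal-area projected CRS,
identified by an opaque `crs_tag`; two grids interoperate only if every
geometry field matches. The library performs no reprojection — harmonizing
heterogeneous products to a shared equal-area CRS is delegated to external
GIS tooling, which keeps the core deterministic and dependency-light. A
point (x, y) maps to `col = floor((x − origin_x)/pixel_size)`,
`row = floor((origin_y − y)/pixel_size)`, with half-open pixels
`[edge, edge + size)`: every point belongs to exactly one pixel, so sample
lookups are unambiguous. GeoTIFF I/O is implemented on `tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA,
GeoAsciiParams for the CRS tag); rasters carrying rotation or shear terms in
a ModelTransformation tag are rejected rather than silently north-upped.
The reserved nodata code is 255, conventional for uint8 rasters and outside
the {0, 1} legend.

Under an equal-area CRS a pixel covers `pixel_size²` m², so areas are pixel
counts times pixel area; all areas are reported in 10⁴ ha (a 30 m pixel is
0.09 ha).

**Temporal majority ties.** When compositing a multi-date stack, a cell with
as many cropland as non-cropland observations defaults to cropland,
mirroring the convention of multi-year cropland products that map a cell as
cropland if a growing crop is detected in any epoch. The rule is a single
documented constant (`tie_value`) and can be flipped.

## Vote map and nodata policies

The vote map counts, per pixel, the products labeling it cropland. Two
policies govern missing observations:

- `zero-vote` (default): a product's nodata contributes no vote; a cell is
  flagged nodata only when *all* products are nodata there. This treats an
  unobserved product as "did not detect cropland" while still
  distinguishing completely unobserved cells from unanimous non-cropland.
- `propagate`: a cell nodata in *any* product is flagged nodata — the
  conservative intersection-of-coverage reading.

The two readings are the only pair that makes the policies distinct; the
default mirrors the vote-map convention of labeling never-detected pixels
zero. Conservation (Σ votes = Σ per-product cropland counts) holds exactly
under `zero-vote`.

## Threshold semantics and selection

Threshold maps use the cumulative reading `vote ≥ t`, not `vote = t`: only
the cumulative reading makes the candidate family nested and the mapped-area
column monotonically decreasing in t, which is what published per-threshold
sweeps exhibit. Nestedness in turn forces producer's accuracy to be
non-increasing in t for any fixed sample — a free structural check.

The selection principle "highest F1, lowest census bias" is not a total
order, so it is formalized as three rules:

- `f1-max`: argmax F1; exact ties broken by smaller |bias|;
- `f1-then-bias` (default, ε = 0): among rows with F1 within ε of the
  maximum, smallest |bias|. With ε = 0 this is argmax-F1 with bias as
  tiebreak, which reproduces the published choice of threshold 5 on the
  published F1 column; ε > 0 exposes the genuinely dual-criterion reading.
- `bias-then-f1`: the symmetric rule, for census-anchored workflows.

Census bias is signed mapped − census (positive = overestimation). The
census total is always an input, never hard-coded.

## Accuracy estimation

Raw metrics follow the standard binary-classification formulas (README).
Degenerate conventions keep sweeps total at the extremes: PA (UA) is 0 with
no reference (mapped) positives, F1 is 0 when PA + UA = 0, MCC is 0 when any
confusion-matrix marginal is zero. Reports round to 3 decimals; internal
computation is at full double precision.

Samples falling outside a map's extent or on nodata cells are dropped with
logged counts — auditable rather than silent cleaning.

**Design-based adjustment.** When the sample is stratified, raw counts are
re-weighted by stratum area proportions W_i (the stratified "error matrix in
area proportions" estimators): adjusted OA is the diagonal sum of
p̂_mr = Σᵢ Wᵢ n_i,mr/nᵢ, adjusted UA/PA are its row/column normalizations,
and the class-area proportion p̂_·r carries the stratified SE given in the
README with 95% CIs at ±1.96 SE. Strata default to the assessed map's own
classes (weights = class area shares); any stratum raster (e.g. vote bins)
with explicit weights is supported. Each stratum needs n ≥ 2 for the SE.
The equal-weight design W_i = n_i/n reduces adjusted OA to raw OA exactly,
and simulation shows nominal CI coverage (0.93–0.97 across seeds at n = 800
redraws from a 256×256 scene).

## Sampling

Stratified draws use one stratum per distinct vote value — the finest
faithful reading of "strata from the consistency map" — optionally
restricted to the maximum cropland extent (vote ≥ 1). Quotas come from
proportional, equal or custom allocation with largest-remainder rounding,
floored at a configurable per-stratum minimum; cells are drawn uniformly
without replacement and points sit at pixel centers (unambiguous labels,
exact reproducibility under a seed).

Pool merging dedups points within a tolerance (default: half a pixel),
keeping the first point in the configured pool order — a documented
source-priority rule where archives may overlap. Ingest accepts CSV with a
configurable label-value map (e.g. archives coding cropland as 10).

## Synthetic scenes

The generator emulates the study's data structure, not any specific
product's error geography:

- **Truth**: seeded Gaussian noise smoothed with a Gaussian kernel
  (σ = correlation length, pixels; wraparound boundaries) and thresholded at
  the empirical quantile of the target cropland fraction. Short correlation
  lengths mimic fragmented parcels; σ = 0 gives an i.i.d. field. The
  realized fraction is exact to grid resolution (within half a percentage
  point at 512²).
- **Products**: class-conditional corruption of the truth — omission flips
  1→0 at rate o, commission flips 0→1 at rate c, independent across
  products, so expected PA against truth is 1 − o. Optionally flips are
  drawn by thresholding a smoothed field at the class-conditional quantile,
  giving spatially clumped errors at the same marginal rates.
- **Zones**: a near-square rectangular-block partition (contiguous,
  equal-area for square counts), with block rows doubling as a coarser
  "province" level.
- **Census**: truth zonal areas, optionally times (1 + ε), ε ~ N(0, sd)
  per zone (default sd = 0, so the census is an exact functional of truth).

Defaults are the study conditions: ten products on a 30 m grid, omission
0.2 / commission 0.1, 30% cropland, correlation length 3 px. One master
seed spawns independent substreams (truth, each product, census noise) via
`numpy.random.SeedSequence`, so scenes are byte-reproducible and components
can be varied independently.

What passing synthetic tests does *not* show: real products' errors are
spatially structured by terrain and correlated *across* products (shared
sensors, training data and methods), reference samples carry interpretation
error, and census statistics have their own biases. The synthetic studies
validate the estimators and the machinery under the stated error model, not
the real-world accuracy of any particular fused product.

## Problem sizes and numerics

The parameter-recovery study uses 20 replicate 512×512 scenes with K = 10
and n = 2000 stratified samples per scene — large enough that the majority
threshold's binomial error cancellation is unambiguous (mean refined F1
≈ 0.995 vs ≈ 0.79 per input map) while the whole study runs in seconds.
Coverage simulation uses 500 redraws of n = 800 from a fixed 256×256 scene.
Quantile thresholds use NumPy's default (linear-interpolation) empirical
quantile; metric computations route products of large counts through floats
to avoid int64 overflow; CSV outputs use `%.10g`, enough to round-trip the
reported quantities.

## Known limitations

- No reprojection, no polygon overlays: zones must be rasterized upstream;
  shapefile I/O is out of scope (CSV is canonical).
- Binary legend only — no multi-class error matrices or fuzzy agreement.
- One global consensus threshold; per-region threshold selection is out of
  scope.
- The spatial-error model is a single correlation length per product, not a
  terrain-driven error field.
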