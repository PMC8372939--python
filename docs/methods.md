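# Methods

## Model

Each coarse land unit aggregates `factor × factor` fine land-cover pixels
(default factor 12: 180 arc-second units over 15 arc-second pixels, so a
full unit holds N = 144 pixels).  Units with at least one pixel of an
agricultural-selection class (cropland 11, paddy 12, cropland/vegetation
mosaic 13 in the packaged 20-class legend) receive

- `SDI = 1 − Σ (nᵢ/N)²` — Simpson diversity over all class counts,
- `P = (Σ natural nᵢ)/(N − 1)` — the natural proportion, where "natural"
  excludes urban (18) and strict agriculture (11, 12) but *not* the mosaic
  class 13, and
- `SI = SDI × P`.

The N − 1 denominator makes P span [0, 1] exactly when the unit's
agricultural content is at least one strict-agriculture pixel.  All other
units, and units with fewer than two valid pixels, are undefined (NaN).

### Numerical and boundary choices

- **P clipping.** A unit whose only "agricultural" pixels are of the mosaic
  class 13 has raw P = N/(N−1) > 1, because class 13 both selects the unit
  and counts as natural.  We clip P at 1 (the index's intended range); the
  raw value is retained in the `p_raw` diagnostic column and clipping
  events are counted and logged.
- **Partial units.** Edge units and units with nodata pixels (ocean,
  missing tiles) use their own valid-pixel count as N in both formulas
  rather than assuming 144.  This keeps coastal units unbiased at the cost
  of a slightly noisier denominator.
- **Grid registration.** The coarse grid is anchored at the fine raster's
  top-left corner — deterministic and resampling-free.  Point containment
  uses half-open cells `[west, east) × (south, north]`; a point exactly on
  a boundary belongs to the cell to its south-east.
- **Thresholding.** SEPL candidacy is `SI ≥ threshold` (inclusive).  The
  threshold is a linear-interpolation percentile (default 50th) of a
  per-site statistic over reference sites.  The statistic defaults to the
  per-site **maximum** because maxima, not medians, are what discriminate
  known sites from random ones: documented site boundaries typically wrap
  extensive non-SEPL area, which deflates medians but leaves the best land
  units visible in the maximum.
- **Theoretical ceiling.** `theoretical_max_si(k, a, N)` evaluates the
  continuous closed form `[1 − a² − (1−a)²/(k−1)] · min(1, (1−a)·N/(N−1))`
  attained when the non-agricultural fraction is split equally over k − 1
  classes, with urban not discounted.  An integer-enumeration oracle in the
  tests confirms it dominates every discrete allocation (the discretization
  gap is at most ~1/N).  A corollary checked by brute force: with one
  cropland pixel in a full unit, at least five cover classes at near-equal
  shares are needed to reach SI ≥ 0.70, so high scores require genuinely
  rich mosaics with low agricultural fractions.

## Validation design

Polygon sites take as members the land units whose centers fall inside the
polygon (boundary inclusive) — the same center rule used for
protected-area membership, applied consistently.  Point sites take the
3 × 3 block of units centered on the unit containing the point ("nine
neighbors"), truncated at grid edges.  A site is evaluable when at least
one member has a defined score; non-evaluable sites are reported but
excluded from tests.

Random null sites are nine-neighbor clusters centered on land-unit centers
drawn uniformly over eligible cells within a latitude band (default 60° S
to 75° N).  The draw is cell-uniform, not cosine-latitude area-weighted,
and clusters may overlap each other or the treatment sites; both
simplifications are deliberate (determinism, independence of draws) and
are limitations for strongly non-uniform masks.

The comparison is a one-sided Wilcoxon rank-sum (Mann–Whitney) test of the
per-site medians and maxima, alternative "sites exceed random".  W is the
pair count `#{tᵢ > rⱼ} + ½·ties`.  The p-value is exact by enumeration when
both samples are tie-free and `n_t·n_r ≤ 10 000`, otherwise a normal
approximation with tie and continuity corrections — the same switching
rule as R's `wilcox.test`, which the implementation matches to printed
precision in the tests.  No multiple-testing correction is applied across
groups; rows are flagged at α = 0.05.

## Synthetic data

The generator emulates the *structure* of a global categorical land-cover
product at desk scale, not its content:

- **Mosaic.** Seeded Voronoi cells (default mean patch ≈ 24 pixels, i.e.
  several patches per land unit) assigned whole-patch classes.  Voronoi
  patches give the raster spatial autocorrelation at a controllable scale;
  per-pixel noise would make every unit near-maximally diverse and destroy
  all between-unit contrast, which is the very signal the index measures.
- **Agricultural fraction** (default 0.3, a mid-range agricultural
  landscape) is enforced by assigning whole patches greedily until the
  realized pixel share is within ±0.05 of the target, preserving patch
  geometry.
- **Heterogeneity contrast δ.** Background patches draw from a pool of
  `background_richness` natural classes (default 2); patches whose seed
  lies in a declared SEPL zone draw from a pool `δ` classes richer.  δ = 0
  makes zones statistically identical to background — the null for type-I
  calibration; δ ≥ 3 produces zone units with visibly higher class
  richness and SI.
- **Sites and layers.** Known-SEPL sites are placed uniformly inside the
  zones (point or rectangular-polygon form); decoys uniformly anywhere.
  Conservation layers are random rectangles added until a probe-lattice
  coverage estimate reaches the requested fraction, with KBA rectangles
  centered inside protected-area rectangles at a requested overlap rate.

What the generator does **not** emulate: real class-confusion structure
(e.g. systematic cropland/grassland misclassification), cosine-latitude
cell-area variation, continent-shaped land masks, or multi-date change.
Passing tests therefore demonstrate the pipeline's arithmetic, its
statistical calibration, and its power under a known planted contrast —
not robustness to classification error in real products.

## Problem sizes and defaults

The default synthetic scenario is a 240 × 240-pixel raster (a 20 × 20
land-unit grid at factor 12), 30 treatment sites versus 60–100 random
sites.  The statistical acceptance checks use 1000 pipeline replicates for
type-I calibration (three-sigma binomial band around 0.05) and 150
replicates for power at δ = 3; at these sizes a replicate costs ~35 ms, so
the full suite runs in well under a minute.  These sizes were chosen as
the smallest at which the binomial Monte-Carlo error is comfortably inside
the acceptance bands.

## Known limitations

- The index is computed on whatever legend the raster carries; thematic
  misclassification (notably cropland recorded as grassland) inflates SI,
  a property of the index itself, not of this implementation.
- Random-site draws are cell-uniform rather than area-weighted; at global
  latitudes this slightly over-represents high latitudes.
- Raster I/O is plain-text ASCII grid; very large global rasters would
  need a chunked binary backend, which is out of scope here.
- The rank-sum exact path requires tie-free data; index values from small
  count tables can tie (e.g. many units at SI = 0), in which case the
  tie-corrected normal approximation is used, as in standard practice.
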