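# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the irrimap pipeline.

## Data model and geometry

All layers live on one north-up analysis grid: 0-based row/col
indices, a pixel (r, c) owning the half-open square
`[x0 + c·ps, x0 + (c+1)·ps) × (y0 − (r+1)·ps, y0 − r·ps]` with pixel
size `ps` (nominally 250 m, hence 6.25 ha per cell).  All polygon
membership (zones, aggregation units) uses the pixel-center rule —
simple, unambiguous and consistent across modules.  Reprojection
between coordinate systems is refused rather than attempted silently;
inputs must share a CRS.  `align_to_grid` resamples within that CRS:
categorical layers by area-majority vote (ties to the lowest code,
so results never depend on iteration order), scalars by area-weighted
mean.  How a 56 m land-cover product is best aggregated to 250 m is
not prescribed anywhere authoritative; majority vote is this package's
choice.

A water-year stack keeps composites whose *start* date falls in
June 1 (Y) – May 31 (Y+1); start dates are what 16-day products are
labelled with.  Composites are stacked raw — no temporal smoothing —
since smoothing buys little classification accuracy and can introduce
inconsistencies between years.  Integer NDVI files are rescaled by
0.0001 only when the file declares that scale factor; undeclared
values pass through unchanged.

## Phenology

Emergence is the (earliest) index minimising the cumulative departure
`C_t = Σ_{s≤t}(x_s − mean(x))`; senescence is defined here as the
earliest post-emergence index maximising `C_t` — the point where the
profile falls back through its mean, the natural dual of the emergence
rule, which is the only endpoint rule stated for the original method.
Constant profiles carry no seasonal signal and are rejected.  Nodata
runs up to 3 composites are linearly interpolated before phenology;
longer runs disqualify a pixel as a training sample (48+ days without
an observation spans a whole crop stage).

Seasonal windows default to the standard Indian cropping seasons
expressed as composite indices of the June–May year: Kharif/FS 0–9
(≈ Jun–Oct), Rabi/SS 10–18 (≈ Nov–Mar), Zaid/IS 19–22 (≈ Apr–May),
CMS the whole year; all configurable per run.  A window is considered
to hold a season when its NDVI swing is at least `min_amplitude`
(default 0.1, roughly five times the per-composite noise of a clean
250 m NDVI product) — this keeps off-season noise from minting
spurious descriptors.

The "height" descriptor maps peak NDVI linearly from the attainable
cropped range [0.1, 0.8] onto [1, 100], clamped at the endpoints.
Lookup-table matching walks entries in explicit priority order
(the hierarchical assignment) and takes the first entry whose season
pool, duration range, height interval and sowing window all admit a
descriptor; ties are therefore impossible by construction.  The
lookup values shipped by the scene generator are synthetic defaults
consistent with its own crops, not an authoritative agronomic table —
real deployments must supply their zone's table (TSV schema documented
in `phenology.py`).

Training pixels sit on a deterministic lattice, one candidate every
`round(spacing / pixel_size)` cells (16 for 4 km at 250 m), offset to
the lattice center and intersected with the mask.  On scenes much
smaller than a real agroecological zone the lattice can be densified
via `sample_spacing_m`.

## SCM classification

The SCM score is the Pearson correlation of the two temporal vectors.
Stated ranges (−1 to 1) and the exclusion of negative correlation are
reconciled as: the score keeps its full range, but assignment never
happens on a non-positive best score.  A configurable floor
(`min_scm`, default 0.5) additionally rejects weak matches; no
authoritative value exists for this floor, and 0.5 marks the point
where a profile shares less than half its variance structure with the
best signature.  Signatures are per-zone means of at least
`min_members` (default 3) training profiles; cross-zone classification
is refused.  Ties in the argmax resolve to the lowest class id.

## Irrigation thresholds

The MVCI equations operate on pool maxima of peak NDVI within a crop
class.  Two readings required a decision:

* **MVCI as a fraction.**  The index is applied as a fraction in
  `NDVI_irclass = NDVI_mp·(1 + MVCI)`; multiplying by 100 merely
  re-expresses it as a percentage for reporting.  A percentage in the
  threshold equation would drive NDVI_irclass far outside [−1, 1].
* **What a "seasonal pool" is.**  Pools are implemented as
  rank-quantile subpopulations (default 4) of the class members' peak
  NDVI within a season window.  With pools taken instead as calendar
  windows, a single-season class has identical pool maxima, MVCI = 0,
  NDVI_irclass equal to the class maximum — and the 0.15 separation
  clause could never fire, labelling nothing irrigated.  Subpopulation
  pools ("spectral subclasses" of a crop) make NDVI_mp track the
  rainfed end of the class's amplitude distribution, which is what
  gives the threshold its discriminating power; the quantile split is
  deterministic and reproduces the canonical three-pool worked case
  (maxima {0.6, 0.8, 0.7} → MVCI −0.142857, threshold 0.514286) on a
  half-irrigated class.

The decision rule for a classified pixel with seasonal peak *v*:
irrigated iff `v ≥ max(NDVI_irclass, min_irclass)` and
`v − NDVI_mp ≥ min_separation`, evaluated in every season window where
the pixel shows a detected season (a pixel irrigated in any season is
fully irrigated — binary product semantics).  Defaults
`min_irclass = 0.2` and `min_separation = 0.15` are the method's
stated constants; both are config keys.  The separation clause is
evaluated per pixel, since the per-pixel class value is what the
clause compares against NDVI_mp.  Consequences worth knowing:

* A class whose members are all alike (all-irrigated or all-rainfed)
  yields MVCI ≈ 0 and a threshold at the class maximum: nothing is
  labelled irrigated.  The method is inherently *relative* and
  requires both conditions present within a class; where rainfed
  counterparts are absent it under-detects rather than guesses.
* Groups smaller than `min_group` (2) pixels get no statistics and no
  irrigated labels.

The slope mask uses the operative 20% figure (surface irrigation is
described as suitable up to ~8%, but 20% is what is actually masked);
the threshold is configurable.  All cropping-season land-cover codes
count as agriculture for masking; seasonality is handled in phenology.

## Synthetic scenes

The generator emulates exactly the premise the classifier exploits:
double-logistic seasonal NDVI curves (rate 0.6 composites, shape
normalised so the discrete-grid maximum equals the nominal peak), with
irrigated pixels peaking `irrigated_boost` (default 0.2 NDVI) above
rainfed pixels of the same crop, i.i.d. Gaussian noise (default sd
0.02, a clean-composite noise level), ~20% non-agricultural land, ~5%
over-steep terrain, and a 50% irrigated fraction.  Defaults: 64×64
pixels, two crops (a Kharif crop at rainfed peak 0.60 and a Rabi crop
at 0.55), one zone.  RED reflectance is fixed per land state
(irrigated 0.04, rainfed 0.06, forest 0.05, bare 0.25) and NIR solved
from the target NDVI, so `NDVI = (NIR−RED)/(NIR+RED)` holds composite
by composite and irrigated pixels sit greener (higher NIR, lower RED)
in spiral-curve space.  All draws come from one seeded generator in a
fixed order over full-scene arrays, so a (config, seed) pair is
bit-reproducible and threshold parameters never shift the stream.

The drought scenario scales rainfed peaks by (1 − deficit), pins
irrigated peaks at their base value (groundwater-buffered), and leaves
a seeded fraction of cropland unsown — reproducing the reduced net
sown area that drives drought-year declines in mapped irrigation.

What the generator does **not** emulate: cloud gaps and composite
artifacts, mixed pixels at field boundaries, spatially correlated
noise, within-class agronomic variation (sowing spread, cultivar
differences), or NDVI saturation behaviour.  Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under the
method's own assumptions, not accuracy on real imagery.

## Numerical conventions

* Ties everywhere break to the earliest index / lowest code / highest
  priority; every stage is deterministic given its inputs.
* R² is the squared Pearson correlation, identical to the
  OLS-with-intercept coefficient of determination for these paired
  comparisons.
* Standardized anomalies use the sample (n−1) standard deviation
  (configurable in principle; the convention is stated because the
  source of the comparison series rarely states its own).
* Float rasters round-trip GeoTIFF at float32 precision (≤1e-6 for
  NDVI-scale values); integer rasters exactly.  Binary irrigation
  products are uint8 with nodata 255 in the file tags.
* Test and acceptance problem sizes (64×64 scenes, 23 composites, two
  crops) are chosen so a full pipeline run completes in well under a
  second while leaving every class with thousands of member pixels;
  recovery rates are insensitive to scene size beyond ~32×32.

## Known limitations

* The quantile-subpool construction is one defensible reading of an
  under-specified pooling rule; with strongly skewed irrigated
  fractions (≳75% of a class irrigated) the weakest pool itself
  contains irrigated pixels and the threshold drifts upward,
  under-detecting irrigation.
* Humid regions where rainfed crops reach irrigated-level peak NDVI
  violate the separation premise; the method is designed for
  water-limited zones.
* SCM is amplitude-invariant by construction, so crops distinguished
  only by amplitude (not timing/shape) collapse into one class and are
  separated solely by the irrigation stage.
* GeoTIFF support covers the tags this pipeline writes and reads;
  exotic foreign GeoTIFFs (tiled BigTIFF pyramids, non-trivial
  GeoKeys) are outside scope.
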