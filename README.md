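# irrimap

Annual irrigated-area mapping from water-year stacks of 16-day NDVI
composites (nominal 250 m MODIS-style pixels), land-cover and slope
layers — the workflow used to build national 250 m irrigation maps for
India's agroecological zones, packaged as a reusable pipeline with a
synthetic-scene generator for controlled evaluation.

## Who this is for

Hydrologists and agricultural remote-sensing practitioners who need
spatially explicit, census-independent irrigated/rainfed maps: crop
typing comes from temporal NDVI signatures alone, and the irrigation
threshold is derived from within-class NDVI contrast rather than
calibration against survey totals.

## Method

For every water year (June of year *Y* through May of year *Y*+1) the
23 16-day NDVI composites are layer-stacked without smoothing.
Non-agricultural land and slopes above 20% are masked, and each
agroecological zone is processed independently.

**Crop typing.** Per-pixel seasonal descriptors — emergence and
senescence by the cumulative-NDVI-departure rule (emergence at the
minimum of the cumulative departure, senescence at its post-emergence
maximum), season duration, and peak NDVI rescaled to a 1–100 "height"
(NDVI 0.1 → 1, 0.8 → 100) — are matched against a priority-ordered,
zone-specific lookup table to label a ~4 km training lattice.  Each
labelled crop becomes an end-member signature (mean member profile),
and every masked pixel is assigned to the crop maximising the Spectral
Correlation Mapper score — the Pearson correlation between the pixel's
temporal profile and the signature, i.e. the Spectral Angle Mapper
cosine after centering, which unlike SAM distinguishes negative from
positive correlation.

**Irrigation decision tree.** Within each (crop class, season window)
group, members are divided into seasonal pools ordered by peak NDVI;
with pool maxima NDVI_imclass(i), i = 1..n:

    NDVI_mclass  = (1/n) Σ NDVI_imclass(i)
    NDVI_mp      = min_i NDVI_imclass(i)
    MVCI         = (NDVI_mp − NDVI_mclass) / NDVI_mclass        (≤ 0)
    NDVI_irclass = NDVI_mp · (1 + MVCI)

A classified pixel with seasonal peak *v* is labelled irrigated when
`v ≥ max(NDVI_irclass, 0.2)` **and** `v − NDVI_mp ≥ 0.15`.  The output
is a binary GeoTIFF (1 = irrigated) where each 250 m pixel accounts
for 6.25 ha.

Diagnostics include space-time spiral curves (class-mean RED/NIR
trajectories), RMSE/R² validation against survey tables, area
aggregation to polygons, and first-difference / standardized anomaly
series.

## Worked example

Generate a 64×64 synthetic scene (two crops, irrigated peak boost 0.2
NDVI, noise sd 0.02) and run the full pipeline:

```bash
irrimap simulate --out demo --seed 7
irrimap run --config demo/pipeline.yaml
irrimap aggregate --irrigation demo/run/irrigation.tif
```

prints

```
water year: 2000-01
agricultural pixels: 3141
irrigated pixels: 1553
zone 1:
  training: {'candidates': 12, 'gap_rejected': 0, 'unassigned': 0, 'assigned': 12}
  signatures: {'n_members': {'Rice': 4, 'Wheat': 8}, 'dropped': []}
  class_pixels: {'Rice': 1542, 'Wheat': 1599}
  irrigated_pixels: 1553
class thresholds (class, window): n, imclass, mclass, mp, MVCI, irclass
  (1, FS): n=1542 imclass=[0.6126, 0.6512, 0.8096, 0.8658] mclass=0.7348 mp=0.6126 MVCI=-0.1663 irclass=0.5107
  (2, SS): n=1599 imclass=[0.5615, 0.6006, 0.7590, 0.8221] mclass=0.6858 mp=0.5615 MVCI=-0.1812 irclass=0.4597
irrigated pixels: 1553
irrigated area: 9706.25 ha (0.009706 mha)
```

Reading: 12 lattice pixels were phenology-labelled and split 4/8
between the two crops; SCM then classified all 3141 agricultural
pixels.  For the monsoon-season class the weakest seasonal pool peaks
at NDVI 0.6126 (the rainfed end), giving MVCI −0.166 and a threshold
NDVI_irclass 0.5107; pixels clearing both that threshold and the 0.15
separation above 0.6126 — the irrigated half of the scene — cover
9706.25 ha.  Against the generator's ground truth this run recovers
irrigation labels on 100% of masked pixels.

`irrimap validate` (no arguments) scores the packaged state-wise
survey comparison table:

```
DES vs MODIS 250 m: n=32 RMSE=0.83 mha R^2=0.95
DES vs IWMI 250 m: n=32 RMSE=7.98 mha R^2=0.76
```

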