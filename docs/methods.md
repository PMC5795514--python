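# Methods

## Model and procedure

The pipeline classifies a multi-season rice landscape without training
samples by exploiting two temporal contrasts:

* **Backscatter phenology (C-band VH).** A transplanted rice field is
  flooded, so its radar return is specular and low (a trough); as the
  canopy closes, volume scattering raises the return to a seasonal peak;
  it declines again toward maturity. Water and forest/built-up are
  temporally flat (near −24 dB and −10 dB respectively). For each rice
  season, compositing the per-pixel **minimum over the early-growth
  window** and **maximum over the middle-growth window** and stacking
  (min, max, max−min) concentrates the rice signal in the difference band.
  The difference band is invariant to any constant radiometric offset, so
  moderate calibration bias does not affect the rice contrast.
* **Seasonal greenness.** Cropland is bare in winter and green in season;
  evergreen forest is green in both; water is non-vegetated in both. The
  (winter NDVI minimum, growing NDVI maximum, difference) stack separates
  cropland (large difference) from forest (small difference, high
  maximum). The NDVI difference band may legitimately be negative (e.g.
  turbid winter water); no clamp is applied — classification handles it.

Each 3-band product is clustered unsupervised (K-Means) and the clusters
merged into binary layers. The final maps come from a fixed-priority
decision tree: water → forest → rice-gated-on-cropland → other, with
middle rice tested before early rice. The ordering encodes an asymmetric
confusion: around the middle-rice transplanting window early rice is
already near its backscatter peak, so early rice cannot be mistaken for
middle rice; the reverse confusion is possible, and giving middle rice
priority resolves it. Early and late rice coincide on double-cropped
fields, so they are mapped as two products; the double-crop area is their
intersection.

## Preprocessing assumptions

Inputs are assumed analysis-ready: calibrated σ° (linear power or dB) and
surface reflectance, co-registered on a common north-up grid adequate for
equal-area accounting. A strict co-registration check (same shape, same
geotransform within 1e−6) runs before every multi-grid operation. The
radiometry steps are 10·log10(σ°) conversion (σ° ≤ 0 → nodata, keeping the
pipeline total on real products), a 5 × 5 moving-median speckle filter,
and nearest-neighbour resampling to the 30 m analysis grid. Border policy
for the median is reflect padding; nodata pixels are excluded from the
window and preserved in the output. Nearest-neighbour ties (equidistant
source centres) resolve to the smaller row index, then column index —
deterministic and testable.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| median filter window | 5 × 5 | pixels | operational speckle-suppression setting |
| analysis pixel | 30 | m | matches the optical grid |
| early-rice windows | 31 Mar–6 May / 18 May–17 Jul | dates | reported study calendar |
| middle-rice windows | 5 May–15 Jun / 25 Jun–5 Aug | dates | regional crop calendar (config-overridable) |
| late-rice windows | 25 Jun–5 Aug / 15 Aug–30 Sep | dates | regional crop calendar (config-overridable) |
| K-Means k / max_iter | 10 / 20 | — | operational classifier settings |
| assessment sample | 100 | pixels/stratum | stratified by map class |
| CI multiplier | 1.96 | — | approximate 95% normal interval |

Phenology windows are closed intervals (both endpoint acquisitions count).
Middle- and late-rice windows are calendar-derived stand-ins, not reported
values, and should be overridden per region in the config. Missing
acquisitions are tolerated naturally — a window composites whatever dates
fall inside it — and an explicit window-coverage error fires only when a
window contains no acquisition at all.

## K-Means implementation

Lloyd's loop is implemented in-package because the contract pins details a
library call leaves open: k-means++ initialisation with an explicit seed
(runs are bit-reproducible), equidistant points assigned to the
lowest-index centroid, empty clusters re-seeded from the point farthest
from its centroid, and a per-iteration inertia trace asserted
non-increasing. A test cross-checks the final inertia against
scikit-learn's K-Means on separated clusters. The cluster → class merging
the operational workflow did by survey data is exposed as an explicit
mapping argument; for unattended runs a centroid heuristic assigns a
cluster to rice when its difference centroid is above the across-centroid
midpoint **and** its minimum centroid below the midpoint (flooded trough
then canopy peak), and analogously cropland/forest from the NDVI product.
The heuristic is a documented default meant to be overridden where
reference data exist; degenerate cases (single cluster, no difference
contrast) map everything to "other".

## Design-based area estimation

The error matrix uses map categories as sampling strata. The proportion
matrix, adjusted areas, standard errors and intervals follow the
stratified estimator stated in the README. Numerical conventions: kappa is
computed on raw sample counts (as conventional classification reports do),
not area-weighted proportions; undefined accuracies (empty category) are
reported as missing, never 0; a stratum with mapped area but no samples,
or fewer than two samples when a variance is needed, raises an explicit
error. Areas are km² (pixel_size² × 10⁻⁶ per pixel); reports round km² and
percentages to 2 decimals, proportions and SEs to 4 — matching how such
tables are conventionally printed. One published inconsistency is worth
noting: the source study's printed middle-rice proportion (0.0681) does
not reproduce its printed adjusted area (556.21 km² = 9000 × 0.0618); the
implementation follows the estimator equations, and validation uses only
the self-consistent printed pairs.

## Synthetic scenes: what they emulate, and what they do not

The generator draws contiguous class patches (competitive multi-seed
region growth; quotas by largest remainder, so empirical class fractions
match the configured ones to within rounding), then per-pixel, per-date
values as a class profile mean plus Gaussian noise (default 1 dB, matching
the ±1 dB spreads observed for flat covers; 0.05 NDVI units). Backscatter
profiles are piecewise-linear in day-of-year: water −24 dB and
forest/built-up −10 dB flat (the two field-reported anchors), rice troughs
at −20 dB and peaks at −11 dB (generator parameters, not reported values),
with the early-rice trough placed clear of the middle-rice transplanting
window so the asymmetric-confusion structure described above is present in
the data. Double-cropped fields get two trough/peak cycles. Optical pairs
are constructed by inverting the target NDVI at a fixed red+NIR band sum
of 0.4, so the NDVI operation recovers the intended index exactly up to
the injected noise. The auxiliary water layer is the true water mask,
emulating an external water-extent product.

Not emulated: mixed boundary pixels, topographic layover/shadow, real
speckle statistics (multiplicative, spatially correlated), cloud
contamination, within-class phenological spread, and georeferencing error.
Passing end-to-end tests therefore demonstrates that the chain is
implemented correctly and separates the stated temporal signatures — not
that it would reach the same accuracy on real scenes, where boundary
mixing and phenological variance dominate the error budget.

## Validation

* **End-to-end**: on a default 200 × 200 scene the full chain reaches
  ≥ 95% agreement with truth (observed ≈ 99.8%; residual errors sit on
  patch boundaries where the median filter mixes neighbourhoods — the same
  boundary-error structure reported for the real workflow).
* **Estimator unbiasedness and coverage**: 500 simulated populations
  (10 000 pixels, three categories, 90% diagonal confusion, 50 samples per
  stratum) — mean adjusted area within Monte-Carlo error of realised
  truth; 95% CI coverage within 3 points of nominal. Populations are
  simulated as label vectors rather than rasters; spatial arrangement is
  irrelevant to the estimator, and this keeps 500 replicates inside
  seconds.
* **Closed-form SE**: agrees with a stratified bootstrap (multinomial
  resampling within map rows, 4000 draws) within 10% on the worked 2 × 2
  example.
* **Worked arithmetic**: season shares, CI halfwidths and adjusted areas
  recomputed from the published study's printed summaries reproduce its
  printed values at printed precision.

## Known limitations

* The cluster-assignment heuristic assumes each thematic class forms
  centroids on the expected side of the across-centroid midpoints; exotic
  landscapes (no rice at all, or rice-dominated scenes) can defeat it —
  supply an explicit mapping in that case.
* The decision-tree priority is hard-coded (water → forest → middle →
  early), by design; it is not a configuration knob.
* Raster I/O writes plain TIFF with a JSON metadata tag (geotransform,
  units, nodata); CRS handling and reprojection are out of scope — inputs
  must already share an equal-area-adequate grid.
* Eq.-style variance treats samples within a stratum as independent; if
  assessment pixels come from clustered quadrats, the reported SE will be
  optimistic.
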