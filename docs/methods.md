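# Methods

## Data model and conventions

All geometry lives in a projected, metre-unit CRS. Grids are square-celled,
anchored at the top-left outer corner, rows increasing southwards. Every
raster–vector operation samples at **cell centres**: a cell belongs to a
polygon, buffer or distance band iff its centre does. One convention is used
everywhere to prevent half-cell drift between stages. Nodata is a sentinel
value handled by masks only; any operation consuming a nodata cell emits
nodata. GeoTIFF I/O is implemented directly over `tifffile`, writing the
standard georeferencing tags (pixel scale, tiepoint, GDAL nodata) and a JSON
image description carrying band names and the CRS label; vector layers are
GeoJSON handled with `shapely`.

## Synthetic scenes

The generator emulates a ~16 ha smallholder landscape at 0.25 m cells
(512×512 default): a meandering river (sinusoidal centreline, width 4 m,
amplitude 12 m, wavelength 80 m → sinuosity ≈ 1.20), two standing water
bodies with configurable mean red value (70 = clear, 150 = turbid), five
red-roofed rectangular buildings of height 3 m on bare soil, and contiguous
parcels of oil palm (35%), crops (20%), natural vegetation (20%) and bare
soil (15%) assigned on a 16 m tile grid to meet the target fractions within
the tile granularity. Oil palms are stamped as circular crowns (radius
1.75 m) on a 4 m planted grid with strong within-crown NIR modulation
(sd 30 DN) and dome-shaped 9 m crowns in the DSM; natural vegetation gets a
12 m canopy with moderate NIR heterogeneity; crops are low (0.5 m) and
spectrally smooth. Spectra are per-class Gaussians on a 0–255-like digital
number scale, clipped at zero, drawn from a single seeded stream so a fixed
seed reproduces the scene bit for bit.

The spectral means are chosen so that the protocol's default thresholds are
*correct* on the scene: NDVI ≥ 0.3 exactly on vegetation, NDWI ≥ 0 exactly
on water (water green > NIR; soil NIR > green), roof red within the
160–220 building range while soil red is not. The terrain (gentle trend +
sinusoids + one steep knoll) spans all three slope classes of the erosion
criterion. What the generator does **not** emulate: shadows and sun-angle
effects, mixed boundary pixels from photogrammetric blur, radiometric
calibration error, seasonal variation, or georeferencing error. Passing the
end-to-end quality bar on these scenes therefore demonstrates correctness
of the pipeline's logic under the protocol's own assumptions, not expected
accuracy on real imagery, where class separability is far weaker.

## Texture

"Mean Euclidean distance" texture is defined centre-vs-neighbour: for each
cell, the mean over all other window cells of the spectral distance to the
centre (single band → mean absolute difference), window 41×41 on the NIR
band by default, edges replicate-padded. The centre cell is excluded from
the average (its distance is identically zero and would only rescale the
statistic). The statistic is non-negative, invariant to adding a constant
and scales linearly with the band — properties the tests exercise. Near
cover boundaries the window straddles classes, so edge cells of smooth
covers can still score high texture; the vegetation discrimination is
per-segment and unaffected, but analyses of texture per cover should use
patch interiors.

## Segmentation

Multiresolution region merging starts from single-cell segments. The fusion
cost combines colour heterogeneity — growth of the size-weighted per-band
population standard deviation, equal band weights by default — and shape
heterogeneity (compactness: perimeter / √area; smoothness: perimeter /
axis-aligned bounding-box perimeter), mixed by the shape (0.1) and
compactness (0.5) weights; a merge is admissible while the cost is below
scale² (scale 40). Adjacency and perimeter use 4-connectivity.

Merge order is *local mutual best fitting executed in vectorized passes*:
each pass computes all edge costs on the region-adjacency graph, orders
admissible edges by (cost, min id, max id), lets every segment pick its
best neighbour, and merges exactly the pairs that choose each other. Mutual
best pairs form a matching, so a pass is well defined and order-free, and
repeated passes terminate when no admissible mutual pair remains. This
keeps the algorithm deterministic (fixed tie-break, no data-dependent
iteration order) and fast enough to segment a 512×512 scene in a few
seconds in pure numpy, while preserving the invariants a sequential
lowest-cost-first scheduler would give: the labels always form a partition
of 4-connected segments, every executed merge had cost < scale² (each run
keeps a merge log so tests can audit this), segment count decreases by
exactly one per merge, and scale → 0 yields the identity partition.
Segmentation uses the spectral bands only; texture and height enter at the
classification stage. Exact object-for-object parity with commercial OBIA
implementations is out of scope.

Rectangular fit is segment area over the area of its minimum-area rotated
enclosing rectangle, computed by rotating calipers over the convex hull of
the segment's cell corners (so a solid axis-aligned rectangle scores
exactly 1; a disc ≈ π/4).

## Classification

The rule hierarchy evaluates per-segment means in a fixed order —
vegetation (NDVI ≥ 0.3), water (NDWI ≥ 0), building (rectangular fit ≥ 0.8
∧ height above terrain ≥ 2 m ∧ mean red ∈ [160, 220]), residual bare soil —
then hands vegetation segments to a 1-nearest-neighbour classifier in a
feature space of band means, mean texture and mean height, standardized to
zero mean / unit spread over the training set; distance ties resolve to the
lowest legend id. The threshold values are protocol parameters exposed in
configuration, not empirical constants; "elevation" in the building rule is
interpreted as height above terrain (DSM − DTM), which is invariant to the
underlying relief. Training samples default to 30 seeded cells per
vegetation class drawn from ground truth at least one crown radius inside
class regions; with real imagery they would come from manual
interpretation, supplied as a row/col/label table.

Accuracy assessment fixes rows = reference, columns = prediction (user and
producer accuracy swap under transposition, so the orientation is part of
the contract). Validation points are simple random without replacement
(default 45); the end-to-end quality-bar measurements use the full-map
confusion matrix instead, since synthetic truth is exhaustive. Ratios with
a zero marginal are NaN and excluded from summaries.

## Indicators

Scores are 3 = high, 2 = medium, 1 = low sustainability; interval
membership is lower-open/upper-closed on the better side, and every printed
boundary is unit-tested. Design choices where the published protocol is
under-specified:

* **Riparian (river)** — implemented as distance-to-centreline banding
  (20/30/40 m) over non-water cells, with natural vegetation scoring 3
  wherever it stands inside the buffer; the fixed bands are used rather
  than channel-width-scaled ones.
* **Riparian (standing water)** — only the low class is defined by the
  criterion table ("no natural vegetation within 100 m"); natural cover
  inside the buffer is scored 3 so compliant buffers are rewarded.
  Configurable.
* **Water clarity** — per-body mean red over its classified water cells,
  painted body-wide; means outside the calibrated 67.1–179.5 range clamp
  to the nearest class (clearer than the baseline cannot score worse than
  it).
* **Channel sinuosity** — the printed class edges (1.05/1.06, 1.30/1.31)
  leave gaps; continuous half-open intervals are adopted. The score paints
  the channel's river cells (water within half the channel width plus one
  cell of the centreline).
* **Connectivity** — read as distance-band score (3/2/1 at ≤25/25–50/>50 m
  from natural vegetation) multiplied by a land-quality coefficient:
  1 for natural vegetation and water (the criterion assigns 1 to the
  river; standing water is treated the same as aquatic habitat,
  configurable), 0.5 for oil palm and crops, 0 for bare soil and built-up.
  Multiplying the raw distance by the coefficient instead would rank bare
  soil highest, which contradicts the coefficient's meaning; band-score ×
  coefficient also admits the sub-1 farm means a pure 1–3 scale cannot
  produce. Distance is to natural vegetation only, not to the river.

Slope uses Horn's 3×3 method (the default of the GIS toolchain this
protocol targets), edge cells edge-replicated. Distance rasters are exact
Euclidean distance transforms scaled by cell size (centre-to-centre);
distances to vector geometry are exact map distances from cell centres.

## Aggregation and reporting

The composite is the weighted mean of the criterion layers *defined at each
cell*, with weights renormalized over the defined layers — undefined
water-only criteria must not drag terrestrial cells toward low scores. (A
neutral-fill alternative can be expressed through the weights/config.) All
indicators carry equal importance; since the two riparian criteria are
facets of one indicator they carry half a weight each by default. The
composite (range [0, 3]) is reclassified by equal-width quintile breaks
(0.6/1.2/1.8/2.4) into five classes for mapping, and by edges 1.5/2.5 into
a three-class low/medium/high summary — both are reporting conventions
exposed in configuration, as the source protocol does not publish its break
values. Farm reports give per-farm means of each indicator over its defined
cells (NaN = not applicable where the farm lacks the feature), per-farm
composite class percentages, and study-area percentages; every percentage
vector sums to 100 over the defined area.

## Problem sizes and numerical notes

Default scenes are 512×512 cells at 0.25 m. The end-to-end quality-bar
measurement (tests and `scripts/acceptance.py`) uses ten such scenes with
consecutive seeds and the default protocol parameters throughout —
segmentation 40/0.1/0.5, texture 41×41, 30 training samples per vegetation
class — scoring each map against the full ground truth; the whole
measurement runs in about a minute on one CPU. Pipeline-level tests use
quarter-size (256×256) scenes with water bodies repositioned to fit the
smaller extent. Merged-segment variances use the sum/sum-of-squares update
clipped at zero against rounding; the incremental statistics are tested to
agree with direct recomputation. All randomness flows through seeded
`numpy` generators: identical configuration and seed reproduce rasters and
tables byte for byte.

## Known limitations

Real UAV surveys violate the generator's assumptions (shadowing, mixed
pixels, radiometric drift), so the near-perfect synthetic accuracies are an
upper bound, not a forecast; the published protocol's own accuracy on real
imagery was assessed at 45 manually interpreted points. Reprojection,
resampling and photogrammetric processing are out of scope — orthomosaic,
DSM and DTM are taken as co-registered inputs. The weighted linear
combination is compensatory by construction: a high connectivity score can
offset a low erosion score within a cell; non-compensatory aggregation
schemes would need a different operator, for which the configuration keeps
a weights hook.
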