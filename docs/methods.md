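# Methods

`salixmap` re-implements a machine-vision yield-monitoring pipeline for
willow (*Salix* spp.) grown in short-rotation forestry: a stereo RGB-D
camera rides past the row during harvest, and each aligned grayscale +
depth frame pair is turned into a count of stems and a per-stem diameter,
geotagged from a GNSS log into a yield transect. This note records the
model, the parameters that matter, the numerical decisions taken where
the design was open, and what the synthetic benchmark does and does not
show.

## Rig geometry and the threshold plane

The camera (horizontal × vertical FOV 87° × 58°, 1280 × 720, depth scale
1 mm per raw unit) sits 1.22 m from the row, pitched 28.5° above the
ground plane so the frame covers the stem section a few metres above
ground. Because of the pitch, a single depth cutoff cannot separate the
row from the background: the top of the frame looks farther along the row
plane than the bottom. The *threshold plane* is therefore a per-row
cutoff: the bottom image row is pinned at 1.23 m (the row centre along
the bottom ray) and each row above gets the hypotenuse length from the
camera centre to that row's intersection with the vertical plane through
the bottom-row point, with ray elevation running linearly from
`tilt − fov_y/2` to `tilt + fov_y/2`. With the default constants the top
row comes out at ≈ 2.29 m.

Numerical details:

* The bottom ray points 0.5° *below* horizontal with the default
  constants, which makes the raw trigonometric profile dip by < 50 µm
  just above the bottom row. A running maximum from the bottom row upward
  enforces the monotone, physically sensible profile.
* `top_plane_distance` may pin the top value explicitly (the plane then
  interpolates linearly), for compatibility with rigs calibrated to a
  specific top cutoff.
* Depth values are treated as scalar range along the viewing ray; the
  conversion chain makes no ray-vs-perpendicular distinction, consistent
  with treating the raw depth value as a distance.

## Segmentation

Four steps produce the binary stem-candidate mask; every step is
deterministic.

1. **Depth mask.** The raw depth map is median-filtered (5 × 5,
   replicated borders — a median keeps stem edges sharp where a Gaussian
   would blur them, which matters for width measurement). A pixel is
   kept iff its metric depth is strictly below the threshold plane for
   its row and its raw depth is non-zero. Zero encodes "no confident
   stereo match" and is treated as no-information, i.e. masked out.
2. **CLAHE.** Contrast-limited adaptive histogram equalization on the
   grayscale frame: an 8 × 8 *grid* of tiles (160 × 90 px at default
   resolution), per-tile histograms clipped at `clip_limit ×
   tile_area / 256` counts (clip limit 40), excess redistributed
   uniformly with the remainder to the lowest bins, clipped-CDF lookup
   tables, bilinear interpolation between the four nearest tile
   mappings. The tile parameter is interpreted as a grid shape — the
   convention of the reference implementation this pipeline's
   parameters were tuned against — rather than a tile size in pixels;
   an 8 × 8-pixel tiling would put whole tiles inside single stems and
   amplify bark texture into full-range noise.
3. **Dynamic histogram thresholding.** The 256-bin histogram of the
   equalized frame, restricted by default to depth-mask pixels
   (`histogram_scope: masked`; `full` is available since the
   description of the original procedure is ambiguous on this point),
   is min-max normalized to [0, 255]. Stem pixels form a distinct spike
   in this masked histogram. A candidate band of total width
   `peak_range` (default 50) is centred on the maximum bin (lowest
   intensity wins ties), clipped below at `low_limit`; every intensity
   in the band whose normalized count exceeds `max − count_difference`
   enters the intensity list.
4. **Seed points and fixed-range flood fill.** Every depth-masked pixel
   whose equalized intensity is in the list becomes a seed (intensity 0
   never seeds: it encodes removed background). Seeds are flooded in
   row-major order; a seed already covered by the accumulating mask is
   skipped. A flooded seed contributes the connected component (default
   4-connectivity) of pixels within `[seed − lowdiff, seed + updiff]`
   (defaults 10 / 30) — the band always references the original seed's
   intensity, not the neighbour's.

`low_limit` (10) and `count_difference` (200) are package choices with
no published counterpart; both are mandatory config entries so they stay
visible. `count_difference = 200` keeps every bin above ~22 % of the
normalized peak: adaptive equalization spreads the stem population over
several tens of grey levels (more when two stems share a tile), and a
tighter cut keeps only the crown of the spike, leaving parts of stems
without seeds. The background plateau normalizes near zero and stays
excluded.

## Detection

The mask is closed with a solid 15-row × 2-column rectangle (one
iteration) — an upright kernel matching the expected stem shape; the
erosion treats out-of-frame pixels as foreground so regions touching the
frame edge are not eaten. Each 8-connected component becomes a contour
candidate with area defined as the *filled pixel count* (robust for
shapes 1–2 px wide, where a boundary-polygon area would underestimate;
interior holes are filled). Two filters then apply: area ≥ 600 px², and
the filled component must have at least one pixel on the bottom image
row — stems enter the frame from below, they do not float. Survivors
get IDs left-to-right by leftmost bottom-row column. Fragmented
components are deliberately *not* regrouped; a stem split into
sub-threshold fragments is simply missed, which is the pipeline's main
known miss mechanism on hard frames.

## Diameter estimation

The width of a detected tree is read off the bottom row of its filled
contour. The row is trimmed of leading/trailing zeros; if interior gaps
remain, the row decomposes into maximal solid runs and the *widest* run
is taken as the stem (leftmost on ties — the original procedure splits
once at the first interior zero; recursive decomposition into maximal
runs strictly contains that behaviour for ≥ 3 runs). The representative
depth is the median of non-zero raw depths over the chosen span
(even-length medians round to the nearest integer raw unit); a tree
whose span has no valid depth borrows the median depth of the frame's
other trees, and if no tree in the frame has depth, the bottom-plane
distance in raw units is used (a documented extension — the borrow rule
needs at least one donor).

Width and depth convert to millimetres by horizontal-FOV trigonometry:

    distance_mm   = depth_raw × depth_scale × 1000
    half_width_mm = tan(fov_x / 2) × distance_mm
    ratio_mm_px   = half_width_mm / (frame_width / 2)
    diameter_mm   = pixel_width × ratio_mm_px

At the row distance (raw depth 1230) the ratio is ≈ 1.824 mm/px, so
width quantization alone bounds single-stem accuracy at ≈ ±1.8 mm.
Measurements refer to the bottom image row (≈ 1.88 m above ground with
the default mount); no height re-mapping is applied.

## Geotagging and the transect

GGA sentences supply time, position and fix quality (checksummed;
malformed lines are skipped with a warning; quality-0 fixes are dropped
by default); an RMC sentence, when present, anchors the date. Frames
are positioned by linear interpolation between bracketing fixes,
clamped outside the covered interval; a constant camera–GNSS clock
offset is a config entry rather than an inference. The transect is the
per-frame sequence of (position, tree count, diameters) with cumulative
along-row haversine distance, written as CSV and GeoJSON points. Trees
seen in overlapping frames are *not* deduplicated — the transect counts
sightings, a known over-count source.

## Synthetic scenes

The generator renders what the rig sees, with exact ground truth:

* **Stems**: eight per frame by default, full frame height, slightly
  slanted (≤ ~±11 px drift), diameters uniform on [28.57, 60] mm (the
  commercial size classes; below 28.57 mm is mulch), depths uniform on
  1.218–1.229 m — inside the harvested row, in front of the 1.23 m
  bottom cutoff, as the rig geometry requires. Each stem's pixel width
  is the rounded inverse of the mm conversion at its true depth, so a
  perfect pipeline recovers the diameter up to quantization. Bottom-row
  spans are disjoint with ≥ 20 px margins.
* **Branches** (the designated false-positive source): near-vertical
  strips (5–25° off vertical — which is exactly why the detector
  mistakes them for stems), 8–18 mm wide, 0.05–0.20 m closer than the
  row, anchored in inter-stem gaps (a branch in front of a stem merges
  into the stem's silhouette and yields no separate detection), half of
  them reaching the bottom row. A branch that reaches the bottom row
  with ≥ 600 px of area is an *expected* false positive and labelled so
  in the ground truth.
* **Photometry**: stems darker than background (grey 80 vs 170) with
  Gaussian bark texture (σ = 6), optional horizontal illumination
  gradient, and optional glare — additive Gaussian blobs in the upper
  frame that wash out contrast and clip to 255 only at small cores,
  modelling sunlight breaking through the canopy.
* **Depth degradation**: Gaussian noise on raw units and uniform
  dropout to zero.

Three presets name the study conditions. `clean` (all degradation off)
isolates counting and quantization. `paper_like` adds 3 branches/frame,
gradient amplitude 25, glare probability 0.15, depth noise σ = 10 raw
units and 5 % dropout. `stress` pushes every term further and, in its
first frame, zeroes all depth in one stem's lower third to exercise the
diameter fallback (a stem with no depth anywhere would never enter the
depth mask and is structurally undetectable — the fallback presupposes
detection).

What the generator does **not** emulate: perspective foreshortening,
leaf canopy occlusion, motion blur, fragmentation of stems into
disconnected dark regions, and real bark reflectance. Passing the
synthetic benchmark therefore bounds algorithmic correctness (the
operators do what they are defined to do, and degradation behaves
gracefully); it does not predict field accuracy, where low stem/background
contrast is the dominant error source.

## Benchmark sizes and observed behaviour

The test suite and the acceptance script run the full pipeline at native
1280 × 720 on 100 clean frames (800 stems) and 40 degraded frames (320
stems) — sizes chosen to keep a complete run in a few minutes on one
core while leaving counting statistics meaningful. On these suites the
pipeline detects every clean stem with no false positives and
quantization-level diameter RMSE (≲ 2 mm, bound 2 × ratio ≈ 3.65 mm);
under the degraded preset, stem recall stays above 90 %, every false
positive coincides with a ground-truth branch, and diameter RMSE stays
within the 5 mm depth-noise bound. Residual degraded-suite misses are
stem pairs bridged into one contour by a branch — counted as a single
detection, matching the validation rule that clustered stems are not
correctly detected.

## Known limitations

* The dynamic histogram threshold is global per frame: a frame whose
  equalized stem intensities split into disjoint populations (strong
  glare or gradient) can lose the minority population entirely.
* Fixed flood bands (`lowdiff`/`updiff`) do not adapt to frame
  brightness; over-bright backgrounds can connect non-tree pixels to
  stem components and inflate widths.
* Diameter rests on a single image row; a local depth artefact or a gap
  at exactly the bottom row biases the width even when the stem above
  is segmented perfectly.
* The transect counts per-frame sightings, not unique trees.
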