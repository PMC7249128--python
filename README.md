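# salixmap

Stem detection, diameter estimation and yield mapping for willow
(*Salix* spp.) grown in short-rotation forestry, from aligned grayscale +
depth frame pairs.

Willow for biomass is harvested row by row, but no yield monitor exists
for it the way one does for grain or cotton. `salixmap` implements the
machine-vision alternative: a stereo RGB-D camera rides past the row at
harvest speed, and each frame pair is processed into a count of stems
and a per-stem diameter, geotagged from a GNSS log into an along-row
yield transect. It is aimed at precision-agriculture researchers and
growers instrumenting a harvester.

## The pipeline

For each frame pair (8-bit grayscale `I`, 16-bit raw depth `Z`, zero =
no stereo match):

1. **Depth mask** — median-filter `Z` (5×5), then keep pixels in front
   of a *threshold plane*: a per-row cutoff tilted with the camera's
   28.5° pitch, pinned at 1.23 m on the bottom row (the row centre) and
   rising to ≈ 2.29 m at the top. Zero depth is masked out.
2. **CLAHE** — contrast-limited adaptive histogram equalization of `I`
   (clip limit 40, 8×8 tile grid).
3. **Dynamic histogram threshold** — the 256-bin histogram of the
   equalized frame over masked pixels is min-max normalized to [0, 255];
   the stem population forms a spike, and every intensity within
   ±`peak_range`/2 of the peak whose count stays within
   `count_difference` of the maximum enters the intensity list.
4. **Fixed-range flood fill** — every masked pixel carrying a listed
   intensity seeds a flood fill that admits neighbours with intensity in
   `[seed − lowdiff, seed + updiff]` (10/30); the union of components is
   the segmentation.
5. **Detection** — morphological closing (upright 15×2 kernel), external
   contours, then two filters: filled area ≥ 600 px² and presence on the
   bottom image row (stems enter from below; they do not float).
6. **Diameter** — the widest solid run of the contour's bottom row gives
   the pixel width `w`; the median non-zero depth over that span gives
   `Z_i` (missing depth borrows the frame median). Then

       diameter_mm = w · tan(fov_x/2) · (Z_i · depth_scale · 1000) / (W/2)

   ≈ 1.824 mm per pixel at the 1.22 m row distance.
7. **Geotag** — NMEA GGA fixes are interpolated to frame timestamps and
   the per-frame counts/diameters become a transect (CSV + GeoJSON).

Because the original field recordings are not available, the package
ships a first-class synthetic scene generator (`salixmap.synthetic`)
that renders stems, branch clutter, illumination gradients, glare, depth
noise and dropout with exact ground truth, plus an evaluator that scores
detections by bottom-row span overlap.

## Worked example

```python
from salixmap import CameraModel, SceneSpec, generate_scene, process_frame

camera = CameraModel()                       # 87°x58° FOV, 28.5° tilt, 1280x720
frame, truth = generate_scene(SceneSpec(seed=3), camera)
seg, trees = process_frame(frame)
print("seeds:", len(seg.seed_points), "flooded:", seg.seeds_flooded)
for t in trees:
    m = t.measurement
    print(f"tree {t.tree_id}: width {m.pixel_width:.0f} px, "
          f"depth {m.depth_value:.0f}, diameter {m.diameter_mm:.1f} mm")
```

prints

```
seeds: 58245 flooded: 3001
tree 1: width 18 px, depth 1226, diameter 32.7 mm
tree 2: width 20 px, depth 1219, diameter 36.1 mm
tree 3: width 30 px, depth 1222, diameter 54.4 mm
tree 4: width 26 px, depth 1224, diameter 47.2 mm
tree 5: width 17 px, depth 1223, diameter 30.8 mm
tree 6: width 23 px, depth 1224, diameter 41.7 mm
tree 7: width 25 px, depth 1226, diameter 45.4 mm
tree 8: width 19 px, depth 1229, diameter 34.6 mm
```

58 245 pixels matched the dynamically selected intensity band but only
3 001 flood fills actually ran (seeds already inside the growing mask
are skipped). All eight rendered stems are found, IDs running left to
right; the true diameters for this seed are 31.3, 36.0, 53.8, 46.9,
31.5, 42.2, 43.6 and 33.6 mm — every estimate is within the ~±1.8 mm
pixel-quantization limit plus depth jitter.

The same workflow from the shell:

```sh
salixmap synth paper_like -n 10 --seed 0 -o suite/
salixmap run suite/manifest.csv -o out/ --nmea suite/track.nmea
salixmap eval out/detections.csv suite/ground_truth.csv
salixmap default-config        # full parameter file (YAML)
```

`run` writes `detections.csv` (one row per tree: frame, ID, area, bbox,
span, pixel width, depth, diameter in mm) and, with an NMEA log, the
transect CSV/GeoJSON; `eval` reports correctly/falsely detected rates,
undetected count, the branch share of false positives and diameter RMSE
per size-class group.

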