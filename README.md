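# reefwarp

Remove perspective distortion from oblique reefscape photographs by
transforming them into top-down views.

Ecologists quantify coral cover from *photoquadrats* — top-down photographs
of small fixed areas — because a top-down view shows every organism at its
true relative size. The far larger archive of *reefscape* images (oblique
shots with reef in the foreground and water column behind) has been
unusable for such analysis: perspective shrinks distant colonies, so
apparent sizes depend on range. `reefwarp` recovers a quantifiable
top-down view from a single oblique image with unknown camera pose, making
scale-invariant metrics such as percentage cover measurable on reefscape
imagery.

## Method

The core operation is inverse-perspective mapping: a planar scene viewed
obliquely is related to its top-down view by a 3×3 homography

```
        | h1 h2 h3 |                  | x'|       | x |
    H = | h4 h5 h6 | ,      λ · | y'| = H · | y | ,
        | h7 h8 1  |                  | 1 |       | 1 |
```

which is fully determined by four point correspondences. With a known
camera pose (as on autonomous vehicles) the correspondences follow from
geometry; for survey photographs the pose is unknown, so the pipeline
detects the scene's perspective geometry instead, in seven stages:

1. **Calibrate the camera lens** from checkerboard views (done once per
   camera model) and **2. undistort** each image, cropping to the largest
   inscribed rectangle of valid pixels.
3. **Detect the horizon line**: the water column produces almost no edges
   while reef texture produces many, so the horizon is recovered from the
   edge-density demarcation — adaptive-threshold Canny edges, a windowed
   density map, robust suppression of surface clutter via a Theil–Sen
   "water-column line", Otsu binarisation, and a Theil–Sen fit to the
   longest contour.
4. **Remove camera roll** by rotating the image until the horizon is level
   and cropping to the largest inscribed axis-aligned rectangle.
5. **Detect the source plane**: the anisotropy `A = 1 / var(arctan ∇E)` of
   edge orientations falls from high values near the horizon (where
   perspective flattens all edges to near-zero slope) to low values close
   to the camera; the row where the normalised anisotropy curve steepens
   past −1 (the *anisotropy index*) bounds the transformable region.
6. **Detect the perspective grid**: many small Hough segments are filtered
   by angle, side, and slope sign; left×right intersections near the
   horizon vote for the overall vanishing point; the segment passing
   closest to it becomes the scene's *vanishing line*, paired with a
   horizontal line through its midpoint.
7. **Brute-force inverse-perspective mapping**: the bottom destination
   corners are pulled inward by a compression factor `x_cf`
   (`d = x_cf · w`, `C_L = (w/2 − d/2, h)`, `C_R = (w/2 + d/2, h)`) while
   the top corners stay fixed; `x_cf` sweeps downward from 1 and the drawn
   grid is re-measured after each warp. The sweep halts when the grid
   measures 90° — the signature that all vanishing lines have become
   parallel and the view is top-down.

A seeded synthetic-scene generator (pinhole camera over a textured ground
plane with analytic ground truth: horizon, vanishing point, true top-down
homography, marker world coordinates) provides test fixtures and
validation scenes; no external data is needed.

## Worked example

```bash
python examples/transform_scene.py
```

prints, for the reference scene (camera 2 units above the reef plane,
pitch 20°, roll 5°):

```
horizon  : slope +0.0913, intercept 321.7 px (true +0.0875 / 329.1)
plane top: row 423 (anisotropy index)
search   : halted after 176 iterations at grid angle 89.97 deg
x_cf     : 0.125 recovered vs 0.1256 true (error -0.0006)
The grid angle reaching 90 deg means the scene's vanishing lines have
become parallel: distances in the output are proportional to the reef.
```

and writes `scene_oblique.png` / `scene_topdown.png`. The recovered
compression factor within 0.003 of the back-projection value means the
bottom border of the output is compressed to its correct real-world
proportion relative to the top. Other examples cover camera calibration
(`calibrate_camera.py`), the stage-by-stage geometry (`scene_geometry.py`),
transect validation (`transect_validation.py`), and folder batch
processing (`batch_folder.py`).

A thin CLI wraps the batch pipeline:

```bash
reefwarp --input-dir photos/ --output-dir topdown/ --camera-name TG-6 \
         --calib-params-dir calib/ --calib-images-dir boards/
```

## Limitations

The reef must be approximately planar with a visible horizon intersecting
the left image edge; high-turbidity scenes defeat the edge statistics the
pipeline relies on; inputs below 0.75 megapixels are rejected. See
`docs/methods.md` for the model, parameter, and design details.
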