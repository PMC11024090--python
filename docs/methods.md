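# Methods

## Model and assumptions

The scene is modelled as a textured plane (the reef) viewed by a pinhole
camera at unknown height, pitch, roll, and yaw. Under this model the
oblique image and the top-down view of any rectangular sub-region (the
*source plane*) are related by a homography `H` with `h33 = 1`; a point
maps as `λ(x', y', 1)ᵀ = H (x, y, 1)ᵀ` with `λ` the homogeneous divisor.
Pixel coordinates are raster-native: origin top-left, y increasing
downward, so "above the horizon" means smaller y and a vanishing line on
the right half of a levelled scene has positive slope.

Because the pose is unknown, the four destination corners cannot be
derived; instead the pipeline constrains them step by step. After roll
removal the two near corners are symmetric about the vertical midline, so
a single unknown remains: the compression factor `x_cf ∈ (0, 1)` setting
the near-border width `d = x_cf·w`. Its correct value equals the ratio of
the real-world widths spanned by the bottom and top rows of the source
plane, and it is found by brute force: sweep `x_cf` downward, warp, and
measure the angle of a drawn *perspective grid* (the scene's
best vanishing line plus a horizontal line through its midpoint). A
four-point homography that maps the source rectangle onto a destination
trapezoid with the correct width ratio equals the true image-to-ground map
composed with an axis-aligned anisotropic scaling, so at the correct
`x_cf` — and only there — every vanishing line becomes vertical while
horizontal lines stay horizontal: the grid measures exactly 90°.

## Stage parameters (defaults, `reefwarp.config.PipelineConfig`)

| Parameter | Default | Meaning |
|---|---|---|
| `gaussian_sigma` | 2.0 px | blur before gradients |
| `canny_low/high` | 50 / 150 (8-bit) | hysteresis thresholds |
| `adaptive_block`, `adaptive_offset` | 51 px, 3.0 | adaptive mean threshold; a pixel must exceed its local mean by the offset |
| `density_radius_frac` / `min` | 1% of diagonal / 5 px | edge-density window radius |
| `n_water_samples` | 100 | zero-density pixels sampled for the water-column line |
| `zscore_threshold` | 2.5 | single-pass y-outlier cut on the horizon contour |
| `anisotropy_cap` | 1e6 | value at (near-)zero orientation variance |
| `profile_smooth_window` | 5 rows | moving average before differentiating the anisotropy curve |
| `hough_threshold/min_length/line_gap` | 10 / 25 / 3 px | deliberately relaxed segment detection |
| `angle_min_mid/top`, `angle_max` | 10° / 25°, 80° | logical-angle window, interpolated in the horizon intercept between H/3 and 2H/3 |
| `horizon_band_frac`, `vp_width_frac` | 1% H, central 25% W | vanishing-point candidate windows |
| `min_vanishing_line_px` | 500 px | drawn-line length floor |
| `step_x_cf`, `angle_tol_deg` | 0.005, 0.5° | sweep resolution and halt tolerance |
| `grid_thickness`, `grid_color` | 9 px, pure yellow | drawn grid |
| `hue_band`, `sat_min`, `val_min` | ±10 hue units, 0.5, 0.5 | HSV segmentation gates |
| `min_megapixels` | 0.75 | resolution floor |
| `seed` | 0 | all stochastic steps (water sampling, Hough, downsampling) |

## Numerical choices

- **Homography fitting** solves the 8×8 linear system of the four corner
  correspondences directly (`h9` fixed to 1); degenerate configurations
  raise a typed error. Warping inverse-maps each output pixel and samples
  bilinearly with black fill.
- **Theil–Sen** uses the median of all pairwise slopes (equal-x pairs
  excluded) and the median residual intercept; the horizon fit subsamples
  contours beyond 2000 points deterministically.
- **Otsu** thresholds the density map quantised to 256 levels; a constant
  map is defined as all-water. Interior holes of the reef class are filled
  before contour tracing because hole boundaries are never the reef/water
  demarcation and filling leaves the outer contour unchanged.
- **Edge-density radius** is 1% of the image diagonal. The density
  boundary sits roughly half a window radius above the true horizon; at 4:3
  aspect this choice keeps that bias within 1% of the image height, which
  is the accuracy the later stages assume.
- **Anisotropy index.** Edge orientation is the tangent angle
  `arctan(gx / −gy) ∈ (−π/2, π/2]` from Sobel gradients of the blurred
  intensity, so near-horizontal structure maps to values near zero without
  wrap-around. The first contiguous run of rows whose smoothed, normalised
  profile derivative is ≤ −1 is the rapid-information-loss zone. When the
  zone begins below the horizon its first row (the −1 crossing) is the
  index — on a curve like `1 − r²` this is the crossing at `r = 0.5`. When
  the zone abuts the horizon itself (profiles on strongly textured scenes
  are often convex, steepest immediately below the horizon), the crossing
  rule would select the horizon row and re-create the unbounded
  near-horizon plane the procedure exists to exclude; the index is then
  the zone's deepest upper-half row, so the whole loss region is cropped
  away and the source plane is the largest that excludes it. A curve that
  never steepens to −1 falls back to the minimum-derivative row, flagged.
- **Grid-angle measurement.** The drawn grid is segmented in HSV (hue band
  around pure yellow; saturation/value ≥ 0.5 so bilinear blending at
  strong compression does not drop the thinning line), closed 5×5, opened
  3×3 against speckle. Hough segments on the mask boundary are split
  against a fixed near-horizontal reference — valid because the drawn
  horizontal line provably stays horizontal under the destination-corner
  warp family, and safe under the axial ±90° wrap as the vanishing line
  nears vertical (a mean-orientation split is not). Each group's
  orientation is then refined as the principal axis of the mask pixels in
  its band, excluding pixels near the other line so the crossing blob
  cannot drag the axis. Group means use length-weighted axial statistics.
- **The sweep** starts at `1 − step` and measures every iterate. The
  per-iteration warp is restricted to the bounding box of the warped grid
  and rescaled toward a fixed pixel budget; a uniform scaling leaves
  angles unchanged while keeping thinning lines properly sampled (zoom in)
  and bounding cost (zoom out). Inside the 0.5° tolerance window the sweep
  keeps scanning until the closest approach to 90° is clearly passed
  (five non-improving steps) or consecutive iterates bracket 90°, in which
  case the closer iterate is kept; halting at the first iterate inside the
  window would bias `x_cf` high by up to the window width over the local
  angle slope.

## The synthetic-scene generator

`reefwarp.synthetic` renders a ground plane (z = 0) through an exact
pinhole model, so the ground-to-image homography, horizon, vanishing
point, and top-down map are analytic; rendering inverse-maps every pixel's
ray, making the rendered horizon agree with the analytic line by
construction. The texture combines seeded multi-octave value noise,
elliptical colony blobs, depth-band structure, and sparse groove lines
parallel to the camera heading — the synthetic analogue of spur-and-groove
reef structure, which furnishes genuine vanishing lines the way lane
markings do on roads. Two imaging effects are modelled because the
pipeline's statistics depend on them: per-axis incoherent averaging over
each pixel's ground footprint (so unresolved texture near the horizon
renders as dense horizontal micro-streaks, not aliasing noise — the source
of the near-horizon anisotropy plateau), and range fog toward the
deep-water colour (the background darkens with distance, which is what
makes adaptive thresholding hug the horizon). Texture grain scales with
camera height, making scenes invariant under a joint rescaling of altitude
and world lengths; blob density and amplitudes are set so Canny marks
roughly 0.5–2% of below-horizon pixels in standard mode and an order of
magnitude more with adaptive thresholding.

What the fixtures do *not* emulate: three-dimensional relief (every scene
is exactly planar, so the flat-plane assumption is never violated),
caustics and surface-light flicker, turbidity, colour casts, and sensor
noise. Passing tests therefore demonstrate the geometry pipeline is
correct under its own assumptions, not that those assumptions hold for any
particular survey photograph; the resolution floor and the
horizon-composition limits observed on real imagery still apply.

Scene families used by the acceptance suite: compression-factor recovery
uses ten poses spanning pitch 10–35° and roll ±8° at 1600×1200 (the size
at which the fixture statistics are calibrated; the reference scene is
camera height 2, pitch 20°, roll 5°, texture seed 0); horizon recovery
uses twenty poses spanning pitch 10–35° and roll ±10°; transect validation
renders an altitude-16 scene with five fixed-separation marker pairs at
increasing range and a ten-marker, 3-unit-spaced line, measured through
the pipeline's own homography chain.

## Known limitations

- Shallow-pitch scenes (horizon low in the frame) put the anisotropy index
  close to the horizon's half-height bound and drive `x_cf` toward very
  small values where the warp is extreme; the measurement-box zoom keeps
  the search stable there, but accuracy is best in the recommended
  composition regime (horizon in the upper part of the frame).
- The vanishing-point estimate assumes the heading direction's vanishing
  point lies near the image centre (central-quarter window); heavily yawed
  compositions fall outside it.
- One compression factor per image: non-planar reefs violate the model and
  stretch locally after transformation.
- The output raster's scale is relative, not metric; only scale-invariant
  metrics (e.g. percentage cover) transfer directly to real surveys.
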