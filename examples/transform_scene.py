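"""Transform one synthetic reefscape into its top-down view.

Renders an oblique reef scene with known camera pose, runs the full
perspective-removal pipeline, and compares the recovered compression
factor with the value obtained by back-projecting the source plane's rows
onto the ground. Writes the oblique and top-down images next to this file.
"""

import imageio.v3 as iio

from reefwarp.pipeline import transform_reefscape
from reefwarp.synthetic import ScenePose, default_camera, render_reefscape

pose = ScenePose(camera_height=2.0, pitch=20.0, roll=5.0, cam=default_camera())
img, gt = render_reefscape(pose, texture_seed=0)

result = transform_reefscape(img)

W, Hp = result.plane_size
x_true = gt.true_compression_factor(
    result.plane_top_row, result.plane_top_row + Hp, 0, W, result.to_original
)

print(f"horizon  : slope {result.horizon.slope:+.4f}, "
      f"intercept {result.horizon.intercept:.1f} px "
      f"(true {gt.horizon.slope:+.4f} / {gt.horizon.intercept:.1f})")
print(f"plane top: row {result.plane_top_row} (anisotropy index)")
print(f"search   : halted after {result.search.n_iterations} iterations at "
      f"grid angle {result.search.grid_angle_at_stop:.2f} deg")
print(f"x_cf     : {result.search.x_cf:.3f} recovered vs {x_true:.4f} true "
      f"(error {result.search.x_cf - x_true:+.4f})")
print("The grid angle reaching 90 deg means the scene's vanishing lines have")
print("become parallel: distances in the output are proportional to the reef.")

iio.imwrite("scene_oblique.png", img)
iio.imwrite("scene_topdown.png", result.search.transformed.astype("uint8"))
print("wrote scene_oblique.png and scene_topdown.png")
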