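"""Transect-equality validation on synthetic scenes.

The validation protocol mirrors a drone ground-truth experiment: marker
pairs separated by a fixed world distance are placed at increasing range
from the camera, and a line of equally spaced markers runs away from the
camera.  After a correct top-down transform, all pair separations are equal
in pixels (no residual x-compression with range) and the along-range
segments are equal too (uniform y-scale).  The coefficient of variation of
the normalised separations quantifies the residual perspective distortion.
"""

from __future__ import annotations

import numpy as np

from .geometry import apply_homography_array
from .pipeline import PipelineResult
from .synthetic import SceneGroundTruth


def _to_output(points_world: np.ndarray, gt: SceneGroundTruth, result: PipelineResult):
    img_pts = np.array([gt.image_point(x, y) for x, y in points_world])
    return apply_homography_array(result.homography_total, img_pts), img_pts


def transect_separations(
    gt: SceneGroundTruth, result: PipelineResult
) -> dict[str, np.ndarray]:
    """Post-transform marker separations, normalised to the output size.

    Returns ``x_separations`` (one per marker pair, normalised to the
    output width) and ``y_separations`` (consecutive along-range segment
    lengths, normalised to the output height, restricted to markers below
    the anisotropy index where the transform is defined).
    """
    W_out, H_out = result.plane_size
    x_seps = []
    for p1, p2 in gt.marker_pairs_x:
        out, img = _to_output(np.array([p1, p2]), gt, result)
        x_seps.append(np.linalg.norm(out[1] - out[0]) / W_out)

    y_pts = np.asarray(gt.marker_line_y)
    out, img = _to_output(y_pts, gt, result)
    # keep markers on the source plane: below the anisotropy index in the
    # roll-removed frame, where the transform is defined
    lev = apply_homography_array(np.linalg.inv(result.to_original), img)
    keep = lev[:, 1] > result.plane_top_row + 1.0
    out = out[keep]
    y_seps = np.linalg.norm(np.diff(out, axis=0), axis=1) / H_out
    return {
        "x_separations": np.asarray(x_seps),
        "y_separations": y_seps,
    }


def coefficient_of_variation(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(values.std() / values.mean())
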