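"""Camera-roll removal.

Rotating the image about its centre by the opposite of the horizon-line
slope makes the horizon horizontal, which in turn makes the two nearest
destination corners equidistant from the camera and reduces the
inverse-perspective search to the single compression-factor dimension.
The rotation pads the canvas, so the largest inscribed axis-aligned
rectangle is cropped out and the horizon intercept is updated by pushing
the horizon's centre-column point through the same rotation and crop.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import Line, largest_inscribed_rect_after_rotation, warp_image
from .horizon import HorizonLine


def roll_transform(w: int, h: int, slope: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Affine (as 3x3 homography) levelling a horizon of the given slope.

    Maps source pixel coordinates into a resized rotated canvas; returns the
    transform and the canvas (width, height).
    """
    theta = math.atan(slope)
    c, s = math.cos(theta), math.sin(theta)
    # R rotates the horizon direction (1, slope) onto (+x)
    R = np.array([[c, s], [-s, c]])
    centre = np.array([w / 2.0, h / 2.0])
    bb_w = w * abs(c) + h * abs(s)
    bb_h = w * abs(s) + h * abs(c)
    new_centre = np.array([bb_w / 2.0, bb_h / 2.0])
    A = np.eye(3)
    A[:2, :2] = R
    A[:2, 2] = new_centre - R @ centre
    return A, (int(round(bb_w)), int(round(bb_h)))


def remove_roll(
    img: np.ndarray, horizon: HorizonLine
) -> tuple[np.ndarray, HorizonLine, np.ndarray]:
    """Level the horizon; returns (cropped image, new horizon, to_original).

    ``to_original`` is the 3x3 affine mapping coordinates of the returned
    crop back into the input image, for callers that track geometry across
    the pipeline.  A zero-slope horizon passes the image through untouched.
    """
    h, w = img.shape[:2]
    slope = horizon.line.slope
    if slope == 0.0:
        return img, horizon, np.eye(3)
    A, (bb_w, bb_h) = roll_transform(w, h, slope)
    rotated = warp_image(img, A, (bb_w, bb_h))
    theta_deg = math.degrees(math.atan(slope))
    rect = largest_inscribed_rect_after_rotation(w, h, theta_deg)
    # the maximal rectangle is tangent to the rotated footprint; a 2 px
    # guard band keeps bilinear black-blend artefacts outside the crop
    pad = 2
    x0, y0 = int(math.ceil(rect.tl[0])) + pad, int(math.ceil(rect.tl[1])) + pad
    x1, y1 = int(math.floor(rect.br[0])) - pad, int(math.floor(rect.br[1])) - pad
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, bb_w), min(y1, bb_h)
    cropped = rotated[y0:y1, x0:x1]

    # intercept update: rotate the horizon point at the centre column, then
    # subtract the crop offset; the rotated horizon is horizontal
    cx = w / 2.0
    p = np.array([cx, horizon.line.y_at(cx), 1.0])
    p_rot = A @ p
    new_intercept = p_rot[1] / p_rot[2] - y0
    new_horizon = HorizonLine(
        line=Line(0.0, float(new_intercept)), source_mode=horizon.source_mode
    )
    T_crop = np.eye(3)
    T_crop[0, 2], T_crop[1, 2] = -x0, -y0
    to_original = np.linalg.inv(T_crop @ A)
    return cropped, new_horizon, to_original
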