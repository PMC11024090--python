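"""Projective-geometry primitives.

Conventions used throughout the package: pixel coordinates have the origin at
the top-left corner, x increasing rightward (columns) and y increasing
*downward* (rows).  "Above the horizon" therefore means smaller y, and a
vanishing line on the right half of a scene has a numerically positive slope.

A homography is the 3x3 matrix H with h[2, 2] fixed to 1; a point maps as

    lambda * (x', y', 1)^T = H (x, y, 1)^T

with lambda the per-point homogeneous divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    PointAtInfinityError,
    SingularConfigurationError,
    VerticalDataError,
)

Point2D = tuple[float, float]


@dataclass(frozen=True)
class Line:
    """A non-vertical line y = slope * x + intercept in pixel coordinates."""

    slope: float
    intercept: float

    def y_at(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class LineSegment:
    p1: Point2D
    p2: Point2D

    def __post_init__(self):
        if self.p1 == self.p2:
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])

    @property
    def midpoint(self) -> Point2D:
        return ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0)

    @property
    def angle_deg(self) -> float:
        """Orientation in degrees in (-90, 90], y-down convention."""
        dx = self.p2[0] - self.p1[0]
        dy = self.p2[1] - self.p1[1]
        a = math.degrees(math.atan2(dy, dx))
        if a <= -90.0:
            a += 180.0
        elif a > 90.0:
            a -= 180.0
        return a

    @property
    def slope(self) -> float:
        dx = self.p2[0] - self.p1[0]
        if dx == 0.0:
            return math.inf
        return (self.p2[1] - self.p1[1]) / dx


@dataclass(frozen=True)
class Quad:
    """Four corners in clockwise order starting at the top-left."""

    tl: Point2D
    tr: Point2D
    br: Point2D
    bl: Point2D

    @property
    def corners(self) -> list[Point2D]:
        return [self.tl, self.tr, self.br, self.bl]

    @classmethod
    def from_rect(cls, x0: float, y0: float, x1: float, y1: float) -> "Quad":
        return cls((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def fit_homography(src: Quad, dst: Quad) -> np.ndarray:
    """Solve the 4-point correspondence for H with h33 fixed to 1.

    Stacks the eight linear equations in (h1..h8) arising from the four
    corner pairs and solves them directly; raises
    :class:`SingularConfigurationError` when the configuration is degenerate
    (three collinear source corners, repeated corners, ...).
    """
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src.corners, dst.corners)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        b[2 * i] = u
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularConfigurationError(f"degenerate quad correspondence: {exc}")
    H = np.append(h, 1.0).reshape(3, 3)
    if abs(np.linalg.det(H)) < 1e-12:
        raise SingularConfigurationError("fitted homography is singular")
    return H


def apply_homography(H: np.ndarray, p: Point2D) -> Point2D:
    """Map one point, dividing by the homogeneous scale lambda."""
    x, y = p
    w = H[2, 0] * x + H[2, 1] * y + H[2, 2]
    if abs(w) < 1e-12:
        raise PointAtInfinityError(f"point {p} maps to infinity")
    u = (H[0, 0] * x + H[0, 1] * y + H[0, 2]) / w
    v = (H[1, 0] * x + H[1, 1] * y + H[1, 2]) / w
    return (u, v)


def apply_homography_array(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Vectorised point mapping; ``pts`` is (N, 2), returns (N, 2)."""
    pts = np.asarray(pts, dtype=float)
    ones = np.ones((pts.shape[0], 1))
    ph = np.hstack([pts, ones]) @ H.T
    w = ph[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise PointAtInfinityError("some points map to infinity")
    return ph[:, :2] / w[:, None]


def warp_image(
    img: np.ndarray, H: np.ndarray, out_size: tuple[int, int]
) -> np.ndarray:
    """Warp ``img`` by homography ``H`` onto a (width, height) canvas.

    Every output pixel is sampled at its inverse-mapped source location with
    bilinear interpolation; pixels falling outside the source are black.
    """
    if abs(np.linalg.det(H)) < 1e-12:
        raise SingularConfigurationError("cannot warp by a singular homography")
    out_w, out_h = out_size
    Hinv = np.linalg.inv(H)
    xs, ys = np.meshgrid(np.arange(out_w, dtype=float), np.arange(out_h, dtype=float))
    w = Hinv[2, 0] * xs + Hinv[2, 1] * ys + Hinv[2, 2]
    w[np.abs(w) < 1e-12] = np.nan
    sx = (Hinv[0, 0] * xs + Hinv[0, 1] * ys + Hinv[0, 2]) / w
    sy = (Hinv[1, 0] * xs + Hinv[1, 1] * ys + Hinv[1, 2]) / w
    coords = np.stack([sy.ravel(), sx.ravel()])
    coords = np.nan_to_num(coords, nan=-1e6)

    def _sample(channel: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            channel.astype(float), coords, order=1, mode="constant", cval=0.0
        ).reshape(out_h, out_w)

    if img.ndim == 2:
        out = _sample(img)
    else:
        out = np.stack([_sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(img.dtype).max).astype(img.dtype)
    return out


def destination_corners(
    w: float, h: float, x_cf: float
) -> tuple[Point2D, Point2D]:
    """Bottom destination corners for compression factor ``x_cf``.

    The near (bottom) border of the top-down destination trapezoid is inset
    symmetrically so that its width is d = x_cf * w, reflecting the narrower
    real-world footprint of the image rows closest to the camera.
    """
    if not (0.0 < x_cf <= 1.0):
        raise ValueError(f"compression factor must lie in (0, 1], got {x_cf}")
    if w <= 0 or h <= 0:
        raise ValueError("source-plane dimensions must be positive")
    d = x_cf * w
    c_l = (w / 2.0 - d / 2.0, float(h))
    c_r = (w / 2.0 + d / 2.0, float(h))
    return c_l, c_r


def theil_sen_fit(points: Sequence[Point2D]) -> Line:
    """Theil–Sen robust line fit.

    slope = median of the slopes of every unique point pair (pairs with equal
    x excluded); intercept = median of the per-point residual intercepts
    y_i - slope * x_i.  No hyperparameters; breakdown point ~29%.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    x, y = pts[:, 0], pts[:, 1]
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    keep = dx != 0.0
    if not np.any(keep):
        raise VerticalDataError("all x-coordinates identical")
    slopes = (y[j] - y[i])[keep] / dx[keep]
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * x))
    return Line(slope, intercept)


def _max_inscribed_dims(w: float, h: float, theta_deg: float) -> tuple[float, float]:
    """Closed-form largest axis-aligned rectangle inside a w x h rectangle
    rotated by theta, axes of the inscribed rectangle parallel to the
    *rotated frame's* axes."""
    theta = math.radians(abs(theta_deg)) % math.pi
    if theta > math.pi / 2:
        theta = math.pi - theta
    s, c = math.sin(theta), math.cos(theta)
    if s < 1e-12:
        return float(w), float(h)
    side_long, side_short = max(w, h), min(w, h)
    if side_short <= 2.0 * s * c * side_long or abs(s - c) < 1e-10:
        x = 0.5 * side_short
        if w >= h:
            wr, hr = x / s, x / c
        else:
            wr, hr = x / c, x / s
    else:
        cos2 = c * c - s * s
        wr = (w * c - h * s) / cos2
        hr = (h * c - w * s) / cos2
    return wr, hr


def largest_inscribed_rect_after_rotation(
    w: int, h: int, theta_deg: float
) -> Quad:
    """Largest axis-aligned rectangle inside the footprint of a w x h image
    rotated about its centre by ``theta_deg``.

    The returned quad is expressed in the *rotated* canvas frame, centred on
    the rotated footprint's centre (the canvas is assumed to be the tight
    bounding box of the rotated footprint, as produced by a resize-on-rotate).
    """
    if abs(theta_deg) >= 90:
        raise ValueError("|theta| must be < 90 degrees")
    wr, hr = _max_inscribed_dims(w, h, theta_deg)
    theta = math.radians(abs(theta_deg))
    bb_w = w * math.cos(theta) + h * math.sin(theta)
    bb_h = w * math.sin(theta) + h * math.cos(theta)
    cx, cy = bb_w / 2.0, bb_h / 2.0
    x0, x1 = cx - wr / 2.0, cx + wr / 2.0
    y0, y1 = cy - hr / 2.0, cy + hr / 2.0
    return Quad.from_rect(x0, y0, x1, y1)


def largest_rect_in_mask(valid: np.ndarray) -> Quad:
    """Maximal-area axis-aligned rectangle of True pixels in a binary mask.

    Histogram-stack algorithm, O(rows * cols).  Returns a quad whose corners
    are inclusive pixel bounds promoted to a half-open box
    [x0, x1) x [y0, y1).
    """
    m = np.asarray(valid).astype(bool)
    if m.size == 0 or not m.any():
        raise ValueError("mask contains no valid pixels")
    n_rows, n_cols = m.shape
    heights = np.zeros(n_cols, dtype=int)
    best = (0, 0, 0, 0, 0)  # area, x0, y0, x1, y1
    for r in range(n_rows):
        heights = np.where(m[r], heights + 1, 0)
        # largest rectangle in histogram via a stack
        stack: list[int] = []
        c = 0
        while c <= n_cols:
            cur = heights[c] if c < n_cols else 0
            if not stack or cur >= heights[stack[-1]]:
                stack.append(c)
                c += 1
            else:
                top = stack.pop()
                width = c if not stack else c - stack[-1] - 1
                area = heights[top] * width
                if area > best[0]:
                    x0 = 0 if not stack else stack[-1] + 1
                    best = (area, x0, r - heights[top] + 1, x0 + width, r + 1)
        # loop leaves stack monotonically increasing; restart each row
    _, x0, y0, x1, y1 = best
    return Quad.from_rect(float(x0), float(y0), float(x1), float(y1))


def perpendicular_distance(seg: LineSegment, p: Point2D) -> float:
    """Distance from point ``p`` to the infinite line through ``seg``."""
    (x1, y1), (x2, y2) = seg.p1, seg.p2
    a = y2 - y1
    b = x1 - x2
    c = x2 * y1 - x1 * y2
    return abs(a * p[0] + b * p[1] + c) / math.hypot(a, b)
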