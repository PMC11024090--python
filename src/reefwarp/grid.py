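"""Perspective-grid detection: vanishing lines, vanishing point, grid.

Images of world-parallel reef structure (sand channels, elongated colonies,
transect tape) converge at the scene's vanishing point on the horizon.
With no consistently occurring lane-marking analogue underwater, many small
Hough segments are gathered and run through logical filters: an angle
window keyed to the horizon height, a left/right split with a slope-sign
rule, balanced downsampling, and intersection filtering near the horizon.
The surviving intersections average to the overall vanishing point; the
segment passing closest to it becomes the scene's representative vanishing
line, paired with a horizontal line through its midpoint to form the
axis-aligned perspective grid whose angle reaches 90 degrees exactly when
perspective is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import probabilistic_hough_line

from .config import PipelineConfig
from .errors import NoCandidateLinesError, NoVanishingLineError, NoVanishingPointError
from .geometry import LineSegment, Point2D, perpendicular_distance
from .horizon import EdgeMap, HorizonLine


@dataclass
class PerspectiveGrid:
    vanishing_line: LineSegment
    horizontal_line: LineSegment
    vp: Point2D


def detect_line_segments(
    edges: EdgeMap, config: PipelineConfig | None = None
) -> list[LineSegment]:
    """Probabilistic Hough transform with relaxed constraints.

    Callers must zero edges above the horizon beforehand; relaxed vote and
    length thresholds deliberately admit many small segments so that scenes
    with low coral cover still yield candidates.
    """
    cfg = config or PipelineConfig()
    if not edges.data.any():
        return []
    raw = probabilistic_hough_line(
        edges.data,
        threshold=cfg.hough_threshold,
        line_length=cfg.hough_min_length,
        line_gap=cfg.hough_line_gap,
        rng=np.random.default_rng(cfg.seed),
    )
    segments = []
    for (x0, y0), (x1, y1) in raw:
        if (x0, y0) != (x1, y1):
            segments.append(LineSegment((float(x0), float(y0)), (float(x1), float(y1))))
    return segments


def min_abs_angle(horizon_intercept: float, height: int, cfg: PipelineConfig) -> float:
    """Angle floor for candidate lines, keyed to the horizon height.

    A horizon in the middle third of the frame leaves vanishing lines
    converging at shallow angles; a horizon in the top third steepens them.
    Linear interpolation between the two regimes.
    """
    return float(
        np.interp(
            horizon_intercept,
            [height / 3.0, 2.0 * height / 3.0],
            [cfg.angle_min_top, cfg.angle_min_mid],
        )
    )


def filter_candidate_lines(
    segments: list[LineSegment],
    horizon: HorizonLine,
    width: int,
    height: int,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[list[LineSegment], list[LineSegment]]:
    """Logical-angle filter, left/right split, sign rule, balanced sampling.

    In y-down coordinates a vanishing line right of the vanishing point
    runs down-rightward (positive slope) and vice versa; segments violating
    the sign rule for their side are dropped.  The larger side is randomly
    downsampled (seeded) to the smaller side's count to avoid side bias in
    the vanishing-point average.
    """
    cfg = config or PipelineConfig()
    a_min = min_abs_angle(horizon.intercept, height, cfg)
    left, right = [], []
    for seg in segments:
        ang = abs(seg.angle_deg)
        if ang < a_min or ang > cfg.angle_max:
            continue
        is_left = seg.midpoint[0] <= width / 2.0
        slope = seg.slope
        if is_left:
            if slope < 0:
                left.append(seg)
        else:
            if math.isfinite(slope) and slope > 0:
                right.append(seg)
    if not left or not right:
        raise NoCandidateLinesError(
            f"no candidates on {'left' if not left else 'right'} side after filtering"
        )
    rng = np.random.default_rng(seed)
    if len(left) > len(right):
        idx = rng.choice(len(left), size=len(right), replace=False)
        left = [left[i] for i in sorted(idx)]
    elif len(right) > len(left):
        idx = rng.choice(len(right), size=len(left), replace=False)
        right = [right[i] for i in sorted(idx)]
    return left, right


def _infinite_line(seg: LineSegment) -> tuple[float, float, float]:
    (x1, y1), (x2, y2) = seg.p1, seg.p2
    return (y2 - y1, x1 - x2, x2 * y1 - x1 * y2)


def candidate_vanishing_points(
    left: list[LineSegment],
    right: list[LineSegment],
    horizon: HorizonLine,
    width: int,
    height: int,
    config: PipelineConfig | None = None,
) -> list[Point2D]:
    """Left x right intersections near the horizon, centred on the frame.

    An intersection survives if it lies within a +-1% height band around the
    horizon line and within the central quarter of the image width.
    """
    cfg = config or PipelineConfig()
    if not left or not right:
        raise NoVanishingPointError("need candidates on both sides")
    band = cfg.horizon_band_frac * height
    half_win = cfg.vp_width_frac / 2.0
    x_lo, x_hi = (0.5 - half_win) * width, (0.5 + half_win) * width
    out = []
    for ls in left:
        a1, b1, c1 = _infinite_line(ls)
        for rs in right:
            a2, b2, c2 = _infinite_line(rs)
            det = a1 * b2 - a2 * b1
            if abs(det) < 1e-12:
                continue
            x = (b1 * c2 - b2 * c1) / det
            y = (a2 * c1 - a1 * c2) / det
            if abs(y - horizon.line.y_at(x)) <= band and x_lo <= x <= x_hi:
                out.append((x, y))
    if not out:
        raise NoVanishingPointError("no intersections in the horizon window")
    return out


def overall_vanishing_point(candidates: list[Point2D]) -> Point2D:
    if not candidates:
        raise NoVanishingPointError("empty candidate set")
    arr = np.asarray(candidates, dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def extend_segment(seg: LineSegment, length: float) -> LineSegment:
    """Extend symmetrically about the midpoint to exactly ``length``."""
    if seg.length >= length:
        return seg
    mx, my = seg.midpoint
    dx = (seg.p2[0] - seg.p1[0]) / seg.length
    dy = (seg.p2[1] - seg.p1[1]) / seg.length
    h = length / 2.0
    return LineSegment((mx - h * dx, my - h * dy), (mx + h * dx, my + h * dy))


def select_vanishing_line(
    segments: list[LineSegment],
    vp: Point2D,
    anisotropy_index: float,
    config: PipelineConfig | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> LineSegment:
    """Highest-ranking vanishing line: minimum perpendicular VP distance.

    Segments whose y-midpoint lies above the anisotropy index are excluded
    so the grid stays on the source plane; the winner is extended to the
    minimum drawable length.  ``bounds`` (x0, y0, x1, y1), when given,
    additionally requires the *extended* segment to stay inside the source
    plane so it can be drawn there.
    """
    cfg = config or PipelineConfig()
    best, best_d = None, np.inf
    for seg in segments:
        if seg.midpoint[1] <= anisotropy_index:
            continue
        ext = extend_segment(seg, cfg.min_vanishing_line_px)
        if bounds is not None:
            x0, y0, x1, y1 = bounds
            ok = all(
                x0 <= p[0] <= x1 and y0 <= p[1] <= y1 for p in (ext.p1, ext.p2)
            )
            if not ok:
                continue
        d = perpendicular_distance(seg, vp)
        if d < best_d:
            best, best_d = ext, d
    if best is None:
        raise NoVanishingLineError(
            "no candidate vanishing line below the anisotropy index"
        )
    return best


def build_perspective_grid(
    vline: LineSegment, width: int, vp: Point2D
) -> PerspectiveGrid:
    """Pair the vanishing line with a horizontal line through its midpoint."""
    y_mid = vline.midpoint[1]
    horizontal = LineSegment((0.0, y_mid), (float(width), y_mid))
    return PerspectiveGrid(vanishing_line=vline, horizontal_line=horizontal, vp=vp)
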