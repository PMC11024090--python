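"""Brute-force inverse-perspective mapping.

The perspective grid is drawn on the source plane in a reserved saturated
colour, and the plane is repeatedly warped while the compression factor
x_cf sweeps downward through (0, 1).  Each iteration re-segments the drawn
grid in HSV space, measures the angle between its two lines, and the sweep
halts when the angle reaches 90 degrees — the signature that vanishing
lines have become parallel and all perspective-induced distortion is gone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import polygon
from skimage.morphology import closing, footprint_rectangle, opening
from skimage.transform import probabilistic_hough_line
from skimage.feature import canny

from .config import PipelineConfig
from .errors import GridLostError, SearchNonConvergenceError
from .geometry import (
    Quad,
    apply_homography_array,
    destination_corners,
    fit_homography,
    warp_image,
)
from .grid import PerspectiveGrid


@dataclass
class SearchResult:
    x_cf: float
    grid_angle_at_stop: float
    homography: np.ndarray
    transformed: np.ndarray
    n_iterations: int
    converged: bool
    angle_trace: list[tuple[float, float]] = field(default_factory=list, repr=False)


def _thick_line_polygon(p1, p2, thickness: float):
    """Corner coordinates of a rectangle around segment p1-p2."""
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    n = math.hypot(dx, dy)
    ox, oy = -dy / n * thickness / 2.0, dx / n * thickness / 2.0
    xs = np.array([p1[0] + ox, p2[0] + ox, p2[0] - ox, p1[0] - ox])
    ys = np.array([p1[1] + oy, p2[1] + oy, p2[1] - oy, p1[1] - oy])
    return ys, xs


def overlay_grid(
    plane: np.ndarray,
    grid: PerspectiveGrid,
    y_offset: float = 0.0,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Draw both grid lines on a copy of the source plane.

    ``y_offset`` shifts grid coordinates (given in full-image rows) into
    plane-local rows.  The reserved colour must survive warping and HSV
    segmentation, so lines are drawn a few pixels thick.  Raises if either
    line leaves the plane.
    """
    cfg = config or PipelineConfig()
    h, w = plane.shape[:2]
    out = plane.copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    for seg in (grid.vanishing_line, grid.horizontal_line):
        p1 = (seg.p1[0], seg.p1[1] - y_offset)
        p2 = (seg.p2[0], seg.p2[1] - y_offset)
        for p in (p1, p2):
            if not (-0.5 <= p[0] <= w + 0.5 and -0.5 <= p[1] <= h + 0.5):
                raise ValueError(f"grid endpoint {p} outside the source plane")
        ys, xs = _thick_line_polygon(p1, p2, cfg.grid_thickness)
        rr, cc = polygon(ys, xs, shape=out.shape[:2])
        out[rr, cc] = cfg.grid_color
    return out


def _segment_grid_mask(warped: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    hsv = rgb2hsv(warped)
    target_h = 1.0 / 6.0  # pure yellow
    dh = np.abs(hsv[..., 0] - target_h)
    dh = np.minimum(dh, 1.0 - dh)
    mask = (dh <= cfg.hue_band) & (hsv[..., 1] >= cfg.sat_min) & (hsv[..., 2] >= cfg.val_min)
    mask = closing(mask, footprint_rectangle((5, 5)))
    # closing keeps isolated speckle; a small opening removes chance
    # colour collisions while leaving the thick drawn lines intact
    return opening(mask, footprint_rectangle((3, 3)))


def _axial_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean of axial (180-degree-periodic) angles via angle doubling.

    Optional weights (e.g. segment lengths): long chords constrain the
    orientation far more tightly than short ones.
    """
    a = np.radians(angles_deg * 2.0)
    if weights is None:
        weights = np.ones_like(a)
    m = math.atan2(
        float(np.average(np.sin(a), weights=weights)),
        float(np.average(np.cos(a), weights=weights)),
    ) / 2.0
    return math.degrees(m)


def _fold180(a: float) -> float:
    """Fold into (-90, 90]."""
    a = (a + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def grid_line_orientations(
    warped: np.ndarray,
    config: PipelineConfig | None = None,
    scale_hint: float = 1.0,
) -> tuple[float, float]:
    """Axial orientations (degrees) of the two grid-line groups.

    Segments detected on the segmented-mask edges are split into the
    horizontal group (the drawn horizontal line, which stays horizontal
    under the source-to-destination warp family) and the vanishing group
    (everything else); returns (horizontal mean, vanishing mean).  The
    split against a fixed near-horizontal reference is safe under the
    axial +-90-degree wrap that occurs as the vanishing line approaches
    vertical.
    """
    cfg = config or PipelineConfig()
    mask = _segment_grid_mask(warped, cfg)
    if mask.sum() < 50:
        raise GridLostError("grid colour mask nearly empty after warping")
    edge = canny(mask.astype(float), sigma=1.0)
    segs = probabilistic_hough_line(
        edge,
        threshold=10,
        line_length=30,
        line_gap=4,
        rng=np.random.default_rng(cfg.seed),
    )
    if len(segs) < 2:
        raise GridLostError(f"only {len(segs)} mask segments; need two line groups")
    ang, lengths = [], []
    for (x0, y0), (x1, y1) in segs:
        a = math.degrees(math.atan2(y1 - y0, x1 - x0))
        ang.append(_fold180(a))
        lengths.append(math.hypot(x1 - x0, y1 - y0))
    ang = np.asarray(ang)
    lengths = np.asarray(lengths)
    is_h = np.abs(ang) <= 6.0
    if not is_h.any() or is_h.all():
        raise GridLostError("could not split mask segments into two groups")
    ys, xs = np.nonzero(mask)
    pix = np.column_stack([xs, ys]).astype(float)
    rough_params = []
    for sel in (is_h, ~is_h):
        rough = _axial_mean_deg(ang[sel], lengths[sel])
        ends = np.array(
            [p for s, keep in zip(segs, sel) if keep for p in s], dtype=float
        )
        centre = np.average(ends, axis=0, weights=np.repeat(lengths[sel], 2))
        normal = np.array(
            [math.sin(math.radians(rough)), -math.cos(math.radians(rough))]
        )
        rough_params.append((rough, np.abs((pix - centre) @ normal)))
    out = []
    for i, (rough, dist) in enumerate(rough_params):
        # principal-axis refinement on mask pixels near the rough line:
        # thousands of pixels along the band pin the orientation far more
        # tightly than the Hough chords alone.  Pixels near the *other*
        # line are excluded — the crossing blob otherwise drags the axis.
        dist_other = rough_params[1 - i][1]
        gate = 8.0 * max(1.0, 0.7 * scale_hint)
        near = pix[(dist <= gate) & (dist_other > 1.75 * gate)]
        if len(near) >= 50:
            c = near - near.mean(axis=0)
            cov = c.T @ c
            evals, evecs = np.linalg.eigh(cov)
            v = evecs[:, np.argmax(evals)]
            out.append(_fold180(math.degrees(math.atan2(v[1], v[0]))))
        else:
            out.append(_fold180(rough))
    return out[0], out[1]


def measure_grid_angle(
    warped: np.ndarray, config: PipelineConfig | None = None
) -> float:
    """Acute angle in degrees between the two drawn grid lines."""
    h_ang, v_ang = grid_line_orientations(warped, config)
    return abs(_fold180(v_ang - h_ang))


def search_compression_factor(
    plane_with_grid: np.ndarray,
    w: int,
    h: int,
    step: float | None = None,
    tol: float | None = None,
    config: PipelineConfig | None = None,
    grid_points: np.ndarray | None = None,
) -> SearchResult:
    """Sweep x_cf downward until the warped grid measures 90 degrees.

    Per iteration the destination trapezoid keeps its far corners at the
    top-source corners while the near corners move inward by the
    compression factor; the homography is fitted, the plane warped, and the
    grid angle measured.  Once inside the angle tolerance the sweep keeps
    stepping while the angle still approaches 90 and saves the closest
    iterate; when consecutive angles bracket 90 the closer iterate is kept.

    ``grid_points``, when given (an (N, 2) array of plane-local points on
    the drawn grid lines), restricts the per-iteration warp to the bounding
    box of the warped grid — a pure speed optimisation with identical
    measurements.
    """
    cfg = config or PipelineConfig()
    step = step if step is not None else cfg.step_x_cf
    tol = tol if tol is not None else cfg.angle_tol_deg
    if not (0.0 < step <= 0.01):
        raise ValueError("step must lie in (0, 0.01]")
    src = Quad.from_rect(0, 0, w, h)
    sign = 0.0
    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    prev: tuple[float, float, np.ndarray, np.ndarray] | None = None
    stall = 0
    trace: list[tuple[float, float]] = []
    n_iter = 0
    x_cf = 1.0 - step
    last_angle = None
    while x_cf > step / 2.0:
        n_iter += 1
        c_l, c_r = destination_corners(w, h, x_cf)
        dst = Quad((0.0, 0.0), (float(w), 0.0), c_r, c_l)
        H = fit_homography(src, dst)
        zoom = 1.0
        if grid_points is not None:
            wp = apply_homography_array(H, grid_points)
            x0 = int(max(0, np.floor(wp[:, 0].min()) - 25))
            x1 = int(min(w, np.ceil(wp[:, 0].max()) + 25))
            y0 = int(max(0, np.floor(wp[:, 1].min()) - 25))
            y1 = int(min(h, np.ceil(wp[:, 1].max()) + 25))
            # scale the measurement box toward a fixed pixel budget: a
            # uniform scaling leaves angles unchanged; zooming in keeps the
            # thinning grid lines properly sampled at strong compression,
            # zooming out bounds the per-iteration cost for large boxes
            bw, bh = max(x1 - x0, 1), max(y1 - y0, 1)
            zoom = float(np.clip(math.sqrt(2.5e5 / (bw * bh)), 0.55, 4.0))
            T = np.diag([zoom, zoom, 1.0])
            T[0, 2], T[1, 2] = -x0 * zoom, -y0 * zoom
            warped = warp_image(
                plane_with_grid, T @ H, (int(bw * zoom), int(bh * zoom))
            )
        else:
            warped = warp_image(plane_with_grid, H, (w, h))
        h_ang, v_ang = grid_line_orientations(warped, cfg, scale_hint=zoom)
        dev = _fold180(v_ang - h_ang)
        if sign == 0.0 and abs(dev) < 89.0:
            sign = 1.0 if dev > 0 else -1.0
        u = sign * dev if sign else abs(dev)
        if u <= 0:
            u += 180.0
        trace.append((x_cf, u))
        last_angle = u

        def _result(state) -> SearchResult:
            xb, ub, Hb, wb = state
            if grid_points is not None:
                wb = warp_image(plane_with_grid, Hb, (w, h))
            return SearchResult(
                x_cf=xb,
                grid_angle_at_stop=ub,
                homography=Hb,
                transformed=wb,
                n_iterations=n_iter,
                converged=True,
                angle_trace=trace,
            )

        cur = (x_cf, u, H, warped)
        if prev is not None and (prev[1] - 90.0) * (u - 90.0) < 0:
            # bracketed 90 between consecutive steps: keep the closer iterate
            return _result(prev if abs(prev[1] - 90.0) < abs(u - 90.0) else cur)
        if abs(u - 90.0) <= tol:
            # inside the detection window: keep scanning until the closest
            # approach is clearly passed, then return it (measurement jitter
            # is far smaller than five steps' worth of angle change)
            if best is None or abs(u - 90.0) < abs(best[1] - 90.0):
                best = cur
                stall = 0
            else:
                stall += 1
                if stall >= 5:
                    return _result(best)
        elif best is not None:
            # left the window without improving: count toward the stall so a
            # single jitter excursion cannot end the scan prematurely
            stall += 1
            if stall >= 5:
                return _result(best)
        prev = cur
        x_cf -= step
    if best is not None:
        xb, ub, Hb, wb = best
        if grid_points is not None:
            wb = warp_image(plane_with_grid, Hb, (w, h))
        return SearchResult(
            x_cf=xb,
            grid_angle_at_stop=ub,
            homography=Hb,
            transformed=wb,
            n_iterations=n_iter,
            converged=True,
            angle_trace=trace,
        )
    diagnosis = "under-corrected" if (last_angle or 0.0) < 90.0 else "over-corrected"
    raise SearchNonConvergenceError(
        f"compression sweep exhausted ({diagnosis}; last angle "
        f"{last_angle if last_angle is not None else float('nan'):.2f} deg)",
        final_angle=last_angle,
    )
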