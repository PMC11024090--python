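"""Horizon-line detection by edge-density demarcation.

The reef's texture produces many edges while the water column produces
almost none, so the horizon is recoverable as the boundary of edge-pixel
density.  The chain is: grayscale -> Gaussian blur -> (adaptive mean
threshold) -> Canny edge map -> local edge-density map -> robust
water-column line (Theil-Sen through randomly sampled zero-density pixels)
-> suppression of everything above it -> Otsu binarisation -> longest
contour -> border and z-score filtering -> Theil-Sen horizon fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import canny
from skimage.filters import threshold_local, threshold_otsu

from .config import PipelineConfig
from .errors import HorizonOffLeftEdgeError, NoHorizonError, NoWaterColumnError
from .geometry import Line, theil_sen_fit

GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 601 luma


@dataclass
class EdgeMap:
    """Binary edge raster plus the gradient orientations used downstream.

    ``orientations`` holds the edge-tangent angle of every pixel of the
    blurred intensity image, in radians in (-pi/2, pi/2]; near-horizontal
    structure maps to values near 0.
    """

    data: np.ndarray  # bool
    mode: str  # "adaptive" | "standard"
    orientations: np.ndarray | None = field(default=None, repr=False)


@dataclass
class DensityMap:
    data: np.ndarray  # float in [0, 1]


@dataclass
class HorizonLine:
    line: Line
    source_mode: str = "detected"  # "detected" | "given"

    @property
    def slope(self) -> float:
        return self.line.slope

    @property
    def intercept(self) -> float:
        return self.line.intercept


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grayscale in [0, 255] float."""
    if img.ndim == 2:
        return img.astype(float)
    return img[..., :3].astype(float) @ GRAY_WEIGHTS


def _edge_tangent_angles(blurred: np.ndarray) -> np.ndarray:
    """Edge-tangent orientation from Sobel gradients, in (-pi/2, pi/2]."""
    gx = ndimage.sobel(blurred, axis=1)
    gy = ndimage.sobel(blurred, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(gx / -gy)
    theta[np.abs(gy) < 1e-12] = np.pi / 2.0
    return theta


def build_edge_map(
    img: np.ndarray, mode: str = "adaptive", config: PipelineConfig | None = None
) -> EdgeMap:
    """Canny edge map, optionally on an adaptively thresholded image.

    Adaptive mean thresholding before Canny rescues faint structure near
    the horizon that global gradient thresholds would miss; the "standard"
    mode (no adaptive step) preserves gradient orientations for texture
    statistics and line detection.
    """
    cfg = config or PipelineConfig()
    if mode not in ("adaptive", "standard"):
        raise ValueError(f"unknown edge-map mode {mode!r}")
    gray = to_gray(img)
    if min(gray.shape) < cfg.adaptive_block:
        raise ValueError("image smaller than the adaptive-threshold block")
    blurred = ndimage.gaussian_filter(gray, cfg.gaussian_sigma)
    orientations = _edge_tangent_angles(blurred)
    if mode == "adaptive":
        # skimage subtracts ``offset`` from the local mean; negate so the
        # config value reads "exceed the local mean by this many 8-bit units"
        local = threshold_local(
            blurred,
            block_size=cfg.adaptive_block,
            method="mean",
            offset=-cfg.adaptive_offset,
        )
        work = (blurred > local).astype(float)
    else:
        work = blurred / 255.0
    edges = canny(
        work,
        sigma=0.0,
        low_threshold=cfg.canny_low / 255.0,
        high_threshold=cfg.canny_high / 255.0,
    )
    return EdgeMap(data=edges, mode=mode, orientations=orientations)


def density_radius(shape: tuple[int, int], config: PipelineConfig) -> int:
    diag = float(np.hypot(*shape))
    return max(cfg_int(config.density_radius_frac * diag), config.density_radius_min)


def cfg_int(x: float) -> int:
    return int(round(x))


def edge_density_map(edges: EdgeMap, radius: int) -> DensityMap:
    """Windowed edge-pixel count, self-normalised to [0, 1]."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    counts = ndimage.uniform_filter(
        edges.data.astype(float), size=size, mode="reflect"
    ) * (size * size)
    counts = np.rint(counts)  # counts are integers; kill cancellation residue
    peak = counts.max()
    if peak <= 0:
        return DensityMap(np.zeros_like(counts))
    return DensityMap(counts / peak)


def fit_water_column_line(
    density: DensityMap, n_samples: int = 100, seed: int = 0
) -> Line:
    """Robust line through randomly sampled zero-edge-density pixels.

    Shadows below the horizon also have zero density and contaminate the
    sample; the Theil-Sen estimator tolerates them up to its ~29% breakdown
    point, leaving a line through the water column.
    """
    ys, xs = np.nonzero(density.data == 0.0)
    if len(ys) < n_samples:
        raise NoWaterColumnError(
            f"only {len(ys)} zero-density pixels; need {n_samples}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ys), size=n_samples, replace=False)
    pts = np.column_stack([xs[idx], ys[idx]]).astype(float)
    return theil_sen_fit(pts)


def suppress_above_line(density: DensityMap, line: Line) -> DensityMap:
    """Zero every pixel strictly above the line (smaller y)."""
    h, w = density.data.shape
    ys, xs = np.mgrid[0:h, 0:w]
    out = density.data.copy()
    out[ys < line.slope * xs + line.intercept] = 0.0
    return DensityMap(out)


def otsu_binarize(density: DensityMap) -> np.ndarray:
    """Two-class split of the density map; 1 = reef, 0 = water.

    The map is quantised to 256 grey levels and thresholded at the level
    minimising intra-class variance; a constant map is defined as all-water.
    """
    q = np.clip(np.rint(density.data * 255.0), 0, 255).astype(np.uint8)
    if q.min() == q.max():
        return np.zeros_like(q, dtype=bool)
    t = threshold_otsu(q)
    return q > t


def extract_horizon_points(binary: np.ndarray, z_thresh: float = 2.5) -> np.ndarray:
    """Horizon point candidates from the longest reef-class contour.

    Border-hugging points are dropped, then a single-pass z-score filter on
    the y-coordinate removes contour excursions into shadowed notches.
    Returns an (N, 2) array of (x, y).

    Interior holes of the reef class (shadowed or texture-poor patches fully
    enclosed by reef) are filled first: their boundaries are never the
    reef/water demarcation, and filling leaves the outer contour unchanged.
    """
    filled = ndimage.binary_fill_holes(binary)
    contours = measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise NoHorizonError("no contours in the binarised density map")
    longest = max(contours, key=len)
    h, w = binary.shape
    ys, xs = longest[:, 0], longest[:, 1]
    interior = (xs > 1.5) & (xs < w - 2.5) & (ys > 1.5) & (ys < h - 2.5)
    xs, ys = xs[interior], ys[interior]
    if len(xs) == 0:
        raise NoHorizonError("longest contour lies entirely on the border")
    sd = ys.std()
    if sd > 0:
        keep = np.abs(ys - ys.mean()) <= z_thresh * sd
        xs, ys = xs[keep], ys[keep]
    if len(xs) < 2:
        raise NoHorizonError("too few horizon points after filtering")
    return np.column_stack([xs, ys])


def detect_horizon(
    img: np.ndarray, config: PipelineConfig | None = None
) -> HorizonLine:
    """Full horizon-detection chain on an undistorted image."""
    cfg = config or PipelineConfig()
    edges = build_edge_map(img, "adaptive", cfg)
    radius = density_radius(edges.data.shape, cfg)
    density = edge_density_map(edges, radius)
    water = fit_water_column_line(density, cfg.n_water_samples, cfg.seed)
    density = suppress_above_line(density, water)
    binary = otsu_binarize(density)
    pts = extract_horizon_points(binary, cfg.zscore_threshold)
    if len(pts) > cfg.max_horizon_points:
        step = len(pts) // cfg.max_horizon_points + 1
        pts = pts[::step]
    line = theil_sen_fit(pts)
    h = img.shape[0]
    y_left = line.y_at(0.0)
    if not (0.0 <= y_left <= h - 1):
        raise HorizonOffLeftEdgeError(
            f"horizon meets the left edge at y={y_left:.1f}, outside the frame"
        )
    if abs(line.slope) >= 1.0 or not (-0.5 * h <= line.intercept <= 1.5 * h):
        raise NoHorizonError(
            f"implausible horizon fit (slope {line.slope:.3f}, "
            f"intercept {line.intercept:.1f})"
        )
    return HorizonLine(line=line, source_mode="detected")
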