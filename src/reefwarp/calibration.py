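"""Per-camera lens calibration and undistortion.

A camera is modelled as a pinhole with focal lengths (fx, fy), principal
point (cx, cy), and a 5-coefficient Brown distortion model (radial k1, k2,
k3 and tangential p1, p2).  Intrinsics are estimated once per camera-lens
model from photographs of a planar checkerboard seen from multiple poses:

1. saddle-point (X-corner) detection via the negative determinant of the
   smoothed intensity Hessian, with sub-pixel quadratic refinement;
2. grid ordering by fitting a board->image homography to the four extreme
   corners and greedily matching the projected ideal lattice;
3. closed-form intrinsics from the plane-homography constraints on the
   image of the absolute conic (Zhang's method), followed by joint
   nonlinear refinement of intrinsics, distortion, and per-view extrinsics
   minimising the reprojection error.

For underwater use the refractive magnification of the housing/water path
is absorbed into the calibrated effective focal length, so calibration
imagery should be captured in the same medium as the survey imagery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from scipy.spatial import ConvexHull

from .errors import InsufficientViewsError, PatternNotFoundError
from .geometry import Quad, largest_rect_in_mask

MIN_CALIBRATION_VIEWS = 10


@dataclass
class CameraModel:
    """Pinhole intrinsics plus Brown radial/tangential distortion."""

    name: str
    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0
    rms_reprojection: float = 0.0
    image_size: tuple[int, int] = (0, 0)  # (width, height)

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        self.image_size = tuple(self.image_size)

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def dist(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])

    @property
    def has_distortion(self) -> bool:
        return bool(np.any(self.dist != 0.0))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraModel":
        d = json.loads(Path(path).read_text())
        d["image_size"] = tuple(d.get("image_size", (0, 0)))
        return cls(**d)


# ----------------------------------------------------------------------
# distortion model


def distort_normalized(xu: np.ndarray, yu: np.ndarray, dist: np.ndarray):
    """Apply Brown distortion to undistorted normalized coordinates."""
    k1, k2, p1, p2, k3 = dist
    r2 = xu * xu + yu * yu
    radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    xd = xu * radial + 2.0 * p1 * xu * yu + p2 * (r2 + 2.0 * xu * xu)
    yd = yu * radial + p1 * (r2 + 2.0 * yu * yu) + 2.0 * p2 * xu * yu
    return xd, yd


def undistort_normalized(
    xd: np.ndarray, yd: np.ndarray, dist: np.ndarray, iterations: int = 15
):
    """Invert the Brown model by fixed-point iteration."""
    xu, yu = np.array(xd, dtype=float, copy=True), np.array(yd, dtype=float, copy=True)
    k1, k2, p1, p2, k3 = dist
    for _ in range(iterations):
        r2 = xu * xu + yu * yu
        radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
        dx = 2.0 * p1 * xu * yu + p2 * (r2 + 2.0 * xu * xu)
        dy = p1 * (r2 + 2.0 * yu * yu) + 2.0 * p2 * xu * yu
        xu = (xd - dx) / radial
        yu = (yd - dy) / radial
    return xu, yu


# ----------------------------------------------------------------------
# checkerboard corner detection


def _saddle_response(gray: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """-det(Hessian) of the smoothed image: large and positive at X-corners."""
    g = ndimage.gaussian_filter(gray.astype(float), sigma)
    gxx = ndimage.gaussian_filter(g, sigma, order=(0, 2))
    gyy = ndimage.gaussian_filter(g, sigma, order=(2, 0))
    gxy = ndimage.gaussian_filter(g, sigma, order=(1, 1))
    return -(gxx * gyy - gxy * gxy)


def _subpixel_peak(resp: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Quadratic fit of the 3x3 neighbourhood around an integer maximum."""
    if not (1 <= y < resp.shape[0] - 1 and 1 <= x < resp.shape[1] - 1):
        return float(x), float(y)
    win = resp[y - 1: y + 2, x - 1: x + 2]
    dx = (win[1, 2] - win[1, 0]) / 2.0
    dy = (win[2, 1] - win[0, 1]) / 2.0
    dxx = win[1, 2] - 2 * win[1, 1] + win[1, 0]
    dyy = win[2, 1] - 2 * win[1, 1] + win[0, 1]
    dxy = (win[2, 2] - win[2, 0] - win[0, 2] + win[0, 0]) / 4.0
    det = dxx * dyy - dxy * dxy
    if abs(det) < 1e-12:
        return float(x), float(y)
    ox = -(dyy * dx - dxy * dy) / det
    oy = -(dxx * dy - dxy * dx) / det
    if abs(ox) > 1 or abs(oy) > 1:
        return float(x), float(y)
    return x + ox, y + oy


def _candidate_corners(gray: np.ndarray, n_expected: int) -> np.ndarray:
    resp = _saddle_response(gray)
    peak = resp.max()
    if peak <= 0:
        raise PatternNotFoundError("no saddle-point response in image")
    footprint = ndimage.maximum_filter(resp, size=9)
    maxima = (resp == footprint) & (resp > 0.05 * peak)
    ys, xs = np.nonzero(maxima)
    if len(ys) < n_expected:
        raise PatternNotFoundError(
            f"found {len(ys)} saddle points, expected at least {n_expected}"
        )
    order = np.argsort(resp[ys, xs])[::-1][: 2 * n_expected]
    pts = [_subpixel_peak(resp, int(ys[i]), int(xs[i])) for i in order]
    return np.asarray(pts)


def _grid_labelings(rows: int, cols: int):
    """Eight dihedral assignments of the unit lattice's four extreme corners."""
    base = [(0.0, 0.0), (cols - 1.0, 0.0), (cols - 1.0, rows - 1.0), (0.0, rows - 1.0)]
    for start in range(4):
        for direction in (1, -1):
            yield [base[(start + direction * k) % 4] for k in range(4)]


def _try_order(
    candidates: np.ndarray, rows: int, cols: int
) -> tuple[np.ndarray, float] | None:
    """One ordering attempt on a candidate subset; returns (ordered, score)."""
    from scipy.optimize import linear_sum_assignment

    from .geometry import fit_homography, apply_homography_array

    n = rows * cols
    if len(candidates) < n:
        return None
    try:
        hull = ConvexHull(candidates)
    except Exception:
        return None
    hull_pts = candidates[hull.vertices]
    # extreme-corner heuristic: works for board tilts below ~45 degrees
    quad_img = [
        tuple(hull_pts[np.argmin(hull_pts.sum(axis=1))]),
        tuple(hull_pts[np.argmax(hull_pts[:, 0] - hull_pts[:, 1])]),
        tuple(hull_pts[np.argmax(hull_pts.sum(axis=1))]),
        tuple(hull_pts[np.argmin(hull_pts[:, 0] - hull_pts[:, 1])]),
    ]
    jj, ii = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    lattice = np.column_stack([jj.ravel(), ii.ravel()])

    best = None
    for labeling in _grid_labelings(rows, cols):
        try:
            H = fit_homography(Quad(*labeling), Quad(*quad_img))
            proj = apply_homography_array(H, lattice)
        except Exception:
            continue
        d = np.sqrt(((proj[:, None, :] - candidates[None, :, :]) ** 2).sum(axis=2))
        ri, ci = linear_sum_assignment(d)
        score = float(d[ri, ci].mean())
        if best is None or score < best[1]:
            best = (ci, score, H)
    if best is None:
        return None
    match, score, H = best
    # refit the board homography on all matches and re-assign once; this
    # absorbs lens distortion the 4-corner fit cannot express
    from scipy.optimize import linear_sum_assignment as lsa

    ordered = candidates[match]
    H2 = _dlt_homography(lattice, ordered)
    from .geometry import apply_homography_array as aha

    proj2 = aha(H2, lattice)
    d2 = np.sqrt(((proj2[:, None, :] - candidates[None, :, :]) ** 2).sum(axis=2))
    ri, ci = lsa(d2)
    return candidates[ci], float(d2[ri, ci].max())


def _order_corners_grid(
    candidates: np.ndarray, rows: int, cols: int
) -> np.ndarray | None:
    """Order detected saddle points into a row-major (rows x cols) lattice.

    Tried first on the strongest rows*cols responses (true X-corners respond
    more strongly than stray board-edge corners), then on progressively
    larger candidate pools.
    """
    n = rows * cols
    best = None
    for pool in (n, int(1.3 * n), len(candidates)):
        subset = candidates[: min(pool, len(candidates))]
        res = _try_order(subset, rows, cols)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        return None
    ordered, worst = best
    spacing = float(np.median(np.linalg.norm(np.diff(
        ordered.reshape(rows, cols, 2), axis=1), axis=2)))
    if worst > 0.35 * spacing:
        return None
    return ordered


def find_checkerboard_corners(
    img: np.ndarray, rows: int, cols: int
) -> np.ndarray:
    """Detect and order the (rows x cols) inner corners of a checkerboard.

    Returns an (rows*cols, 2) array of sub-pixel (x, y) corner positions in
    row-major board order; raises :class:`PatternNotFoundError` otherwise.
    """
    gray = img if img.ndim == 2 else img.mean(axis=2)
    candidates = _candidate_corners(gray, rows * cols)
    ordered = _order_corners_grid(candidates, rows, cols)
    if ordered is None:
        raise PatternNotFoundError("could not order saddle points into a grid")
    return ordered


# ----------------------------------------------------------------------
# Zhang closed-form initialisation


def _dlt_homography(obj_xy: np.ndarray, img_xy: np.ndarray) -> np.ndarray:
    """Normalised DLT homography from n>=4 planar correspondences."""

    def normalise(pts):
        c = pts.mean(axis=0)
        s = math.sqrt(2.0) / np.mean(np.linalg.norm(pts - c, axis=1))
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return ph, T

    src, Ts = normalise(obj_xy)
    dst, Td = normalise(img_xy)
    A = []
    for (x, y, _), (u, v, _) in zip(src, dst):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, Vt = np.linalg.svd(np.asarray(A))
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _v_ij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ]
    )


def _zhang_intrinsics(homographies: list[np.ndarray], size: tuple[int, int]):
    V = []
    for H in homographies:
        V.append(_v_ij(H, 0, 1))
        V.append(_v_ij(H, 0, 0) - _v_ij(H, 1, 1))
    _, _, Vt = np.linalg.svd(np.asarray(V))
    B11, B12, B22, B13, B23, B33 = Vt[-1]
    try:
        v0 = (B12 * B13 - B11 * B23) / (B11 * B22 - B12 * B12)
        lam = B33 - (B13 * B13 + v0 * (B12 * B13 - B11 * B23)) / B11
        alpha = math.sqrt(lam / B11)
        beta = math.sqrt(lam * B11 / (B11 * B22 - B12 * B12))
        u0 = -B13 * alpha * alpha / lam
        if not (0 < alpha < 1e6 and 0 < beta < 1e6):
            raise ValueError
        return alpha, beta, u0, v0
    except (ValueError, ZeroDivisionError, FloatingPointError):
        w, h = size
        return 1.2 * max(w, h), 1.2 * max(w, h), w / 2.0, h / 2.0


def _init_extrinsics(K: np.ndarray, H: np.ndarray):
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
    return Rotation.from_matrix(R).as_rotvec(), t


def _project(params_cam, rvec, tvec, obj3):
    fx, fy, cx, cy = params_cam[:4]
    dist = params_cam[4:9]
    R = Rotation.from_rotvec(rvec).as_matrix()
    pc = obj3 @ R.T + tvec
    x, y = pc[:, 0] / pc[:, 2], pc[:, 1] / pc[:, 2]
    xd, yd = distort_normalized(x, y, dist)
    return np.column_stack([fx * xd + cx, fy * yd + cy])


def calibrate_camera(
    images: list[np.ndarray],
    pattern: tuple[int, int, float],
    name: str = "camera",
) -> CameraModel:
    """Estimate a :class:`CameraModel` from checkerboard photographs.

    ``pattern`` is (inner-corner rows, inner-corner cols, square size in any
    consistent world unit).  At least :data:`MIN_CALIBRATION_VIEWS` images in
    which the full pattern is detectable are required; the pattern should be
    seen from different angles and in different parts of the frame so the
    plane constraints span the intrinsic space.
    """
    rows, cols, square = pattern
    detections, sizes = [], set()
    for img in images:
        sizes.add((img.shape[1], img.shape[0]))
        try:
            detections.append(find_checkerboard_corners(img, rows, cols))
        except PatternNotFoundError:
            continue
    if not detections:
        raise PatternNotFoundError("calibration pattern not found in any image")
    if len(detections) < MIN_CALIBRATION_VIEWS:
        raise InsufficientViewsError(
            f"only {len(detections)} usable views; need {MIN_CALIBRATION_VIEWS}"
        )
    size = max(sizes)
    jj, ii = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    obj_xy = np.column_stack([jj.ravel(), ii.ravel()]) * square
    obj3 = np.column_stack([obj_xy, np.zeros(len(obj_xy))])

    homographies = [_dlt_homography(obj_xy, det) for det in detections]
    fx, fy, cx, cy = _zhang_intrinsics(homographies, size)
    K0 = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1]])
    extr = [_init_extrinsics(K0, H) for H in homographies]

    x0 = np.concatenate(
        [[fx, fy, cx, cy, 0, 0, 0, 0, 0]] + [np.concatenate([r, t]) for r, t in extr]
    )
    n_views = len(detections)

    def residuals(p):
        cam = p[:9]
        res = []
        for v in range(n_views):
            rv = p[9 + 6 * v: 12 + 6 * v]
            tv = p[12 + 6 * v: 15 + 6 * v]
            proj = _project(cam, rv, tv, obj3)
            res.append((proj - detections[v]).ravel())
        return np.concatenate(res)

    sol = optimize.least_squares(residuals, x0, method="trf", x_scale="jac")
    cam = sol.x[:9]
    n_pts = sum(len(d) for d in detections)
    rms = float(math.sqrt(np.sum(sol.fun**2) / n_pts))
    return CameraModel(
        name=name,
        fx=float(cam[0]),
        fy=float(cam[1]),
        cx=float(cam[2]),
        cy=float(cam[3]),
        k1=float(cam[4]),
        k2=float(cam[5]),
        p1=float(cam[6]),
        p2=float(cam[7]),
        k3=float(cam[8]),
        rms_reprojection=rms,
        image_size=size,
    )


# ----------------------------------------------------------------------
# undistortion


def _retaining_camera_matrix(cam: CameraModel, size: tuple[int, int]):
    """New intrinsics whose frame contains every undistorted source pixel."""
    w, h = size
    edge = np.linspace(0, 1, 64)
    top = np.column_stack([edge * (w - 1), np.zeros(64)])
    bottom = np.column_stack([edge * (w - 1), np.full(64, h - 1)])
    left = np.column_stack([np.zeros(64), edge * (h - 1)])
    right = np.column_stack([np.full(64, w - 1), edge * (h - 1)])
    border = np.vstack([top, bottom, left, right])
    xd = (border[:, 0] - cam.cx) / cam.fx
    yd = (border[:, 1] - cam.cy) / cam.fy
    xu, yu = undistort_normalized(xd, yd, cam.dist)
    fx_new = (w - 1) / (xu.max() - xu.min())
    fy_new = (h - 1) / (yu.max() - yu.min())
    cx_new = -xu.min() * fx_new
    cy_new = -yu.min() * fy_new
    return fx_new, fy_new, cx_new, cy_new


def undistort_image(
    img: np.ndarray, cam: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Remove modelled lens distortion; returns (image, valid-pixel mask).

    The output frame is chosen so that all source pixels are retained
    (free-scaling); the valid mask marks output pixels whose inverse-mapped
    source sample lies inside the source frame.  Callers typically crop to
    ``largest_rect_in_mask(mask)`` afterwards, slightly reducing dimensions.
    """
    h, w = img.shape[:2]
    if not cam.has_distortion:
        return img.copy(), np.ones((h, w), bool)
    # rescale principal point/focals if the image is not at calibration size
    cw, ch = cam.image_size if cam.image_size != (0, 0) else (w, h)
    sx, sy = w / cw, h / ch
    scaled = CameraModel(
        name=cam.name,
        fx=cam.fx * sx,
        fy=cam.fy * sy,
        cx=cam.cx * sx,
        cy=cam.cy * sy,
        k1=cam.k1, k2=cam.k2, p1=cam.p1, p2=cam.p2, k3=cam.k3,
        image_size=(w, h),
    )
    fx_n, fy_n, cx_n, cy_n = _retaining_camera_matrix(scaled, (w, h))
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xu = (xs - cx_n) / fx_n
    yu = (ys - cy_n) / fy_n
    xd, yd = distort_normalized(xu, yu, scaled.dist)
    src_x = xd * scaled.fx + scaled.cx
    src_y = yd * scaled.fy + scaled.cy
    mask = (src_x >= 0) & (src_x <= w - 1) & (src_y >= 0) & (src_y <= h - 1)
    coords = np.stack([src_y.ravel(), src_x.ravel()])

    def _sample(channel):
        return ndimage.map_coordinates(
            channel.astype(float), coords, order=1, mode="constant", cval=0.0
        ).reshape(h, w)

    if img.ndim == 2:
        out = _sample(img)
    else:
        out = np.stack([_sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(img.dtype).max).astype(img.dtype)
    return out, mask


def undistort_and_crop(img: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Undistort then crop to the maximum inscribed axis-aligned rectangle."""
    out, mask = undistort_image(img, cam)
    rect = largest_rect_in_mask(mask)
    x0, y0 = int(rect.tl[0]), int(rect.tl[1])
    x1, y1 = int(rect.br[0]), int(rect.br[1])
    return out[y0:y1, x0:x1]
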