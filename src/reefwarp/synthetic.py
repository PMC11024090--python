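"""Seeded synthetic reefscapes with analytic ground truth.

The renderer emulates the imaging geometry of an oblique reef survey: a
textured ground plane (z = 0) viewed by a pinhole camera at height
``camera_height`` above the plane, pitched down by ``pitch`` degrees, rolled
by ``roll`` and yawed by ``yaw``.  World frame: x to the camera's right,
y pointing away from the camera along its heading, z up.  Camera frame:
x right, y down, z forward (the usual computer-vision convention), so with
zero pitch/roll/yaw the camera looks along world +y.

With ``R`` the world-to-camera rotation and ``t = -R C`` (camera centre
``C = (0, 0, camera_height)``), a ground point (X, Y, 0) images at

    s * (u, v, 1)^T = K [r1  r2  t] (X, Y, 1)^T

so the ground-to-image map is itself a homography, from which the scene's
horizon (image of the plane's line at infinity), vanishing point (image of
the heading direction), and true top-down homography are all derived in
closed form.  Rendering is done by inverse mapping: each pixel's ray is
intersected with the plane and a procedural texture is evaluated at the hit
point, so the rendered horizon agrees with the analytic line to sub-pixel
accuracy by construction.

The texture mixes seeded multi-octave value noise, elliptical "colony"
blobs from a spatial-hash process, and sparse groove lines running parallel
to the camera heading (the synthetic analogue of spur-and-groove reef
structure and transect tape), which furnish genuine vanishing lines.  Blob
and noise amplitudes are chosen so that Canny yields roughly 1-5% edge
pixels below the horizon.  The water column above the horizon is a smooth
blue gradient, optionally with bright near-surface clutter blobs to
exercise water-column suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CameraModel, undistort_normalized
from .errors import FixtureError
from .geometry import Line

# ----------------------------------------------------------------------
# pose and projection


def default_camera(
    width: int = 1600, height: int = 1200, focal: float = 550.0, name: str = "synthetic"
) -> CameraModel:
    """Zero-distortion pinhole used by the synthetic scenes.

    The wide field of view (~110 deg diagonal, typical of action cameras
    used on reef surveys) keeps the horizon comfortably inside the frame —
    with at least ~13% water column — across the full pitch range the
    fixtures exercise, matching the composition the method is designed for.
    """
    return CameraModel(
        name=name,
        fx=focal,
        fy=focal,
        cx=width / 2.0,
        cy=height / 2.0,
        image_size=(width, height),
    )


@dataclass
class ScenePose:
    """Camera pose above the reef plane; angles in degrees."""

    camera_height: float = 2.0
    pitch: float = 20.0  # downward tilt below the horizontal
    roll: float = 0.0
    yaw: float = 0.0
    cam: CameraModel = field(default_factory=default_camera)

    def __post_init__(self):
        if not (0.0 < self.pitch < 90.0):
            raise ValueError("pitch must lie in (0, 90) degrees")
        if abs(self.roll) >= 45.0:
            raise ValueError("|roll| must be below 45 degrees")

    @property
    def rotation(self) -> np.ndarray:
        """World-to-camera rotation matrix."""
        th = math.radians(self.pitch)
        ph = math.radians(self.roll)
        ps = math.radians(self.yaw)
        # base: camera x = world x, camera y = -world z, camera z = world y
        R0 = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        Rx = np.array(
            [[1, 0, 0], [0, math.cos(th), -math.sin(th)], [0, math.sin(th), math.cos(th)]]
        )
        Rz = np.array(
            [[math.cos(ph), -math.sin(ph), 0], [math.sin(ph), math.cos(ph), 0], [0, 0, 1]]
        )
        Rw = np.array(
            [[math.cos(ps), -math.sin(ps), 0], [math.sin(ps), math.cos(ps), 0], [0, 0, 1]]
        )
        return Rz @ Rx @ R0 @ Rw

    @property
    def ground_to_image(self) -> np.ndarray:
        """Homography mapping ground (X, Y) to pixel (u, v)."""
        R = self.rotation
        C = np.array([0.0, 0.0, self.camera_height])
        t = -R @ C
        H = self.cam.K @ np.column_stack([R[:, 0], R[:, 1], t])
        return H / H[2, 2]

    def horizon_line(self) -> Line:
        """Image of the ground plane's line at infinity."""
        KR = self.cam.K @ self.rotation
        v1 = KR @ np.array([1.0, 0.0, 0.0])
        v2 = KR @ np.array([0.0, 1.0, 0.0])
        a, b, c = np.cross(v1, v2)
        if abs(b) < 1e-9:
            raise FixtureError("horizon is vertical in the image")
        return Line(-a / b, -c / b)

    def vanishing_point(self) -> tuple[float, float]:
        """Image of the heading direction (world +y rotated by yaw)."""
        ps = math.radians(self.yaw)
        d = np.array([math.sin(ps), math.cos(ps), 0.0])
        v = self.cam.K @ self.rotation @ d
        if abs(v[2]) < 1e-12:
            raise FixtureError("heading direction has no finite vanishing point")
        return (v[0] / v[2], v[1] / v[2])


# ----------------------------------------------------------------------
# procedural texture


def _hash01(ix: np.ndarray, iy: np.ndarray, seed: int, salt: int = 0) -> np.ndarray:
    """Deterministic uniform [0, 1) noise on an integer (int64) lattice."""
    ix = np.asarray(ix, dtype=np.int64)
    iy = np.asarray(iy, dtype=np.int64)
    h = (
        ix * np.int64(374761393)
        + iy * np.int64(668265263)
        + np.int64(seed) * np.int64(144269504)
        + np.int64(salt) * np.int64(1013904223)
    )
    h = (h ^ (h >> 13)) * np.int64(1274126177)
    h = h ^ (h >> 16)
    return (h & np.int64(0x7FFFFFFF)) * (1.0 / float(0x7FFFFFFF))


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3.0 - 2.0 * t)


def _value_noise(x: np.ndarray, y: np.ndarray, seed: int, scale: float, salt: int = 0):
    fx, fy = x / scale, y / scale
    ix, iy = np.floor(fx), np.floor(fy)
    tx, ty = _smoothstep(fx - ix), _smoothstep(fy - iy)
    ix, iy = ix.astype(np.int64), iy.astype(np.int64)
    v00 = _hash01(ix, iy, seed, salt)
    v10 = _hash01(ix + 1, iy, seed, salt)
    v01 = _hash01(ix, iy + 1, seed, salt)
    v11 = _hash01(ix + 1, iy + 1, seed, salt)
    return (v00 * (1 - tx) + v10 * tx) * (1 - ty) + (v01 * (1 - tx) + v11 * tx) * ty


def _colony_blobs(x: np.ndarray, y: np.ndarray, seed: int, cell: float = 0.9):
    """Spatial-hash field of elliptical colony blobs; returns darkening in [0, 1]."""
    ix, iy = np.floor(x / cell).astype(np.int64), np.floor(y / cell).astype(np.int64)
    dark = np.zeros_like(x)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            cxi, cyi = ix + dx, iy + dy
            present = _hash01(cxi, cyi, seed, 11) < 0.8
            bx = (cxi + _hash01(cxi, cyi, seed, 12)) * cell
            by = (cyi + _hash01(cxi, cyi, seed, 13)) * cell
            a = cell * (0.16 + 0.30 * _hash01(cxi, cyi, seed, 14))
            b = cell * (0.14 + 0.26 * _hash01(cxi, cyi, seed, 15))
            ang = math.pi * _hash01(cxi, cyi, seed, 16)
            amp = 0.20 + 0.40 * _hash01(cxi, cyi, seed, 17)
            ca, sa = np.cos(ang), np.sin(ang)
            u = ca * (x - bx) + sa * (y - by)
            v = -sa * (x - bx) + ca * (y - by)
            m = (u / a) ** 2 + (v / b) ** 2
            cov = np.clip(4.0 * (1.0 - m), 0.0, 1.0)
            dark = np.maximum(dark, amp * cov * present)
    return dark


def _depth_bands(
    y: np.ndarray, fpy: np.ndarray, seed: int, spacing: float = 1.2
) -> np.ndarray:
    """Brightness bands at seeded depths, box-filtered by the y-footprint.

    Each band is a Gaussian bump in world depth; convolution with the
    pixel's depth footprint (approximated as a Gaussian of matched
    variance) is analytic, so distant bands render as smooth, faint
    horizontal streaks instead of aliasing noise.
    """
    val = np.zeros_like(y)
    k0 = np.floor(y / spacing).astype(np.int64)
    zero = np.zeros_like(k0)
    var_fp = fpy * fpy / 12.0
    for dk in (-2, -1, 0, 1, 2):
        kk = k0 + dk
        yk = (kk + _hash01(kk, zero, seed, 41)) * spacing
        w = (0.15 + 0.50 * _hash01(kk, zero, seed, 42)) * (spacing / 1.2)
        a = (_hash01(kk, zero, seed, 43) - 0.5)
        w_eff2 = w * w + var_fp
        val += (
            a
            * (w / np.sqrt(w_eff2))
            * np.exp(-0.5 * (y - yk) ** 2 / w_eff2)
        )
    return val


def _groove_lines(x: np.ndarray, seed: int, spacing: float = 2.0):
    """Grooves parallel to the heading: the scene's true vanishing lines."""
    dark = np.zeros_like(x)
    k = np.floor(x / spacing).astype(np.int64)
    zero = np.zeros_like(k)
    for dk in (-1, 0, 1):
        kk = k + dk
        xk = (kk + 0.15 + 0.7 * _hash01(kk, zero, seed, 21)) * spacing
        hw = (0.03 + 0.05 * _hash01(kk, zero, seed, 22)) * (spacing / 2.0)
        d = np.abs(x - xk)
        cov = np.clip((hw - d) / (0.03 * spacing / 2.0), 0.0, 1.0)
        dark = np.maximum(dark, cov)
    return dark


# ----------------------------------------------------------------------
# markers and ground truth


@dataclass
class MarkerSpec:
    """Transect markers replicating the drone validation layout.

    ``x_pair_row_fractions``: image-row fractions (of height) at which pairs
    of markers separated by a fixed world distance are placed, increasing
    depth = decreasing fraction.  ``x_pair_separation``: world units; None
    picks 55% of the bottom row's world width.  ``y_spacing``: world spacing
    of the 10-point line running away from the camera; None spans rows
    [0.93H, 0.60H] with nine equal segments.
    """

    x_pair_row_fractions: tuple[float, ...] = (0.95, 0.86, 0.77, 0.68, 0.60)
    x_pair_separation: float | None = None
    y_spacing: float | None = None
    n_y_points: int = 10


@dataclass
class SceneGroundTruth:
    pose: ScenePose
    horizon: Line
    vp: tuple[float, float]
    H_ground_to_image: np.ndarray
    H_topdown: np.ndarray
    size: tuple[int, int]  # (width, height)
    marker_pairs_x: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    marker_line_y: list[np.ndarray] = field(default_factory=list)  # world points

    def ground_point(self, u: float, v: float) -> np.ndarray:
        g = np.linalg.inv(self.H_ground_to_image) @ np.array([u, v, 1.0])
        return g[:2] / g[2]

    def image_point(self, X: float, Y: float) -> np.ndarray:
        p = self.H_ground_to_image @ np.array([X, Y, 1.0])
        return p[:2] / p[2]

    def row_world_width(
        self, y: float, x0: float, x1: float, to_original: np.ndarray | None = None
    ) -> float:
        """World length of the ground segment imaged along row ``y``.

        ``to_original`` maps coordinates of a derived frame (e.g. the
        roll-removed crop) back to the rendered frame.
        """
        pts = np.array([[x0, y, 1.0], [x1, y, 1.0]])
        if to_original is not None:
            pts = pts @ to_original.T
            pts /= pts[:, 2:3]
        g = [self.ground_point(p[0], p[1]) for p in pts]
        return float(np.linalg.norm(g[1] - g[0]))

    def true_compression_factor(
        self,
        top_row: float,
        bottom_row: float,
        x0: float,
        x1: float,
        to_original: np.ndarray | None = None,
    ) -> float:
        """Ratio of bottom-row to top-row world width of a source plane."""
        wb = self.row_world_width(bottom_row, x0, x1, to_original)
        wt = self.row_world_width(top_row, x0, x1, to_original)
        return wb / wt


def _topdown_homography(pose: ScenePose, size: tuple[int, int]) -> np.ndarray:
    """Similarity-normalised image->ground map for the lower image half."""
    W, H = size
    Hgi = pose.ground_to_image
    Hinv = np.linalg.inv(Hgi)
    corners = np.array(
        [[0, 0.55 * H, 1], [W, 0.55 * H, 1], [W, H, 1], [0, H, 1]], dtype=float
    )
    g = corners @ Hinv.T
    g = g[:, :2] / g[:, 2:3]
    span_x = g[:, 0].max() - g[:, 0].min()
    s = W / span_x
    # ground y decreases downward in the top-down view (near reef at bottom)
    T = np.array([[s, 0, -s * g[:, 0].min()], [0, -s, s * g[:, 1].max()], [0, 0, 1]])
    return T @ Hinv


def _draw_disc(img: np.ndarray, u: float, v: float, radius: int, color) -> None:
    H, W = img.shape[:2]
    x0, x1 = max(0, int(u - radius - 1)), min(W, int(u + radius + 2))
    y0, y1 = max(0, int(v - radius - 1)), min(H, int(v + radius + 2))
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - u) ** 2 + (ys - v) ** 2 <= radius**2
    img[y0:y1, x0:x1][inside] = color


# ----------------------------------------------------------------------
# renderer


def render_reefscape(
    pose: ScenePose,
    texture_seed: int = 0,
    size: tuple[int, int] | None = None,
    clutter: bool = False,
    markers: MarkerSpec | None = None,
    draw_markers: bool = False,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one synthetic reefscape and its analytic ground truth.

    Returns an (H, W, 3) uint8 image.  Raises :class:`FixtureError` when the
    pose places the horizon outside the usable frame (the algorithm requires
    a visible horizon intersecting the left image edge).
    """
    cam = pose.cam
    if size is not None and tuple(size) != tuple(cam.image_size):
        cam = CameraModel(
            name=cam.name,
            fx=cam.fx,
            fy=cam.fy,
            cx=size[0] / 2.0,
            cy=size[1] / 2.0,
            k1=cam.k1, k2=cam.k2, p1=cam.p1, p2=cam.p2, k3=cam.k3,
            image_size=tuple(size),
        )
        pose = ScenePose(pose.camera_height, pose.pitch, pose.roll, pose.yaw, cam)
    W, H = cam.image_size
    horizon = pose.horizon_line()
    for x_edge in (0.0, float(W - 1)):
        yh = horizon.y_at(x_edge)
        if not (0.01 * H < yh < 0.92 * H):
            raise FixtureError(
                f"horizon at x={x_edge:.0f} is y={yh:.1f}; outside the usable frame"
            )

    xs, ys = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    xn = (xs - cam.cx) / cam.fx
    yn = (ys - cam.cy) / cam.fy
    if cam.has_distortion:
        xn, yn = undistort_normalized(xn, yn, cam.dist)
    R = pose.rotation
    # rays in world coordinates
    d = np.stack([xn, yn, np.ones_like(xn)], axis=-1) @ R  # R.T applied per pixel
    dz = d[..., 2]
    ground = dz < -1e-9
    t = np.where(ground, -pose.camera_height / np.where(ground, dz, -1.0), 0.0)
    # clamp extreme distances so lattice hashing stays in range
    X = np.clip(t * d[..., 0], -1e6, 1e6)
    Y = np.clip(t * d[..., 1], -1e6, 1e6)

    seed = int(texture_seed)
    # pixel ground footprints: how much world distance one pixel spans.  A
    # real camera averages the texture over this footprint, so frequencies
    # beyond it vanish; near the horizon the y-footprint explodes and only
    # structure varying with depth survives, as horizontal streaks.
    fpx = np.abs(np.gradient(X, axis=1))
    fpy = np.abs(np.gradient(Y, axis=0))

    # texture evaluated on ground pixels only (flat arrays)
    g = ground.ravel()
    Xg, Yg = X.ravel()[g], Y.ravel()[g]
    fpxg, fpyg = fpx.ravel()[g], fpy.ravel()[g]

    def att_axis(s: float, fp: np.ndarray) -> np.ndarray:
        # incoherent averaging over N = fp/s independent texture cells
        # reduces the standard deviation by sqrt(N)
        return np.minimum(1.0, np.sqrt(s / np.maximum(fp, 1e-9)))

    def att2(s: float) -> np.ndarray:
        return att_axis(s, fpxg) * att_axis(s, fpyg)

    # texture grain scales with camera height, so a scene is invariant under
    # a joint rescaling of altitude and world lengths (a survey from 16 m
    # sees proportionally larger structure than one from 2 m)
    ts = 0.25 * pose.camera_height
    octaves = [(6.0 * ts, 0.22, 9), (1.8 * ts, 0.20, 1), (0.35 * ts, 0.16, 2),
               (0.15 * ts, 0.20, 4), (0.06 * ts, 0.20, 3), (0.025, 0.22, 5),
               (0.010, 0.18, 6)]
    base = np.full_like(Xg, 0.55)
    for s, amp, salt in octaves:
        base += amp * (_value_noise(Xg, Yg, seed, s, salt) - 0.5) * 2.0 * att2(s)
    # compressed-texture streaks: where the y-footprint exceeds the feature
    # scale, rows sample independent texture -> dense horizontal micro-streaks
    # dominate the strip just below the horizon, as in oblique reef photos
    for s, amp, salt in [(0.6 * ts, 0.30, 7), (2.0 * ts, 0.22, 8)]:
        unresolved = np.clip(1.0 - s / np.maximum(fpyg, 1e-9), 0.0, 1.0)
        base += (
            amp
            * (_value_noise(Xg, Yg, seed, s, salt) - 0.5)
            * 2.0
            * att_axis(s, fpxg)
            * unresolved
        )
    base += 0.9 * _depth_bands(Yg, fpyg, seed, spacing=1.2 * ts)
    # colonies and grooves darken multiplicatively so internal texture
    # survives, as in real reef imagery where coral heads and sand channels
    # keep fine structure of their own; both fade with their footprint
    intensity = (
        base
        * (1.0 - 0.75 * _groove_lines(Xg, seed, spacing=2.0 * ts)
           * att_axis(0.12 * ts, fpxg) ** 2)
        * (1.0 - 0.65 * _colony_blobs(Xg, Yg, seed, cell=0.9 * ts) * att2(0.5 * ts))
    )
    intensity = np.clip(intensity, 0.04, 1.0)

    # distance fog toward deep-water colour: light is lost with range, so the
    # reef fades toward the dark background near the horizon
    fog_g = np.clip(1.0 - np.exp(-t.ravel()[g] / (60.0 * pose.camera_height)), 0.0, 0.45)
    water_col = np.array([30.0, 55.0, 80.0])
    reef_flat = intensity[:, None] * np.array([235.0, 210.0, 170.0])
    reef_flat = reef_flat * (1.0 - fog_g[:, None]) + water_col * fog_g[:, None]
    reef_rgb = np.zeros((H * W, 3))
    reef_rgb[g] = reef_flat
    reef_rgb = reef_rgb.reshape(H, W, 3)

    # water column: texture-free gradient, darkest at the horizon (range-induced
    # light loss), brighter toward the sunlit surface at the top of the frame
    frac = np.clip(ys / max(horizon.y_at(W / 2.0), 1.0), 0.0, 1.0)
    water_rgb = np.stack(
        [
            68.0 - 40.0 * frac,
            108.0 - 56.0 * frac,
            138.0 - 60.0 * frac,
        ],
        axis=-1,
    )
    img = np.where(ground[..., None], reef_rgb, water_rgb)

    if clutter:
        rng = np.random.default_rng(seed + 7919)
        y_min_h = min(horizon.y_at(0), horizon.y_at(W - 1))
        for _ in range(8):
            cu = rng.uniform(0.05 * W, 0.95 * W)
            cv = rng.uniform(0.03 * H, 0.55 * y_min_h)
            a = rng.uniform(8, 30)
            b = rng.uniform(5, 15)
            ang = rng.uniform(0, math.pi)
            ca, sa = math.cos(ang), math.sin(ang)
            u = ca * (xs - cu) + sa * (ys - cv)
            v = -sa * (xs - cu) + ca * (ys - cv)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            img[inside] = np.array([235.0, 235.0, 228.0])

    gt = SceneGroundTruth(
        pose=pose,
        horizon=horizon,
        vp=pose.vanishing_point(),
        H_ground_to_image=pose.ground_to_image,
        H_topdown=_topdown_homography(pose, (W, H)),
        size=(W, H),
    )

    if markers is not None:
        Hgi = gt.H_ground_to_image
        bottom_w = gt.row_world_width(H - 1.0, 0.0, W - 1.0)
        sep = markers.x_pair_separation or 0.55 * bottom_w
        for frac in markers.x_pair_row_fractions:
            Xc, Yc = gt.ground_point(W / 2.0, frac * H)
            p1 = np.array([Xc - sep / 2.0, Yc])
            p2 = np.array([Xc + sep / 2.0, Yc])
            gt.marker_pairs_x.append((p1, p2))
        _, Y0 = gt.ground_point(W / 2.0, 0.93 * H)
        if markers.y_spacing is None:
            _, Y1 = gt.ground_point(W / 2.0, 0.60 * H)
            spacing = (Y1 - Y0) / (markers.n_y_points - 1)
        else:
            spacing = markers.y_spacing
        Xline = gt.ground_point(0.40 * W, 0.90 * H)[0]
        for k in range(markers.n_y_points):
            gt.marker_line_y.append(np.array([Xline, Y0 + k * spacing]))
        if draw_markers:
            for p1, p2 in gt.marker_pairs_x:
                for p in (p1, p2):
                    u, v = gt.image_point(*p)
                    _draw_disc(img, u, v, 4, np.array([250.0, 250.0, 250.0]))
            for p in gt.marker_line_y:
                u, v = gt.image_point(*p)
                _draw_disc(img, u, v, 4, np.array([250.0, 60.0, 60.0]))

    return np.clip(img, 0, 255).astype(np.uint8), gt


# ----------------------------------------------------------------------
# calibration imagery


def render_checkerboard(
    cam: CameraModel,
    rows: int,
    cols: int,
    square_px: float,
    rvec: np.ndarray,
    tvec: np.ndarray,
    supersample: int = 2,
) -> np.ndarray:
    """Render a checkerboard plane under pose (rvec, tvec) with distortion.

    ``rows x cols`` are *inner* corners, so the board has (rows+1) x (cols+1)
    squares of side ``square_px`` world units.  Background is mid grey.
    """
    from scipy.spatial.transform import Rotation

    W, H = cam.image_size
    Rm = Rotation.from_rotvec(rvec).as_matrix()
    Hb = cam.K @ np.column_stack([Rm[:, 0], Rm[:, 1], tvec])
    Hb_inv = np.linalg.inv(Hb / Hb[2, 2])
    ss = supersample
    xs, ys = np.meshgrid(
        (np.arange(W * ss) + 0.5) / ss - 0.5, (np.arange(H * ss) + 0.5) / ss - 0.5
    )
    if cam.has_distortion:
        xn = (xs - cam.cx) / cam.fx
        yn = (ys - cam.cy) / cam.fy
        xu, yu = undistort_normalized(xn, yn, cam.dist)
        u = xu * cam.fx + cam.cx
        v = yu * cam.fy + cam.cy
    else:
        u, v = xs, ys
    w = Hb_inv[2, 0] * u + Hb_inv[2, 1] * v + Hb_inv[2, 2]
    w = np.where(np.abs(w) < 1e-12, np.nan, w)
    bx = (Hb_inv[0, 0] * u + Hb_inv[0, 1] * v + Hb_inv[0, 2]) / w
    by = (Hb_inv[1, 0] * u + Hb_inv[1, 1] * v + Hb_inv[1, 2]) / w
    # inner corner (0,0) sits one square in from the board edge
    gx = bx / square_px + 1.0
    gy = by / square_px + 1.0
    on_board = (gx >= 0) & (gx <= cols + 1) & (gy >= 0) & (gy <= rows + 1)
    on_board &= np.isfinite(gx) & np.isfinite(gy)
    checker = (np.floor(gx).astype(np.int64) + np.floor(gy).astype(np.int64)) % 2
    val = np.where(on_board, np.where(checker == 0, 235.0, 20.0), 128.0)
    val = val.reshape(H, ss, W, ss).mean(axis=(1, 3))
    return val.astype(np.uint8)


def render_calibration_set(
    cam: CameraModel, n_views: int = 15, seed: int = 0
) -> list[np.ndarray]:
    """Seeded checkerboard views spanning tilts and frame positions."""
    if n_views < MIN_VIEWS_FOR_SET:
        raise ValueError(f"need at least {MIN_VIEWS_FOR_SET} views")
    rng = np.random.default_rng(seed)
    W, H = cam.image_size
    rows, cols = 6, 9
    square = 1.0
    images = []
    for i in range(n_views):
        tilt_x = math.radians(rng.uniform(-22, 22))
        tilt_y = math.radians(rng.uniform(-22, 22))
        spin = math.radians(rng.uniform(-15, 15))
        rvec = np.array([tilt_x, tilt_y, spin])
        # place board centre at a varying frame position and depth
        depth = rng.uniform(14, 22) * square
        ux = rng.uniform(0.3, 0.7) * W
        uy = rng.uniform(0.3, 0.7) * H
        # board centre in board coords
        bc = np.array([(cols - 1) / 2.0 * square, (rows - 1) / 2.0 * square, 0.0])
        from scipy.spatial.transform import Rotation

        Rm = Rotation.from_rotvec(rvec).as_matrix()
        dir_cam = np.linalg.inv(cam.K) @ np.array([ux, uy, 1.0])
        tvec = dir_cam / dir_cam[2] * depth - Rm @ bc
        images.append(render_checkerboard(cam, rows, cols, square, rvec, tvec))
    return images


MIN_VIEWS_FOR_SET = 10
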