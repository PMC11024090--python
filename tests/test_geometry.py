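"""Projective primitives against brute-force / closed-form oracles."""

import math

import numpy as np
import pytest

from reefwarp.errors import (
    PointAtInfinityError,
    SingularConfigurationError,
    VerticalDataError,
)
from reefwarp.geometry import (
    LineSegment,
    Quad,
    apply_homography,
    apply_homography_array,
    destination_corners,
    fit_homography,
    largest_inscribed_rect_after_rotation,
    largest_rect_in_mask,
    perpendicular_distance,
    theil_sen_fit,
    warp_image,
)

UNIT = Quad.from_rect(0, 0, 1, 1)


def brute_theil_sen(points):
    """Enumeration oracle: all pairwise slopes, then residual intercepts."""
    slopes = []
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            dx = points[j][0] - points[i][0]
            if dx != 0:
                slopes.append((points[j][1] - points[i][1]) / dx)
    m = float(np.median(slopes))
    b = float(np.median([y - m * x for x, y in points]))
    return m, b


def brute_max_rect(mask):
    """Exhaustive O(n^3-ish) rectangle enumeration oracle."""
    rows, cols = mask.shape
    best = 0
    integral = np.cumsum(np.cumsum(mask.astype(int), 0), 1)

    def count(y0, x0, y1, x1):  # inclusive corners
        s = integral[y1, x1]
        if y0 > 0:
            s -= integral[y0 - 1, x1]
        if x0 > 0:
            s -= integral[y1, x0 - 1]
        if y0 > 0 and x0 > 0:
            s += integral[y0 - 1, x0 - 1]
        return s

    for y0 in range(rows):
        for x0 in range(cols):
            if not mask[y0, x0]:
                continue
            for y1 in range(y0, rows):
                if not mask[y1, x0]:
                    break
                for x1 in range(x0, cols):
                    h, w = y1 - y0 + 1, x1 - x0 + 1
                    if count(y0, x0, y1, x1) == h * w:
                        best = max(best, h * w)
                    else:
                        break
    return best


class TestFitHomography:
    def test_identity(self):
        H = fit_homography(UNIT, UNIT)
        assert np.allclose(H, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        dst = Quad.from_rect(5, 0, 6, 1)
        H = fit_homography(UNIT, dst)
        assert np.allclose(H, [[1, 0, 5], [0, 1, 0], [0, 0, 1]], atol=1e-9)

    def test_recovers_random_homography(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            Hstar = np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
            Hstar /= Hstar[2, 2]
            if abs(np.linalg.det(Hstar)) < 1e-3:
                continue
            dst_pts = apply_homography_array(Hstar, np.array(UNIT.corners))
            dst = Quad(*[tuple(p) for p in dst_pts])
            H = fit_homography(UNIT, dst)
            assert np.allclose(H, Hstar, atol=1e-9)

    def test_degenerate_raises(self):
        bad = Quad((0, 0), (1, 0), (2, 0), (3, 0))  # all collinear
        with pytest.raises(SingularConfigurationError):
            fit_homography(bad, UNIT)

    def test_round_trip_on_random_quads(self):
        """fit then apply returns the four defining corners, 1000 quads."""
        rng = np.random.default_rng(0)
        n_ok = 0
        while n_ok < 1000:
            src_c = rng.uniform(0, 100, (4, 2))
            dst_c = rng.uniform(0, 100, (4, 2))
            src = Quad(*[tuple(p) for p in src_c])
            dst = Quad(*[tuple(p) for p in dst_c])
            try:
                H = fit_homography(src, dst)
            except SingularConfigurationError:
                continue
            got = apply_homography_array(H, src_c)
            if not np.all(np.isfinite(got)):
                continue
            assert np.allclose(got, dst_c, atol=1e-6)
            n_ok += 1


class TestApplyHomography:
    def test_identity(self):
        assert apply_homography(np.eye(3), (13, 7)) == pytest.approx((13, 7))

    def test_pure_scaling(self):
        H = np.diag([2.0, 2.0, 1.0])
        assert apply_homography(H, (3, 4)) == pytest.approx((6, 8))

    def test_projective_division(self):
        # h7 = 0.001, rest identity: lambda = 0.001*100 + 1 = 1.1
        H = np.eye(3)
        H[2, 0] = 0.001
        u, v = apply_homography(H, (100, 50))
        assert u == pytest.approx(100 / 1.1)
        assert v == pytest.approx(50 / 1.1)

    def test_point_at_infinity(self):
        H = np.eye(3)
        H[2, 0] = -0.01  # denominator zero at x=100
        with pytest.raises(PointAtInfinityError):
            apply_homography(H, (100, 0))


class TestWarpImage:
    def test_identity_preserves_image(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (20, 30))
        out = warp_image(img, np.eye(3), (30, 20))
        assert np.allclose(out, img, atol=1e-8)

    def test_translation_shifts_and_blackfills(self):
        img = np.full((10, 10), 200.0)
        H = np.array([[1, 0, 4], [0, 1, 0], [0, 0, 1]], dtype=float)
        out = warp_image(img, H, (10, 10))
        assert np.allclose(out[:, 4:], 200.0)
        assert np.allclose(out[:, :3], 0.0)

    def test_round_trip_smooth_image(self):
        ys, xs = np.mgrid[0:60, 0:80]
        img = 100 + 50 * np.sin(xs / 9.0) * np.cos(ys / 7.0)
        H = fit_homography(
            Quad.from_rect(0, 0, 80, 60), Quad((4, 2), (76, 3), (78, 57), (2, 58))
        )
        there = warp_image(img, H, (80, 60))
        back = warp_image(there, np.linalg.inv(H), (80, 60))
        interior = np.abs(back - img)[10:-10, 10:-10]
        assert interior.mean() < 2.0


class TestDestinationCorners:
    def test_identity_factor(self):
        assert destination_corners(1000, 400, 1.0) == ((0.0, 400.0), (1000.0, 400.0))

    def test_half_factor(self):
        assert destination_corners(1000, 400, 0.5) == ((250.0, 400.0), (750.0, 400.0))

    @pytest.mark.parametrize("x_cf", [0.01, 0.3, 0.77, 1.0])
    def test_symmetry_and_width(self, x_cf):
        w = 640
        c_l, c_r = destination_corners(w, 480, x_cf)
        assert c_l[0] + c_r[0] == pytest.approx(w)
        assert c_r[0] - c_l[0] == pytest.approx(x_cf * w)

    def test_monotone_in_x_cf(self):
        widths = [
            destination_corners(500, 300, f)[1][0] - destination_corners(500, 300, f)[0][0]
            for f in np.linspace(0.05, 1.0, 12)
        ]
        assert np.all(np.diff(widths) > 0)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            destination_corners(100, 100, bad)


class TestTheilSen:
    def test_exact_line(self):
        pts = [(x, 2 * x + 1) for x in range(10)]
        line = theil_sen_fit(pts)
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(1.0)

    def test_two_points(self):
        line = theil_sen_fit([(0, 3), (2, 7)])
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(3.0)

    def test_outlier_resistance(self):
        pts = [(x, 2 * x + 1) for x in range(20)]
        pts += [(3, 500), (8, -300), (11, 900), (15, 777), (17, -50), (19, 1e4)]
        line = theil_sen_fit(pts)
        assert line.slope == pytest.approx(2.0, abs=1e-9)
        assert line.intercept == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        pts = [tuple(p) for p in rng.normal(0, 10, (n, 2))]
        m, b = brute_theil_sen(pts)
        line = theil_sen_fit(pts)
        assert line.slope == pytest.approx(m, abs=1e-12)
        assert line.intercept == pytest.approx(b, abs=1e-12)

    def test_vertical_data_error(self):
        with pytest.raises(VerticalDataError):
            theil_sen_fit([(1, 0), (1, 5), (1, 9)])


class TestInscribedRect:
    def test_no_rotation(self):
        q = largest_inscribed_rect_after_rotation(800, 600, 0)
        assert q.tr[0] - q.tl[0] == pytest.approx(800)
        assert q.bl[1] - q.tl[1] == pytest.approx(600)

    def test_square_45deg(self):
        q = largest_inscribed_rect_after_rotation(400, 400, 45)
        side = q.tr[0] - q.tl[0]
        assert side == pytest.approx(400 / math.sqrt(2), abs=1.0)
        assert q.bl[1] - q.tl[1] == pytest.approx(side, abs=1e-6)

    @pytest.mark.parametrize("theta", [2.0, 5.0, 12.0, 30.0])
    def test_matches_raster_oracle(self, theta):
        """Rasterised containment check of the closed-form rectangle."""
        w, h = 160, 120
        q = largest_inscribed_rect_after_rotation(w, h, theta)
        t = math.radians(theta)
        bb_w = w * math.cos(t) + h * math.sin(t)
        bb_h = w * math.sin(t) + h * math.cos(t)
        # footprint polygon of the rotated image in the canvas frame
        c, s = math.cos(t), math.sin(t)
        centre = np.array([bb_w / 2, bb_h / 2])
        corners = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
        R = np.array([[c, -s], [s, c]])
        poly = corners @ R.T + centre

        def inside(p, eps=1e-6):
            # point-in-convex-polygon via cross products
            sgn = 0
            for i in range(4):
                a, b = poly[i], poly[(i + 1) % 4]
                cr = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                if abs(cr) < eps:
                    continue
                if sgn == 0:
                    sgn = np.sign(cr)
                elif np.sign(cr) != sgn:
                    return False
            return True

        for corner in q.corners:
            assert inside(corner, eps=1e-3)
        # maximality: growing every side by 2 px escapes the footprint
        x0, y0 = q.tl
        x1, y1 = q.br
        grown = [(x0 - 2, y0 - 2), (x1 + 2, y0 - 2), (x1 + 2, y1 + 2), (x0 - 2, y1 + 2)]
        assert not all(inside(p) for p in grown)


class TestLargestRectInMask:
    def test_all_valid(self):
        q = largest_rect_in_mask(np.ones((80, 100), bool))
        assert (q.tl, q.br) == ((0, 0), (100, 80))

    def test_top_row_invalid(self):
        m = np.ones((80, 100), bool)
        m[0] = False
        q = largest_rect_in_mask(m)
        assert q.tl == (0, 1)
        assert q.br == (100, 80)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            largest_rect_in_mask(np.zeros((5, 5), bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((50, 50)) > 0.25
        if not mask.any():
            mask[0, 0] = True
        q = largest_rect_in_mask(mask)
        area = (q.br[0] - q.tl[0]) * (q.br[1] - q.tl[1])
        assert area == brute_max_rect(mask)
        sub = mask[int(q.tl[1]): int(q.br[1]), int(q.tl[0]): int(q.br[0])]
        assert sub.all()


class TestPerpendicularDistance:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p1, p2, q = rng.uniform(-50, 50, (3, 2))
            if np.allclose(p1, p2):
                continue
            seg = LineSegment(tuple(p1), tuple(p2))
            a, b = p2[1] - p1[1], p1[0] - p2[0]
            c = p2[0] * p1[1] - p1[0] * p2[1]
            expect = abs(a * q[0] + b * q[1] + c) / math.hypot(a, b)
            assert perpendicular_distance(seg, tuple(q)) == pytest.approx(expect)
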